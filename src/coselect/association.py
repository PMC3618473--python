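"""Per-drug association of single events and co-events with response.

Frequencies of an event tuple among the drug's sensitive (S) and
resistant (R) lines are compared two ways, following the selection
rules used for biomarker discovery in cell-line screens:

* significance — Fisher's exact test for single events; Pearson
  chi-square on the 2x2 (tuple presence x S/R membership) table for
  co-events, with observed-vs-predicted goodness-of-fit diagnostics
  inside each subpopulation;
* effect size — the S/R frequency ratio, with a greater-than-1.5-fold
  change (outside [0.667, 1.5]) required for selection. An event absent
  from resistant lines but present in sensitive lines gives an infinite
  ratio, a strong association with sensitivity.

Denominators are always the genomically characterized lines tested
with the drug, not the whole panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import EventMatrix
from .coevents import enumerate_event_tuples
from .exceptions import UntestableError
from .response import ResponseCall
from .stats import chi2_contingency_2x2, chisq_obs_vs_pred, fisher_exact_2x2

SENSITIVE = "sensitive"
RESISTANT = "resistant"
NONE = "none"

#: Fold-change window [1/fold, fold] outside which an S/R ratio counts.
DEFAULT_FOLD = 1.5
#: Prevalence filter for single events (fraction of S or R lines).
DEFAULT_MIN_PREVALENCE = 0.12
#: Minimum cell lines carrying a co-event for it to be scored.
DEFAULT_MIN_COUNT = 4


def sr_ratio(count_s: int, n_s: int, count_r: int, n_r: int) -> float:
    """S/R frequency ratio with the +inf sentinel for count_R = 0."""
    freq_s = count_s / n_s
    freq_r = count_r / n_r
    if count_r == 0:
        return math.inf if count_s > 0 else float("nan")
    return freq_s / freq_r


def direction_of(ratio: float, fold: float = DEFAULT_FOLD) -> str:
    if math.isnan(ratio):
        return NONE
    if ratio > fold:
        return SENSITIVE
    if ratio < 1.0 / fold:
        return RESISTANT
    return NONE


@dataclass
class DrugAssociationResult:
    """Association of a 1-3 locus event tuple with one drug's response."""

    loci: tuple[str, ...]
    drug: str
    n_S: int
    n_R: int
    count_S: int
    count_R: int
    freq_S: float
    freq_R: float
    sr_ratio: float
    p_value: float | None
    direction: str
    powered: bool
    selected: bool = False
    p_value_yates: float | None = None
    p_obs_pred_S: float | None = None
    p_obs_pred_R: float | None = None
    testable: bool = True

    @property
    def tuple_size(self) -> int:
        return len(self.loci)

    @property
    def total_count(self) -> int:
        """Cell lines harboring the event among tested lines."""
        return self.count_S + self.count_R


def _tested_groups(matrix: EventMatrix, call: ResponseCall):
    """Genomically characterized tested lines, split S/R.

    Lines screened but absent from the genomic tables are retained for
    response calling upstream and excluded here.
    """
    genomic = set(matrix.cell_lines)
    s_lines = sorted(call.sensitive & genomic)
    r_lines = sorted(call.resistant & genomic)
    if not s_lines or not r_lines:
        raise ValueError(
            f"{call.drug}: empty sensitive or resistant group after "
            "intersecting with genomic lines (degenerate call upstream?)"
        )
    return s_lines, r_lines


def _tuple_counts(matrix: EventMatrix, lines, loci) -> int:
    sub = matrix.restrict_cell_lines(lines)
    mask = np.ones(sub.n_cell_lines, dtype=bool)
    for g in loci:
        mask &= sub.locus_column(g)
    return int(mask.sum())


def single_event_drug_association(
    matrix: EventMatrix,
    call: ResponseCall,
    min_prevalence: float = DEFAULT_MIN_PREVALENCE,
    fold: float = DEFAULT_FOLD,
) -> list[DrugAssociationResult]:
    """Score every locus against one drug's S/R partition.

    p-values come from the two-sided Fisher's exact test on
    [[count_S, n_S - count_S], [count_R, n_R - count_R]]; an event is
    *powered* when its frequency exceeds ``min_prevalence`` in the
    sensitive or the resistant lines. Loci absent from both groups are
    skipped.
    """
    s_lines, r_lines = _tested_groups(matrix, call)
    n_s, n_r = len(s_lines), len(r_lines)
    sub_s = matrix.restrict_cell_lines(s_lines)
    sub_r = matrix.restrict_cell_lines(r_lines)
    results = []
    for j, locus in enumerate(matrix.loci):
        c_s = int(sub_s.locus_column(locus).sum())
        c_r = int(sub_r.locus_column(locus).sum())
        if c_s == 0 and c_r == 0:
            continue
        ratio = sr_ratio(c_s, n_s, c_r, n_r)
        p = fisher_exact_2x2(c_s, n_s, c_r, n_r)
        freq_s, freq_r = c_s / n_s, c_r / n_r
        results.append(
            DrugAssociationResult(
                loci=(locus,),
                drug=call.drug,
                n_S=n_s,
                n_R=n_r,
                count_S=c_s,
                count_R=c_r,
                freq_S=freq_s,
                freq_R=freq_r,
                sr_ratio=ratio,
                p_value=p,
                direction=direction_of(ratio, fold),
                powered=(freq_s > min_prevalence or freq_r > min_prevalence),
            )
        )
    return results


def coevent_drug_association(
    matrix: EventMatrix,
    call: ResponseCall,
    k: int = 2,
    min_count: int = DEFAULT_MIN_COUNT,
    fold: float = DEFAULT_FOLD,
    alpha: float = 0.05,
    subpop_marginals: str = "within",
) -> list[DrugAssociationResult]:
    """Score k-event tuples against one drug's S/R partition.

    The primary p-value is the Pearson chi-square on the 2x2 table of
    co-event presence x S/R membership (the Yates-corrected variant is
    reported alongside). Secondary diagnostics re-run the
    observed-vs-predicted goodness of fit inside the sensitive and the
    resistant subpopulations, with marginals computed within each
    subpopulation (``subpop_marginals='within'``, default) or over the
    whole tested population (``'whole'``).

    A tuple is *selected* when p <= alpha and its S/R ratio falls
    strictly outside [1/fold, fold]. Tuples carried by fewer than
    ``min_count`` tested lines, or absent from both groups, are skipped.
    """
    if subpop_marginals not in ("within", "whole"):
        raise ValueError("subpop_marginals must be 'within' or 'whole'")
    s_lines, r_lines = _tested_groups(matrix, call)
    n_s, n_r = len(s_lines), len(r_lines)
    tested = matrix.restrict_cell_lines(s_lines + r_lines)
    sub_s = tested.restrict_cell_lines(s_lines)
    sub_r = tested.restrict_cell_lines(r_lines)
    _, counts = enumerate_event_tuples(tested, k)
    whole_freqs = {g: tested.locus_column(g).mean() for g in tested.loci}
    results = []
    for loci, total in sorted(counts.items()):
        if total < min_count:
            continue
        c_s = _tuple_counts(sub_s, sub_s.cell_lines, loci)
        c_r = total - c_s
        if c_s == 0 and c_r == 0:
            continue
        ratio = sr_ratio(c_s, n_s, c_r, n_r)
        res = DrugAssociationResult(
            loci=loci,
            drug=call.drug,
            n_S=n_s,
            n_R=n_r,
            count_S=c_s,
            count_R=c_r,
            freq_S=c_s / n_s,
            freq_R=c_r / n_r,
            sr_ratio=ratio,
            p_value=None,
            direction=direction_of(ratio, fold),
            powered=True,
        )
        try:
            _, res.p_value = chi2_contingency_2x2(c_s, n_s, c_r, n_r, yates=False)
            _, res.p_value_yates = chi2_contingency_2x2(c_s, n_s, c_r, n_r, yates=True)
        except UntestableError:
            res.testable = False
        for group_matrix, count, attr in (
            (sub_s, c_s, "p_obs_pred_S"),
            (sub_r, c_r, "p_obs_pred_R"),
        ):
            if subpop_marginals == "within":
                margs = [group_matrix.locus_column(g).mean() for g in loci]
            else:
                margs = [whole_freqs[g] for g in loci]
            n_group = group_matrix.n_cell_lines
            expected = n_group * float(np.prod(margs))
            try:
                _, p_gof = chisq_obs_vs_pred(count, expected, n_group)
                setattr(res, attr, p_gof)
            except UntestableError:
                pass
        res.selected = bool(
            res.testable
            and res.p_value is not None
            and res.p_value <= alpha
            and (res.sr_ratio > fold or res.sr_ratio < 1.0 / fold)
        )
        results.append(res)
    return results


def _abs_log_ratio(ratio: float) -> float:
    if math.isinf(ratio):
        return math.inf
    if ratio <= 0 or math.isnan(ratio):
        return math.inf  # 0 means absent from S: maximal resistance signal
    return abs(math.log(ratio))


def rank_top_events(results, alpha: float = 0.05) -> list[DrugAssociationResult]:
    """Order by the table-selection key: most significant p-value first,
    then the maximum number of cell lines harboring the event, then the
    S/R ratio furthest from unity (the infinite sentinel ranks above
    every finite ratio); deterministic ties by locus tuple."""
    kept = [r for r in results if r.p_value is not None and r.p_value <= alpha]
    return sorted(
        kept,
        key=lambda r: (r.p_value, -r.total_count, -_abs_log_ratio(r.sr_ratio), r.loci),
    )


class DrugAssociationResults:
    """Container for one drug's single- and co-event associations."""

    _COLUMNS = [
        "drug", "loci", "tuple_size", "n_S", "n_R", "count_S", "count_R",
        "freq_S", "freq_R", "sr_ratio", "p_value", "direction", "powered",
    ]

    def __init__(self, drug: str, results: list[DrugAssociationResult]):
        self.drug = drug
        self.results = results

    def __len__(self) -> int:
        return len(self.results)

    def __iter__(self):
        return iter(self.results)

    def of_size(self, k: int):
        return [r for r in self.results if r.tuple_size == k]

    def top(self, alpha: float = 0.05):
        return rank_top_events(self.results, alpha=alpha)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "drug": r.drug,
                "loci": "::".join(r.loci),
                "tuple_size": r.tuple_size,
                "n_S": r.n_S,
                "n_R": r.n_R,
                "count_S": r.count_S,
                "count_R": r.count_R,
                "freq_S": r.freq_S,
                "freq_R": r.freq_R,
                "sr_ratio": r.sr_ratio,
                "p_value": r.p_value,
                "direction": r.direction,
                "powered": r.powered,
            }
            for r in self.results
        ]
        return pd.DataFrame(rows, columns=self._COLUMNS)

    def summary(self) -> str:
        top = self.top()
        lines = [
            f"Drug association: {self.drug}",
            f"  scored tuples   {len(self.results)}",
            f"  significant     {len(top)} (p <= 0.05)",
        ]
        for r in top[:10]:
            ratio = "inf" if math.isinf(r.sr_ratio) else f"{r.sr_ratio:.3g}"
            lines.append(
                f"    {'::'.join(r.loci):<30} p={r.p_value:.3g} "
                f"S/R={ratio} ({r.direction})"
            )
        return "\n".join(lines)


class DrugAssociation:
    """Model of event-response association for one drug.

    ``fit()`` scores singles (Fisher's exact, prevalence filter) and
    co-events of the requested sizes (chi-square, fold filter) and
    returns a :class:`DrugAssociationResults`.
    """

    def __init__(self, matrix: EventMatrix, call: ResponseCall,
                 tuple_sizes=(1, 2), min_prevalence: float = DEFAULT_MIN_PREVALENCE,
                 min_count: int = DEFAULT_MIN_COUNT, fold: float = DEFAULT_FOLD):
        self.matrix = matrix
        self.call = call
        self.tuple_sizes = tuple(tuple_sizes)
        self.min_prevalence = min_prevalence
        self.min_count = min_count
        self.fold = fold

    def fit(self, alpha: float = 0.05) -> DrugAssociationResults:
        results: list[DrugAssociationResult] = []
        for k in self.tuple_sizes:
            if k == 1:
                results.extend(
                    single_event_drug_association(
                        self.matrix, self.call,
                        min_prevalence=self.min_prevalence, fold=self.fold,
                    )
                )
            else:
                results.extend(
                    coevent_drug_association(
                        self.matrix, self.call, k=k, min_count=self.min_count,
                        fold=self.fold, alpha=alpha,
                    )
                )
        return DrugAssociationResults(self.call.drug, results)
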
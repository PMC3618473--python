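"""Mutation x lineage interaction and the subtraction cross-validation.

A biomarker that predicts drug response may do so only through the
tumor lineages it happens to concentrate in. This module (1) tests each
(event tuple, lineage) pair for association with the S/R partition and
(2) re-tests the tuple after *subtracting* every lineage that reached
significance — the remaining cell lines form an internal test set that
played no part in selecting the interacting lineages, so a tuple that
stays significant is associated with response regardless of lineage.

The default per-pair test is a proportional goodness of fit: the m
carriers of the (tuple, lineage) combination are split against the
expectation (m*n_S/n, m*n_R/n) from the panel-wide S/R proportions,
with the same two-cell chi-square used for co-event disequilibrium. A
Fisher 2x2 alternative (carriers vs non-carriers x S/R) is selectable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import UNKNOWN_LINEAGE, EventMatrix
from .exceptions import UntestableError
from .response import ResponseCall
from .stats import chisq_obs_vs_pred, fisher_exact_2x2

PROPORTIONAL_GOF = "proportional_gof"
FISHER_2X2 = "fisher_2x2"

#: Minimum carriers of a (tuple, lineage) combination for the test to run.
DEFAULT_MIN_CARRIERS = 3
#: Prevalence below which a residual association is reported as unpowered.
DEFAULT_MIN_PREVALENCE = 0.12


@dataclass
class LineagePairResult:
    """Association of one (event tuple, lineage) pair with S/R."""

    loci: tuple[str, ...]
    lineage: str
    drug: str
    count_S: int
    count_R: int
    expected_S: float
    expected_R: float
    p_value: float | None
    significant: bool
    tested: bool = True

    @property
    def total(self) -> int:
        return self.count_S + self.count_R


@dataclass
class ResidualAssociationResult:
    """Tuple-response association after removing interacting lineages."""

    loci: tuple[str, ...]
    drug: str
    removed_lineages: frozenset[str]
    n_remaining: int
    count_S: int
    count_R: int
    p_value: float | None
    powered: bool
    direction: str
    significant: bool


def _carrier_mask(matrix: EventMatrix, loci) -> np.ndarray:
    mask = np.ones(matrix.n_cell_lines, dtype=bool)
    for g in loci:
        mask &= matrix.locus_column(g)
    return mask


def enumerate_event_lineage_pairs(matrix: EventMatrix):
    """All (locus, lineage) pairs with >= 1 carrying cell line.

    Returns ``{(locus, lineage): count}`` over the whole panel. Raises
    when no lineage annotations are present.
    """
    lineages = np.array([matrix.lineage[c] for c in matrix.cell_lines])
    if all(l == UNKNOWN_LINEAGE for l in lineages):
        raise ValueError("event matrix carries no lineage annotations")
    pairs: dict[tuple[str, str], int] = {}
    for j, locus in enumerate(matrix.loci):
        col = matrix.values[:, j]
        for lin in np.unique(lineages[col]):
            pairs[(locus, str(lin))] = int((col & (lineages == lin)).sum())
    return pairs


def test_event_lineage_association(
    matrix: EventMatrix,
    call: ResponseCall,
    loci,
    lineage: str,
    null: str = PROPORTIONAL_GOF,
    alpha: float = 0.05,
    min_carriers: int = DEFAULT_MIN_CARRIERS,
) -> LineagePairResult:
    """Test one (event tuple, lineage) pair against the S/R partition.

    ``proportional_gof`` (default) splits the pair's m carriers against
    the expectation proportional to the panel's group sizes;
    ``fisher_2x2`` tests carriers vs non-carriers across S/R.
    """
    loci = tuple(loci) if not isinstance(loci, str) else (loci,)
    tested_lines = sorted(
        (call.sensitive | call.resistant) & set(matrix.cell_lines)
    )
    sub = matrix.restrict_cell_lines(tested_lines)
    lineages = np.array([sub.lineage[c] for c in sub.cell_lines])
    carriers = _carrier_mask(sub, loci) & (lineages == lineage)
    in_s = np.array([c in call.sensitive for c in sub.cell_lines])
    n_s, n_r = int(in_s.sum()), int((~in_s).sum())
    n = n_s + n_r
    count_s = int((carriers & in_s).sum())
    count_r = int((carriers & ~in_s).sum())
    m = count_s + count_r
    expected_s = m * n_s / n
    expected_r = m * n_r / n
    result = LineagePairResult(
        loci, lineage, call.drug, count_s, count_r, expected_s, expected_r,
        None, False,
    )
    if m < min_carriers:
        result.tested = False
        return result
    if null == PROPORTIONAL_GOF:
        try:
            _, result.p_value = chisq_obs_vs_pred(count_s, expected_s, m)
        except UntestableError:
            result.tested = False
            return result
    elif null == FISHER_2X2:
        result.p_value = fisher_exact_2x2(count_s, n_s, count_r, n_r)
    else:
        raise ValueError(f"unknown null model {null!r}")
    result.significant = result.p_value is not None and result.p_value <= alpha
    return result


def subtract_and_retest(
    matrix: EventMatrix,
    call: ResponseCall,
    loci,
    significant_lineages,
    alpha: float = 0.05,
    min_prevalence: float = DEFAULT_MIN_PREVALENCE,
) -> ResidualAssociationResult:
    """Re-test a tuple's S/R association outside the interacting lineages.

    Every cell line whose lineage reached significance is excluded; the
    association is recomputed on the remainder with the module-default
    proportional goodness of fit. The result is unpowered (never an
    exception) when the remainder is empty or the event occurs in fewer
    than ``min_prevalence`` of both remaining groups.
    """
    loci = tuple(loci) if not isinstance(loci, str) else (loci,)
    removed = frozenset(significant_lineages)
    tested_lines = sorted(
        (call.sensitive | call.resistant) & set(matrix.cell_lines)
    )
    keep = [c for c in tested_lines if matrix.lineage[c] not in removed]
    if not keep:
        return ResidualAssociationResult(
            loci, call.drug, removed, 0, 0, 0, None, False, "none", False
        )
    sub = matrix.restrict_cell_lines(keep)
    in_s = np.array([c in call.sensitive for c in sub.cell_lines])
    carriers = _carrier_mask(sub, loci)
    n_s, n_r = int(in_s.sum()), int((~in_s).sum())
    count_s = int((carriers & in_s).sum())
    count_r = int((carriers & ~in_s).sum())
    m = count_s + count_r
    freq_s = count_s / n_s if n_s else 0.0
    freq_r = count_r / n_r if n_r else 0.0
    powered = m > 0 and (freq_s >= min_prevalence or freq_r >= min_prevalence)
    p_value = None
    direction = "none"
    significant = False
    if m > 0 and n_s > 0 and n_r > 0:
        expected_s = m * n_s / (n_s + n_r)
        try:
            _, p_value = chisq_obs_vs_pred(count_s, expected_s, m)
            significant = p_value <= alpha
            if significant:
                direction = "sensitive" if count_s > expected_s else "resistant"
        except UntestableError:
            p_value = None
    return ResidualAssociationResult(
        loci, call.drug, removed, len(keep), count_s, count_r,
        p_value, powered, direction, significant,
    )


def lineage_independence_summary(results, alphas=(0.05, 0.10),
                                 exclude_loci=None) -> pd.DataFrame:
    """Counts and fractions of lineage-independent co-events per alpha.

    Only powered residual results enter the denominator. An optional
    exclusion list removes tuples containing any of the given loci
    (e.g. ubiquitous tumor-suppressor events) before counting.
    """
    results = list(results)
    if not results:
        raise ValueError("no residual results to summarize")
    exclude = set(exclude_loci or ())
    kept = [r for r in results if not (set(r.loci) & exclude)]
    rows = []
    for alpha in alphas:
        powered = [r for r in kept if r.powered and r.p_value is not None]
        n_sig = sum(1 for r in powered if r.p_value <= alpha)
        rows.append(
            {
                "alpha": alpha,
                "n_powered": len(powered),
                "n_significant": n_sig,
                "fraction": n_sig / len(powered) if powered else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["alpha", "n_powered", "n_significant", "fraction"])


class LineageInteractionResults:
    """Per-tuple lineage tests plus the residual cross-validation."""

    def __init__(self, drug: str, pair_results, residual_results):
        self.drug = drug
        self.pair_results = pair_results
        self.residual_results = residual_results

    def pairs_frame(self) -> pd.DataFrame:
        rows = [
            {
                "drug": r.drug,
                "loci": "::".join(r.loci),
                "lineage": r.lineage,
                "count_S": r.count_S,
                "count_R": r.count_R,
                "expected_S": r.expected_S,
                "expected_R": r.expected_R,
                "p_value": r.p_value,
                "significant": r.significant,
                "tested": r.tested,
            }
            for r in self.pair_results
        ]
        return pd.DataFrame(
            rows,
            columns=["drug", "loci", "lineage", "count_S", "count_R",
                     "expected_S", "expected_R", "p_value", "significant", "tested"],
        )

    def residual_frame(self) -> pd.DataFrame:
        rows = [
            {
                "drug": r.drug,
                "loci": "::".join(r.loci),
                "removed_lineages": ",".join(sorted(r.removed_lineages)),
                "n_remaining": r.n_remaining,
                "count_S": r.count_S,
                "count_R": r.count_R,
                "p_value": r.p_value,
                "powered": r.powered,
                "direction": r.direction,
                "significant": r.significant,
            }
            for r in self.residual_results
        ]
        return pd.DataFrame(
            rows,
            columns=["drug", "loci", "removed_lineages", "n_remaining",
                     "count_S", "count_R", "p_value", "powered", "direction",
                     "significant"],
        )

    def summary(self, alphas=(0.05, 0.10)) -> str:
        table = lineage_independence_summary(self.residual_results, alphas=alphas)
        lines = [f"Lineage interaction: {self.drug}"]
        for row in table.itertuples(index=False):
            lines.append(
                f"  alpha={row.alpha:.2f}: {row.n_significant}/{row.n_powered} "
                f"co-events lineage-independent"
            )
        return "\n".join(lines)


class LineageInteraction:
    """Model of mutation x lineage interaction for one drug.

    For each supplied event tuple, ``fit()`` tests every co-occurring
    lineage, subtracts the significant ones, and re-tests the tuple on
    the remaining cell lines (the internal cross-validation loop).
    """

    def __init__(self, matrix: EventMatrix, call: ResponseCall,
                 null: str = PROPORTIONAL_GOF,
                 min_carriers: int = DEFAULT_MIN_CARRIERS):
        self.matrix = matrix
        self.call = call
        self.null = null
        self.min_carriers = min_carriers

    def fit(self, tuples, alpha: float = 0.05) -> LineageInteractionResults:
        matrix, call = self.matrix, self.call
        tested_lines = sorted(
            (call.sensitive | call.resistant) & set(matrix.cell_lines)
        )
        sub = matrix.restrict_cell_lines(tested_lines)
        lineages = sorted({sub.lineage[c] for c in sub.cell_lines})
        pair_results = []
        residual_results = []
        for loci in tuples:
            loci = tuple(loci) if not isinstance(loci, str) else (loci,)
            carriers = _carrier_mask(sub, loci)
            lin_of = np.array([sub.lineage[c] for c in sub.cell_lines])
            per_tuple = []
            for lin in lineages:
                if not (carriers & (lin_of == lin)).any():
                    continue
                per_tuple.append(
                    test_event_lineage_association(
                        matrix, call, loci, lin, null=self.null, alpha=alpha,
                        min_carriers=self.min_carriers,
                    )
                )
            pair_results.extend(per_tuple)
            significant = {r.lineage for r in per_tuple if r.significant}
            residual_results.append(
                subtract_and_retest(matrix, call, loci, significant, alpha=alpha)
            )
        return LineageInteractionResults(call.drug, pair_results, residual_results)
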
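"""Population-level co-event disequilibrium scan.

Enumerates the pair (or triple) co-event space over the panel, compares
observed co-occurrence counts with the independence-model prediction,
and classifies each observed tuple:

* ``co_selected`` — observed frequency above predicted, p <= alpha;
* ``partially_exclusive`` — observed between zero and predicted, p <= alpha;
* ``mutually_exclusive`` — never observed together (observed frequency
  exactly zero) despite a nonzero prediction, p <= alpha;
* ``none`` — no significant disequilibrium.

Co-selected pairs are candidates for cooperating drivers (and, by the
synthetic-lethality rationale, for co-targeting); mutually exclusive
pairs flag events that are redundant or incompatible in the same tumor.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import EventMatrix
from .exceptions import UntestableError
from .stats import PAPER_COMPAT, chisq_obs_vs_pred, multiple_testing, predicted_cooccurrence

CO_SELECTED = "co_selected"
PARTIALLY_EXCLUSIVE = "partially_exclusive"
MUTUALLY_EXCLUSIVE = "mutually_exclusive"
NONE = "none"


@dataclass
class CoEventResult:
    """One event tuple scored against the independence model."""

    loci: tuple[str, ...]
    n_total: int
    observed_count: int
    predicted_count_raw: float
    predicted_count: float
    observed_freq: float
    predicted_freq: float
    difference: float
    chi2: float | None = None
    p_value: float | None = None
    klass: str = NONE
    testable: bool = True

    @property
    def tuple_size(self) -> int:
        return len(self.loci)


def enumerate_event_tuples(matrix: EventMatrix, k: int, include_unobserved: bool = False):
    """Potential co-event space size and the event tuples with counts.

    Loci are first restricted to those with at least one event; the
    potential space is C(G, k) over the remaining G loci. By default
    only observed tuples (carried by at least one cell line) are
    returned, keyed by the canonically sorted locus tuple;
    ``include_unobserved=True`` returns every potential pair including
    zero-count ones (where mutual exclusivity lives) and is supported
    for k=2 only.
    """
    if k not in (2, 3):
        raise ValueError("tuple size k must be 2 or 3")
    reduced = matrix.drop_empty_loci()
    g = reduced.n_loci
    potential = math.comb(g, k)
    counts: dict[tuple[str, ...], int] = {}
    values = reduced.values
    if include_unobserved and k != 2:
        raise ValueError("include_unobserved is supported for pairs only")
    if k == 2:
        co = values.T.astype(np.int64) @ values.astype(np.int64)
        if include_unobserved:
            iu = np.triu_indices(g, 1)
            for i, j in zip(*iu):
                counts[(reduced.loci[i], reduced.loci[j])] = int(co[i, j])
        else:
            ii, jj = np.nonzero(np.triu(co, 1))
            for i, j in zip(ii, jj):
                counts[(reduced.loci[i], reduced.loci[j])] = int(co[i, j])
    else:
        for row in values:
            present = np.flatnonzero(row)
            for combo in itertools.combinations(present, 3):
                key = tuple(reduced.loci[j] for j in combo)
                counts[key] = counts.get(key, 0) + 1
    return potential, counts


def classify_disequilibrium(result: CoEventResult, alpha: float = 0.05) -> str:
    """Assign the disequilibrium class from counts and significance."""
    if not result.testable or result.p_value is None or result.p_value > alpha:
        return NONE
    if result.observed_count == 0:
        return MUTUALLY_EXCLUSIVE
    if result.observed_freq < result.predicted_freq:
        return PARTIALLY_EXCLUSIVE
    if result.observed_freq > result.predicted_freq:
        return CO_SELECTED
    return NONE


def score_tuple(loci, observed: int, marginals, n_total: int,
                rounding: str = PAPER_COMPAT, alpha: float = 0.05) -> CoEventResult:
    """Score one event tuple against the independence model."""
    e_raw, e = predicted_cooccurrence(marginals, n_total, rounding=rounding)
    obs_freq = observed / n_total
    pred_freq = e_raw / n_total
    res = CoEventResult(
        loci=tuple(loci),
        n_total=n_total,
        observed_count=observed,
        predicted_count_raw=e_raw,
        predicted_count=e,
        observed_freq=obs_freq,
        predicted_freq=pred_freq,
        difference=obs_freq - pred_freq,
    )
    try:
        res.chi2, res.p_value = chisq_obs_vs_pred(observed, e, n_total)
    except UntestableError:
        res.testable = False
        res.chi2 = res.p_value = None
    res.klass = classify_disequilibrium(res, alpha)
    return res


class CoEventScanResults:
    """Ranked disequilibrium-scan results with optional correction mask."""

    _COLUMNS = [
        "loci", "n_total", "observed_count", "predicted_count_raw",
        "predicted_count", "observed_freq", "predicted_freq", "difference",
        "chi2", "p_value", "class",
    ]

    def __init__(self, results, potential_space: int, k: int, alpha: float,
                 rounding: str, correction=None, dropped_zero_loci: bool = True):
        self.results = results
        self.potential_space = potential_space
        self.k = k
        self.alpha = alpha
        self.rounding = rounding
        self.correction = correction
        #: output metadata: loci with zero events were dropped before
        #: enumeration of the potential space
        self.dropped_zero_loci = dropped_zero_loci

    def __len__(self) -> int:
        return len(self.results)

    def __iter__(self):
        return iter(self.results)

    @property
    def testable(self):
        return [r for r in self.results if r.testable]

    def significant(self, klass: str | None = None):
        hits = [r for r in self.results if r.klass != NONE]
        if klass is not None:
            hits = [r for r in hits if r.klass == klass]
        return hits

    def by_difference(self):
        """Most negative difference first (exclusivity table order)."""
        return sorted(self.results, key=lambda r: (r.difference, r.loci))

    def by_p_value(self):
        return sorted(
            self.testable, key=lambda r: (r.p_value, r.difference, r.loci)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "loci": "::".join(r.loci),
                "n_total": r.n_total,
                "observed_count": r.observed_count,
                "predicted_count_raw": r.predicted_count_raw,
                "predicted_count": r.predicted_count,
                "observed_freq": r.observed_freq,
                "predicted_freq": r.predicted_freq,
                "difference": r.difference,
                "chi2": r.chi2,
                "p_value": r.p_value,
                "class": r.klass,
            }
            for r in self.by_difference()
        ]
        return pd.DataFrame(rows, columns=self._COLUMNS)

    def summary(self) -> str:
        counts = {
            k: sum(1 for r in self.results if r.klass == k)
            for k in (CO_SELECTED, PARTIALLY_EXCLUSIVE, MUTUALLY_EXCLUSIVE)
        }
        untestable = sum(1 for r in self.results if not r.testable)
        lines = [
            f"Co-event disequilibrium scan (k={self.k}, alpha={self.alpha}, "
            f"rounding={self.rounding})",
            f"  potential space      {self.potential_space}",
            f"  observed tuples      {len(self.results)}",
            f"  untestable           {untestable}",
            f"  co-selected          {counts[CO_SELECTED]}",
            f"  partially exclusive  {counts[PARTIALLY_EXCLUSIVE]}",
            f"  mutually exclusive   {counts[MUTUALLY_EXCLUSIVE]}",
        ]
        if self.correction is not None:
            lines.append(
                f"  {self.correction.method} correction (q={self.correction.q}): "
                f"{self.correction.n_significant} of "
                f"{self.correction.p_values.size} significant"
            )
        return "\n".join(lines)


class CoEventScan:
    """Model of pairwise (or triple) event disequilibrium in a panel.

    Parameters
    ----------
    matrix : EventMatrix
        Binary event matrix; loci with zero events are dropped before
        the potential space is enumerated (recorded in the results
        metadata).
    k : 2 or 3
    rounding : 'paper_compat' (default) rounds the predicted count to
        the nearest integer before the chi-square; 'exact' keeps it
        real-valued.
    """

    def __init__(self, matrix: EventMatrix, k: int = 2, rounding: str = PAPER_COMPAT):
        if k not in (2, 3):
            raise ValueError("tuple size k must be 2 or 3")
        self.matrix = matrix.drop_empty_loci()
        self.k = k
        self.rounding = rounding

    def fit(self, alpha: float = 0.05, correction: str | None = None,
            q: float = 0.05) -> CoEventScanResults:
        """Score every observed tuple; optionally attach a BH or
        Bonferroni mask over the testable tuples."""
        matrix = self.matrix
        n = matrix.n_cell_lines
        freqs = matrix.values.mean(axis=0)
        fmap = dict(zip(matrix.loci, freqs))
        # the full pair space is scored (zero-count pairs are the mutually
        # exclusive candidates); the cubic triple space is scored where observed
        potential, counts = enumerate_event_tuples(
            matrix, self.k, include_unobserved=(self.k == 2)
        )
        results = [
            score_tuple(loci, obs, [fmap[g] for g in loci], n,
                        rounding=self.rounding, alpha=alpha)
            for loci, obs in sorted(counts.items())
        ]
        corr = None
        if correction is not None:
            testable = [r for r in results if r.testable]
            corr = multiple_testing([r.p_value for r in testable], method=correction, q=q)
            for r, sig in zip(testable, corr.significant):
                if not sig:
                    r.klass = NONE
        return CoEventScanResults(
            results, potential, self.k, alpha, self.rounding, corr
        )


def population_disequilibrium_scan(matrix: EventMatrix, k: int = 2,
                                   alpha: float = 0.05,
                                   rounding: str = PAPER_COMPAT,
                                   correction: str | None = None) -> CoEventScanResults:
    """Functional wrapper: ``CoEventScan(matrix, k, rounding).fit(...)``."""
    return CoEventScan(matrix, k=k, rounding=rounding).fit(alpha=alpha, correction=correction)
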
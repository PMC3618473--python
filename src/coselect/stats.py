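"""Disequilibrium and association statistics.

The central statistic compares an observed co-event count O with the
count E predicted by the independence model (panel size times the
product of the constituent events' marginal frequencies) through a
two-cell goodness-of-fit chi-square over {co-event, no co-event}::

    chi2 = (O - E)^2 * (1/E + 1/(N - E)),   p = upper tail, 1 df

In *paper-compatible* mode the predicted count is rounded to the
nearest integer (half away from zero) before the test; the exact mode
keeps E real-valued. No continuity correction is applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

from .exceptions import UntestableError

PAPER_COMPAT = "paper_compat"
EXACT = "exact"
ROUNDING_MODES = (PAPER_COMPAT, EXACT)


def round_half_away(x: float) -> float:
    """Round to the nearest integer, halves away from zero."""
    return float(np.floor(np.abs(x) + 0.5) * np.sign(x))


def predicted_cooccurrence(marginal_freqs, n_total: int, rounding: str = PAPER_COMPAT):
    """Independence-model prediction for a co-event.

    Returns ``(E_raw, E)`` where ``E_raw = N * prod(marginal_freqs)``
    and E is its nearest-integer rounding in paper-compatible mode, or
    E_raw itself in exact mode. Triples use the three-way product.
    """
    if rounding not in ROUNDING_MODES:
        raise ValueError(f"unknown rounding mode {rounding!r}")
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    freqs = list(marginal_freqs)
    for f in freqs:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"marginal frequency {f} outside [0, 1]")
    e_raw = float(n_total * np.prod(freqs))
    e = round_half_away(e_raw) if rounding == PAPER_COMPAT else e_raw
    return e_raw, e


def chisq_obs_vs_pred(observed: float, expected: float, n_total: int):
    """Two-cell observed-vs-predicted goodness-of-fit chi-square (1 df).

    The two cells are {cell lines with the co-event, cell lines
    without}; the expected split is (E, N - E). Returns ``(chi2, p)``.
    Raises :class:`UntestableError` when E <= 0 or E >= N (the
    configuration is flagged untestable, never a silent NaN).
    """
    if not 0 <= observed <= n_total:
        raise ValueError("observed count outside [0, N]")
    if expected <= 0 or expected >= n_total:
        raise UntestableError(
            f"expected count {expected} outside (0, {n_total}); no test possible"
        )
    chi2 = (observed - expected) ** 2 * (1.0 / expected + 1.0 / (n_total - expected))
    p = float(_sps.chi2.sf(chi2, 1))
    return float(chi2), p


def fisher_exact_2x2(count_a: int, n_a: int, count_b: int, n_b: int) -> float:
    """Two-sided Fisher's exact p for [[count_a, n_a-count_a],
    [count_b, n_b-count_b]]."""
    table = [[count_a, n_a - count_a], [count_b, n_b - count_b]]
    return float(_sps.fisher_exact(table, alternative="two-sided")[1])


def chi2_contingency_2x2(count_a: int, n_a: int, count_b: int, n_b: int,
                         yates: bool = False):
    """Pearson chi-square on the 2x2 table (presence x group membership).

    Returns ``(chi2, p)``; raises :class:`UntestableError` on
    zero-variance tables (an all-zero margin).
    """
    table = np.array([[count_a, n_a - count_a], [count_b, n_b - count_b]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise UntestableError("zero margin in 2x2 table")
    chi2, p, _, _ = _sps.chi2_contingency(table, correction=yates)
    return float(chi2), float(p)


@dataclass
class MultipleTestingResult:
    """Outcome of a multiple-testing correction over a p-value vector."""

    p_values: np.ndarray
    method: str
    q: float
    significant: np.ndarray
    threshold: float

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())


def multiple_testing(p_values, method: str = "bh", q: float = 0.05) -> MultipleTestingResult:
    """Benjamini-Hochberg step-up (FDR q, default 5%), Bonferroni, or none.

    The BH significant set equals the step-up rule's rejection set; the
    Bonferroni threshold is q/m. ``method='none'`` thresholds raw
    p-values at q. Empty input gives an empty result.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return MultipleTestingResult(p, method, q, np.zeros(0, dtype=bool), float("nan"))
    if method == "bh":
        reject = multipletests(p, alpha=q, method="fdr_bh")[0]
        threshold = float(p[reject].max()) if reject.any() else 0.0
    elif method == "bonferroni":
        threshold = q / p.size
        reject = p <= threshold
    elif method == "none":
        threshold = q
        reject = p <= threshold
    else:
        raise ValueError(f"unknown correction method {method!r}")
    return MultipleTestingResult(p, method, q, reject, threshold)
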
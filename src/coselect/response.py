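"""Sensitive/resistant calling from rank-ordered growth-inhibition curves.

For each drug the growth-inhibition (GI) values of the tested cell lines
are rank ordered ascending and the curve is modelled as a high-order
polynomial on the rank axis rescaled to [0, 1]. The cutoff between the
sensitive minority (early, low-GI part of the curve) and the resistant
majority is the *inflection point*: the first rank at which the fitted
curve's second derivative attains its largest absolute value over the
interior of the rank grid. Viability-ratio screens additionally apply a
cap (default 0.78): the cutoff is whichever of the inflection GI and the
cap gives the greater sensitivity (the smaller GI value).

GI semantics: gIC50 in nM for dose-response screens, viable-cell
fraction after 72 h for viability screens; lower always means more
sensitive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_poly = np.polynomial.polynomial

logger = logging.getLogger(__name__)

GIC50_NM = "gic50_nm"
VIABILITY_RATIO = "viability_ratio"
ASSAY_MODES = (GIC50_NM, VIABILITY_RATIO)

#: Default viability-mode cap on the cutoff GI.
DEFAULT_VIABILITY_CAP = 0.78

#: Relative tolerance for "first instance" of the |f''| maximum.
FIRST_INSTANCE_RTOL = 1e-9


@dataclass
class DrugScreen:
    """Per-drug GI values over (a subset of) the panel's cell lines."""

    drug: str
    assay_mode: str
    gi: dict[str, float]

    def __post_init__(self) -> None:
        if self.assay_mode not in ASSAY_MODES:
            raise ValueError(f"unknown assay mode {self.assay_mode!r}")
        for cell, value in self.gi.items():
            if not np.isfinite(value):
                raise ValueError(f"non-finite GI value for {cell!r}")
            if self.assay_mode == VIABILITY_RATIO and value < 0:
                raise ValueError(f"negative viability ratio for {cell!r}")

    @property
    def n_tested(self) -> int:
        return len(self.gi)


def rank_order_profile(screen: DrugScreen, min_lines: int = 10):
    """Rank-order the screen's GI values ascending (ranks 0..n-1).

    Ties are broken by cell-line identifier. Returns a list of
    ``(rank, cell_line, gi)`` triples.
    """
    if screen.n_tested < min_lines:
        raise ValueError(
            f"{screen.drug}: {screen.n_tested} tested lines < minimum {min_lines}"
        )
    ordered = sorted(screen.gi.items(), key=lambda kv: (kv[1], kv[0]))
    return [(rank, cell, gi) for rank, (cell, gi) in enumerate(ordered)]


def fit_response_curve(gi_values, degree: int):
    """Least-squares polynomial fit of GI against rescaled rank.

    The rank axis is rescaled to [0, 1] before fitting; coefficients are
    reported on that axis (power basis, ascending order). An
    ill-conditioned (rank-deficient) fit triggers automatic degree
    reduction, logged at WARNING. Returns ``(coefficients, residual_norm,
    degree_used)``.
    """
    y = np.asarray(gi_values, dtype=float)
    n = len(y)
    if degree < 3:
        raise ValueError("polynomial degree must be >= 3")
    if degree >= n:
        raise ValueError("polynomial degree must be below the number of lines")
    x = np.arange(n) / (n - 1)
    deg = degree
    while True:
        coef, diag = _poly.polyfit(x, y, deg, full=True)
        resid, rank = diag[0], diag[1]
        if rank == deg + 1 or deg == 3:
            break
        logger.warning("ill-conditioned degree-%d fit; reducing to %d", deg, deg - 1)
        deg -= 1
    residual_norm = float(np.sqrt(resid[0])) if len(resid) else 0.0
    return coef, residual_norm, deg


def find_inflection_point(coefficients, n: int, degenerate_floor: float = 1e-8):
    """First rank at which |f''| attains its interior maximum.

    The analytic second derivative of the fitted polynomial is evaluated
    on the n rank positions of the rescaled axis; endpoints are excluded
    (polynomial edge artifacts). The returned index is the smallest rank
    whose |f''| is within relative tolerance 1e-9 of the interior
    maximum. The call is degenerate when the interior maximum falls
    below ``degenerate_floor`` (no curvature structure, e.g. a linear
    profile) or when the polynomial degree is below 3.
    """
    coefficients = np.asarray(coefficients, dtype=float)
    if len(coefficients) - 1 < 3:
        return 0, True
    x = np.arange(n) / (n - 1)
    second = _poly.polyval(x, _poly.polyder(coefficients, 2))
    interior = np.abs(second[1 : n - 1])
    peak = interior.max()
    if peak < degenerate_floor:
        return 0, True
    first = int(np.flatnonzero(interior >= peak * (1 - FIRST_INSTANCE_RTOL))[0]) + 1
    return first, False


@dataclass
class ResponseCall:
    """Results of a per-drug sensitive/resistant partition."""

    drug: str
    assay_mode: str
    ordered_cell_lines: list[str]
    ordered_gi: np.ndarray
    inflection_index: int
    cutoff_gi: float
    sensitive: set[str]
    resistant: set[str]
    degenerate: bool
    degree_used: int = 0
    coefficients: np.ndarray | None = None
    residual_norm: float = float("nan")

    @property
    def n_sensitive(self) -> int:
        return len(self.sensitive)

    @property
    def n_resistant(self) -> int:
        return len(self.resistant)

    @property
    def n_tested(self) -> int:
        return len(self.ordered_cell_lines)

    def group_of(self, cell_line: str) -> str:
        if cell_line in self.sensitive:
            return "S"
        if cell_line in self.resistant:
            return "R"
        raise KeyError(cell_line)

    def to_frame(self) -> pd.DataFrame:
        """Long-format calls table (one row per tested cell line)."""
        return pd.DataFrame(
            {
                "drug": self.drug,
                "cell_line": self.ordered_cell_lines,
                "group": [self.group_of(c) for c in self.ordered_cell_lines],
                "cutoff_gi": self.cutoff_gi,
                "inflection_index": self.inflection_index,
                "degenerate": self.degenerate,
            }
        )

    def summary(self) -> str:
        lines = [
            f"Response call: {self.drug} ({self.assay_mode})",
            f"  tested lines       {self.n_tested}",
            f"  polynomial degree  {self.degree_used}",
            f"  inflection index   {self.inflection_index}",
            f"  cutoff GI          {self.cutoff_gi:.6g}",
            f"  sensitive (S)      {self.n_sensitive}",
            f"  resistant (R)      {self.n_resistant}",
            f"  degenerate         {self.degenerate}",
        ]
        return "\n".join(lines)


def classify_sensitivity(screen: DrugScreen, inflection_index: int,
                         degenerate: bool = False, cap: float | None = None,
                         min_lines: int = 10, **fit_info) -> ResponseCall:
    """Partition tested lines into S/R at the inflection cutoff.

    gIC50 mode: sensitive lines are the ranks strictly before the
    inflection index. Viability mode with a cap: the cutoff is the
    smaller of the inflection GI and the cap. Lines sharing the cutoff
    GI value never straddle the boundary: all ties at the cutoff are
    assigned resistant (conservative).
    """
    profile = rank_order_profile(screen, min_lines=min_lines)
    cells = [cell for _, cell, _ in profile]
    gis = np.array([gi for _, _, gi in profile])
    if degenerate and cap is None:
        return ResponseCall(
            screen.drug, screen.assay_mode, cells, gis, 0, float("nan"),
            set(), set(cells), True, **fit_info,
        )
    if degenerate:
        cutoff = float(cap)
    else:
        cutoff = float(gis[inflection_index])
        if cap is not None:
            cutoff = min(cutoff, float(cap))
    sensitive = {c for c, g in zip(cells, gis) if g < cutoff}
    resistant = set(cells) - sensitive
    return ResponseCall(
        screen.drug, screen.assay_mode, cells, gis, inflection_index,
        cutoff, sensitive, resistant, False, **fit_info,
    )


class ResponseCurve:
    """Model of one drug's rank-ordered GI curve.

    ``fit()`` runs the full calling procedure — rank ordering, polynomial
    fit, inflection detection, S/R classification — and returns a
    :class:`ResponseCall`. Inflection points are determined independently
    per drug and per cohort; fit each cohort's screen separately.

    Parameters
    ----------
    screen : DrugScreen
    degree : polynomial degree (the curve is "high order"; default 9).
    cap : optional GI cap; defaults to 0.78 in viability mode, none in
        gIC50 mode.
    min_lines : minimum tested lines for a non-degenerate call.
    """

    def __init__(self, screen: DrugScreen, degree: int = 9,
                 cap: float | None = None, min_lines: int = 10):
        self.screen = screen
        self.degree = degree
        self.min_lines = min_lines
        if cap is None and screen.assay_mode == VIABILITY_RATIO:
            cap = DEFAULT_VIABILITY_CAP
        self.cap = cap

    def fit(self) -> ResponseCall:
        screen = self.screen
        if screen.n_tested < self.min_lines:
            # degenerate call, no partition
            cells = sorted(screen.gi, key=lambda c: (screen.gi[c], c))
            gis = np.array([screen.gi[c] for c in cells])
            return ResponseCall(
                screen.drug, screen.assay_mode, cells, gis, 0, float("nan"),
                set(), set(cells), True,
            )
        profile = rank_order_profile(screen, min_lines=self.min_lines)
        gis = np.array([gi for _, _, gi in profile])
        degree = min(self.degree, len(gis) - 1)
        coef, resid, degree_used = fit_response_curve(gis, degree)
        gi_range = float(gis.max() - gis.min())
        floor = max(1e-12, 1e-8 * max(gi_range, 1.0))
        idx, degenerate = find_inflection_point(coef, len(gis), degenerate_floor=floor)
        return classify_sensitivity(
            self.screen, idx, degenerate=degenerate, cap=self.cap,
            min_lines=self.min_lines, degree_used=degree_used,
            coefficients=coef, residual_norm=resid,
        )


def load_screen_table(path) -> list[DrugScreen]:
    """Read a screens TSV (columns cell_line, drug, gi_value, assay_mode)."""
    frame = pd.read_csv(path, sep="\t")
    required = {"cell_line", "drug", "gi_value", "assay_mode"}
    missing = required - set(frame.columns)
    if missing:
        from .exceptions import TableFormatError

        raise TableFormatError(f"{path}: missing required column(s) {sorted(missing)}")
    screens = []
    for (drug, mode), sub in sorted(frame.groupby(["drug", "assay_mode"], sort=True)):
        gi = dict(zip(sub["cell_line"], sub["gi_value"].astype(float)))
        screens.append(DrugScreen(drug, mode, gi))
    return screens


def write_calls_table(calls, path) -> None:
    """Write response calls (columns drug, cell_line, group, cutoff_gi,
    inflection_index, degenerate)."""
    pd.concat([c.to_frame() for c in calls], ignore_index=True).to_csv(
        path, sep="\t", index=False
    )
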
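"""Synthetic cell-line panels with known ground truth.

Generates event matrices with planted per-locus marginals, pairwise
coupling and lineage enrichment, plus drug screens with planted
single-event, epistatic, lineage and lineage-conditional effects, so
every pipeline stage can be validated without any external download.

The coupling parameter follows the independence model directly: for a
planted pair, ``P(A and B) = lambda * f_A * f_B`` — lambda 1 is
independence, lambda 0 strict mutual exclusivity, lambda > 1
co-selection. Couplings are restricted to disjoint pairs so the joint
law stays exact. Lineage enrichment multiplies the odds of a locus
within a lineage (clipped to the open unit interval) and is applied
before coupling, so enriched loci may not take part in couplings.

Drug screens follow ``GI = baseline * prod(applicable shifts) *
exp(noise)`` with log-normal baselines: gIC50 baselines have median
~650 nM (the scale of reported inflection cutoffs) and viability
baselines sit near 0.92 so the 0.78 cap rule is exercised. Sensitizing
shifts are < 1 (lower GI = more sensitive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .catalog import EventMatrix, LineageMap
from .exceptions import InfeasibleCouplingError
from .response import GIC50_NM, VIABILITY_RATIO, DrugScreen

DEFAULT_N_CELL_LINES = 300
DEFAULT_N_LOCI = 260
DEFAULT_N_LINEAGES = 20

#: Default gIC50 baseline (nM): log-normal median echoing reported cutoffs.
GIC50_BASELINE_MEDIAN = 650.0
GIC50_BASELINE_LOG_SD = 0.8
#: Default viability baseline: bulk concentrated just above the 0.78 cap.
VIABILITY_BASELINE_MEDIAN = 0.92
VIABILITY_BASELINE_LOG_SD = 0.2


@dataclass
class DrugEffectSpec:
    """Planted response structure for one simulated drug.

    ``single_effects`` maps locus -> multiplicative GI shift applied to
    carriers; ``epistatic_effects`` maps a locus tuple -> shift applied
    only when *all* events are present; ``lineage_effects`` maps lineage
    -> shift; ``interaction_effects`` maps (locus, lineage) -> shift
    applied only to carriers of the locus inside that lineage (a
    genuinely lineage-confined effect).
    """

    drug: str
    assay_mode: str = GIC50_NM
    baseline_median: float | None = None
    baseline_log_sd: float | None = None
    single_effects: dict = field(default_factory=dict)
    epistatic_effects: dict = field(default_factory=dict)
    lineage_effects: dict = field(default_factory=dict)
    interaction_effects: dict = field(default_factory=dict)
    noise_sd: float = 0.1
    fraction_tested: float = 1.0

    def __post_init__(self) -> None:
        if self.baseline_median is None:
            self.baseline_median = (
                VIABILITY_BASELINE_MEDIAN if self.assay_mode == VIABILITY_RATIO
                else GIC50_BASELINE_MEDIAN
            )
        if self.baseline_log_sd is None:
            self.baseline_log_sd = (
                VIABILITY_BASELINE_LOG_SD if self.assay_mode == VIABILITY_RATIO
                else GIC50_BASELINE_LOG_SD
            )
        for shift in (
            *self.single_effects.values(),
            *self.epistatic_effects.values(),
            *self.lineage_effects.values(),
            *self.interaction_effects.values(),
        ):
            if shift <= 0:
                raise ValueError("effect shifts must be positive")
        if not 0.0 < self.fraction_tested <= 1.0:
            raise ValueError("fraction_tested must be in (0, 1]")


@dataclass
class PanelConfig:
    """Ground-truth description of a synthetic panel."""

    n_cell_lines: int = DEFAULT_N_CELL_LINES
    n_loci: int = DEFAULT_N_LOCI
    lineages: list[str] | None = None
    lineage_weights: list[float] | None = None
    marginal_freqs: list[float] | None = None
    couplings: list[tuple[str, str, float]] = field(default_factory=list)
    lineage_enrichment: list[tuple[str, str, float]] = field(default_factory=list)
    drugs: list[DrugEffectSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lineages is None:
            self.lineages = [f"lineage{i + 1:02d}" for i in range(DEFAULT_N_LINEAGES)]
        if self.lineage_weights is None:
            self.lineage_weights = [1.0 / len(self.lineages)] * len(self.lineages)
        if len(self.lineage_weights) != len(self.lineages):
            raise ValueError("lineage_weights length must match lineages")
        coupled = [g for a, b, _ in self.couplings for g in (a, b)]
        if len(coupled) != len(set(coupled)):
            raise ValueError("couplings must involve disjoint loci")
        enriched = {g for g, _, _ in self.lineage_enrichment}
        if enriched & set(coupled):
            raise ValueError("a locus may not be both coupled and lineage-enriched")

    def locus_names(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_loci)]

    def cell_line_names(self) -> list[str]:
        return [f"CL{i + 1:04d}" for i in range(self.n_cell_lines)]


@dataclass
class PanelTruth:
    """The planted structure implied by a generated panel."""

    marginal_freqs: dict[str, float]
    couplings: list[tuple[str, str, float]]
    lineage_enrichment: list[tuple[str, str, float]]
    lineage_of: dict[str, str]
    drugs: list[DrugEffectSpec] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "couplings": [list(c) for c in self.couplings],
            "lineage_enrichment": [list(e) for e in self.lineage_enrichment],
            "drugs": [
                {
                    "drug": d.drug,
                    "assay_mode": d.assay_mode,
                    "single_effects": dict(d.single_effects),
                    "epistatic_effects": {
                        "::".join(k): v for k, v in d.epistatic_effects.items()
                    },
                    "lineage_effects": dict(d.lineage_effects),
                    "interaction_effects": {
                        f"{g}::{lin}": v for (g, lin), v in d.interaction_effects.items()
                    },
                }
                for d in self.drugs
            ],
        }


def default_marginals(n_loci: int, rng: np.random.Generator) -> np.ndarray:
    """Realistic per-locus event frequencies: mostly rare, a heavy tail.

    Beta(1.1, 25) clipped to [0.005, 0.6]; mean ~0.04, matching the
    sparsity of curated panels (hundreds of loci, ~10 events per line).
    """
    return np.clip(rng.beta(1.1, 25.0, n_loci), 0.005, 0.6)


def _coupled_pair_sample(rng, n, f_a, f_b, lam, pair_name):
    p11 = lam * f_a * f_b
    p10 = f_a - p11
    p01 = f_b - p11
    p00 = 1.0 - p11 - p10 - p01
    probs = np.array([p11, p10, p01, p00])
    if (probs < -1e-12).any() or p11 > min(f_a, f_b) + 1e-12:
        raise InfeasibleCouplingError(
            f"coupling {pair_name}: lambda={lam} incompatible with "
            f"marginals ({f_a:.3f}, {f_b:.3f})"
        )
    cell = rng.choice(4, size=n, p=np.clip(probs, 0, None) / probs.clip(0, None).sum())
    return (cell == 0) | (cell == 1), (cell == 0) | (cell == 2)


def generate_event_matrix(config: PanelConfig, rng: np.random.Generator | None = None):
    """Sample a panel's event matrix under the configured ground truth.

    Returns ``(EventMatrix, PanelTruth)``. A fixed seed yields an
    identical matrix.
    """
    rng = rng or np.random.default_rng(config.seed)
    n, loci = config.n_cell_lines, config.locus_names()
    cells = config.cell_line_names()
    marginals = (
        np.asarray(config.marginal_freqs, dtype=float)
        if config.marginal_freqs is not None
        else default_marginals(config.n_loci, rng)
    )
    if len(marginals) != config.n_loci:
        raise ValueError("marginal_freqs length must match n_loci")
    if ((marginals <= 0) | (marginals >= 1)).any():
        raise ValueError("marginals must lie in (0, 1)")
    lin_labels = rng.choice(
        config.lineages, size=n, p=np.asarray(config.lineage_weights) / np.sum(config.lineage_weights)
    )
    lineage_map = LineageMap({c: str(l) for c, l in zip(cells, lin_labels)})
    fmap = dict(zip(loci, marginals))
    enrich = {(g, lin): mult for g, lin, mult in config.lineage_enrichment}

    values = np.zeros((n, len(loci)), dtype=bool)
    coupled = {g for a, b, _ in config.couplings for g in (a, b)}
    for j, g in enumerate(loci):
        if g in coupled:
            continue
        f = fmap[g]
        probs = np.full(n, f)
        for (gg, lin), mult in enrich.items():
            if gg == g:
                odds = mult * f / (1.0 - f)
                probs[lin_labels == lin] = np.clip(odds / (1.0 + odds), 1e-9, 1 - 1e-9)
        values[:, j] = rng.random(n) < probs
    locus_index = {g: j for j, g in enumerate(loci)}
    for a, b, lam in config.couplings:
        col_a, col_b = _coupled_pair_sample(rng, n, fmap[a], fmap[b], lam, f"{a}::{b}")
        values[:, locus_index[a]] = col_a
        values[:, locus_index[b]] = col_b

    matrix = EventMatrix(cells, loci, values, lineage_map)
    truth = PanelTruth(
        marginal_freqs=fmap,
        couplings=list(config.couplings),
        lineage_enrichment=list(config.lineage_enrichment),
        lineage_of=dict(lineage_map),
        drugs=list(config.drugs),
    )
    return matrix, truth


def generate_drug_screens(matrix: EventMatrix, truth: PanelTruth,
                          specs, rng: np.random.Generator) -> list[DrugScreen]:
    """Sample per-drug GI vectors under the planted effect structure."""
    screens = []
    for spec in specs:
        n = matrix.n_cell_lines
        log_gi = (
            np.log(spec.baseline_median)
            + rng.normal(0.0, spec.baseline_log_sd, n)
        )
        shifts = np.ones(n)
        for locus, shift in spec.single_effects.items():
            shifts[matrix.locus_column(locus)] *= shift
        for loci, shift in spec.epistatic_effects.items():
            mask = np.ones(n, dtype=bool)
            for g in loci:
                mask &= matrix.locus_column(g)
            shifts[mask] *= shift
        lineages = np.array([matrix.lineage[c] for c in matrix.cell_lines])
        for lin, shift in spec.lineage_effects.items():
            shifts[lineages == lin] *= shift
        for (locus, lin), shift in spec.interaction_effects.items():
            shifts[matrix.locus_column(locus) & (lineages == lin)] *= shift
        gi = np.exp(log_gi + rng.normal(0.0, spec.noise_sd, n)) * shifts
        tested = np.ones(n, dtype=bool)
        if spec.fraction_tested < 1.0:
            tested = rng.random(n) < spec.fraction_tested
        values = {
            c: float(g)
            for c, g, t in zip(matrix.cell_lines, gi, tested)
            if t
        }
        screens.append(DrugScreen(spec.drug, spec.assay_mode, values))
    return screens


@dataclass
class Panel:
    """A generated panel: events, screens, lineages and ground truth."""

    matrix: EventMatrix
    screens: list[DrugScreen]
    lineage: LineageMap
    truth: PanelTruth


def generate_panel(config: PanelConfig, out_dir=None) -> Panel:
    """Generate a full panel; optionally write the four TSV/YAML files
    in the dialects the loaders read (mutations, screens, lineage,
    truth)."""
    rng = np.random.default_rng(config.seed)
    matrix, truth = generate_event_matrix(config, rng)
    screens = generate_drug_screens(matrix, truth, config.drugs, rng)
    panel = Panel(matrix, screens, matrix.lineage, truth)
    if out_dir is not None:
        write_panel(panel, out_dir)
    return panel


def write_panel(panel: Panel, out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    events = panel.matrix.to_events_frame()
    events["mutated"] = 1
    paths["mutations"] = out / "mutations.tsv"
    events.to_csv(paths["mutations"], sep="\t", index=False)

    rows = []
    for screen in panel.screens:
        for cell in sorted(screen.gi):
            rows.append((cell, screen.drug, screen.gi[cell], screen.assay_mode))
    import pandas as pd

    paths["screens"] = out / "screens.tsv"
    pd.DataFrame(rows, columns=["cell_line", "drug", "gi_value", "assay_mode"]).to_csv(
        paths["screens"], sep="\t", index=False
    )

    paths["lineage"] = out / "lineage.tsv"
    pd.DataFrame(
        sorted(panel.lineage.items()), columns=["cell_line", "lineage"]
    ).to_csv(paths["lineage"], sep="\t", index=False)

    paths["truth"] = out / "truth.yaml"
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(panel.truth.to_dict(), fh, sort_keys=True)
    return paths


def two_regime_profile(n: int, knee_fraction: float, mu1: float, mu2: float,
                       sigma: float, rng: np.random.Generator,
                       drug: str = "synthetic", assay_mode: str = GIC50_NM):
    """A rank-ordered two-regime GI profile with a planted knee.

    The first ``round(knee_fraction * n)`` lines sit on the low plateau
    mu1, the rest on the high plateau mu2, with additive Gaussian noise
    sigma (sigma << mu2 - mu1 for a well-defined knee). Returns
    ``(DrugScreen, knee_rank)``.
    """
    k = int(round(knee_fraction * n))
    base = np.concatenate([np.full(k, mu1), np.full(n - k, mu2)])
    gi = base + rng.normal(0.0, sigma, n)
    cells = [f"CL{i + 1:04d}" for i in range(n)]
    return DrugScreen(drug, assay_mode, dict(zip(cells, gi))), k
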
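"""Stage orchestration and report writing.

Runs the stage sequence simulate -> call-response -> scan-coevents ->
drug-assoc -> lineage -> cluster under one config, records a manifest
(seed, effective parameters, row counts), and writes the report tables.
Every output row carries the counts needed to recompute its own
p-value, so the reports are self-verifiable.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import DrugAssociation
from .catalog import EventMatrix, LineageMap, load_lineage_table, load_mutation_table, build_event_matrix
from .clustering import hierarchical_cluster, scale_profiles
from .coevents import CoEventScan
from .lineage import LineageInteraction
from .response import ResponseCurve, load_screen_table
from .simulate import DrugEffectSpec, PanelConfig, default_marginals, generate_panel
from .stats import PAPER_COMPAT

logger = logging.getLogger(__name__)

STAGES = ("simulate", "call_response", "scan_coevents", "drug_assoc", "lineage", "cluster")


@dataclass
class PipelineConfig:
    """Effective parameter set for one pipeline run."""

    mutations: str | None = None
    lineage: str | None = None
    screens: str | None = None
    out_dir: str = "results"
    seed: int = 0
    simulate: bool = True
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    degree: int = 9
    cap: float | None = None
    min_lines: int = 10
    alpha: float = 0.05
    fold: float = 1.5
    min_prevalence: float = 0.12
    min_count: int = 4
    rounding: str = PAPER_COMPAT
    correction: str | None = None
    tuple_sizes: tuple = (1, 2)
    max_lineage_tuples: int = 30

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "tuple_sizes" in raw:
            raw["tuple_sizes"] = tuple(raw["tuple_sizes"])
        cfg = cls(**raw)
        return cfg

    def to_dict(self) -> dict:
        return {
            "mutations": self.mutations,
            "lineage": self.lineage,
            "screens": self.screens,
            "out_dir": self.out_dir,
            "seed": self.seed,
            "simulate": self.simulate,
            "stages": dict(self.stages),
            "degree": self.degree,
            "cap": self.cap,
            "min_lines": self.min_lines,
            "alpha": self.alpha,
            "fold": self.fold,
            "min_prevalence": self.min_prevalence,
            "min_count": self.min_count,
            "rounding": self.rounding,
            "correction": self.correction,
            "tuple_sizes": list(self.tuple_sizes),
            "max_lineage_tuples": self.max_lineage_tuples,
        }


def default_panel_config(seed: int = 0) -> PanelConfig:
    """Demonstration panel: planted couplings, a single-event drug and
    an epistatic viability drug, with detectable marginals."""
    rng = np.random.default_rng(seed)
    marginals = default_marginals(60, rng)
    # detectable structure on the first loci
    marginals[:8] = [0.25, 0.25, 0.20, 0.20, 0.15, 0.75, 0.75, 0.30]
    drugs = [
        DrugEffectSpec(
            "drug01", "viability_ratio", single_effects={"G0005": 0.6},
            noise_sd=0.05,
        ),
        DrugEffectSpec(
            "drug02", "viability_ratio",
            epistatic_effects={("G0006", "G0007"): 0.83},
            baseline_log_sd=0.2, noise_sd=0.05,
        ),
    ]
    return PanelConfig(
        n_cell_lines=300,
        n_loci=60,
        marginal_freqs=list(marginals),
        couplings=[("G0001", "G0002", 0.0), ("G0003", "G0004", 3.0)],
        lineage_enrichment=[("G0008", "lineage01", 8.0)],
        drugs=drugs,
        seed=seed,
    )


def format_report_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Render floats with 9 decimal places; +inf as the literal 'inf'."""

    def fmt(x):
        if isinstance(x, float):
            if math.isinf(x):
                return "inf" if x > 0 else "-inf"
            if math.isnan(x):
                return "NA"
            return f"{x:.9f}"
        if x is None:
            return "NA"
        return x

    out = frame.copy()
    for col in out.columns:
        if out[col].dtype == object or pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(fmt)
    return out


def write_reports(tables: dict[str, pd.DataFrame], out_dir) -> dict[str, Path]:
    """Write the report TSVs with the documented column contracts.

    Fails before any partial file when the output directory cannot be
    created or written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not os.access(out, os.W_OK):
        raise PermissionError(f"output directory {out} is not writable")
    paths = {}
    for name, frame in tables.items():
        paths[name] = out / f"{name}.tsv"
        format_report_frame(frame).to_csv(paths[name], sep="\t", index=False)
    return paths


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order.

    Returns the run manifest; also writes the report tables and the
    manifest itself under ``config.out_dir``. A stage failure is
    recorded in the manifest and skips downstream stages.
    """
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": config.to_dict(),
        "stages": {},
        "row_counts": {},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    tables: dict[str, pd.DataFrame] = {}
    matrix: EventMatrix | None = None
    screens = []
    failed = False

    def record(stage, status, **extra):
        manifest["stages"][stage] = {"status": status, **extra}
        logger.info("stage %s: %s", stage, status)

    logger.info("effective parameters: %s", manifest["parameters"])

    # -- inputs ----------------------------------------------------------
    try:
        if config.simulate and config.stages.get("simulate", True):
            panel = generate_panel(default_panel_config(config.seed))
            matrix, screens = panel.matrix, panel.screens
            record("simulate", "ok")
        else:
            lineage = load_lineage_table(config.lineage) if config.lineage else LineageMap()
            mutations = load_mutation_table(config.mutations)
            matrix = build_event_matrix(mutations, [], lineage=lineage)
            screens = load_screen_table(config.screens)
            record("simulate", "skipped")
    except Exception as exc:  # noqa: BLE001
        record("simulate", f"failed: {exc}")
        failed = True

    # -- response calling ------------------------------------------------
    calls = []
    if not failed and config.stages.get("call_response", True):
        try:
            for screen in screens:
                calls.append(
                    ResponseCurve(
                        screen, degree=config.degree, cap=config.cap,
                        min_lines=config.min_lines,
                    ).fit()
                )
            tables["calls"] = pd.concat(
                [c.to_frame() for c in calls], ignore_index=True
            )
            record("call_response", "ok", n_drugs=len(calls))
        except Exception as exc:  # noqa: BLE001
            record("call_response", f"failed: {exc}")
            failed = True

    # -- population disequilibrium scan ----------------------------------
    if not failed and config.stages.get("scan_coevents", True):
        try:
            scan = CoEventScan(matrix, k=2, rounding=config.rounding).fit(
                alpha=config.alpha, correction=config.correction
            )
            tables["coevents"] = scan.to_frame()
            record("scan_coevents", "ok", potential_space=scan.potential_space,
                   observed=len(scan))
        except Exception as exc:  # noqa: BLE001
            record("scan_coevents", f"failed: {exc}")
            failed = True

    # -- per-drug association --------------------------------------------
    assoc_results = {}
    if not failed and config.stages.get("drug_assoc", True):
        try:
            frames = []
            for call in calls:
                if call.degenerate:
                    continue
                res = DrugAssociation(
                    matrix, call, tuple_sizes=config.tuple_sizes,
                    min_prevalence=config.min_prevalence,
                    min_count=config.min_count, fold=config.fold,
                ).fit(alpha=config.alpha)
                assoc_results[call.drug] = res
                frames.append(res.to_frame())
            tables["drug_assoc"] = (
                pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
            )
            record("drug_assoc", "ok", n_drugs=len(frames))
        except Exception as exc:  # noqa: BLE001
            record("drug_assoc", f"failed: {exc}")
            failed = True

    # -- lineage interaction ----------------------------------------------
    if not failed and config.stages.get("lineage", True):
        try:
            pair_frames, residual_frames = [], []
            for call in calls:
                if call.degenerate or call.drug not in assoc_results:
                    continue
                top = assoc_results[call.drug].top(alpha=config.alpha)
                tuples = [r.loci for r in top][: config.max_lineage_tuples]
                if not tuples:
                    continue
                res = LineageInteraction(matrix, call).fit(tuples, alpha=config.alpha)
                pair_frames.append(res.pairs_frame())
                residual_frames.append(res.residual_frame())
            tables["lineage_assoc"] = (
                pd.concat(pair_frames, ignore_index=True) if pair_frames else pd.DataFrame()
            )
            tables["residual_assoc"] = (
                pd.concat(residual_frames, ignore_index=True)
                if residual_frames
                else pd.DataFrame()
            )
            record("lineage", "ok")
        except Exception as exc:  # noqa: BLE001
            record("lineage", f"failed: {exc}")
            failed = True

    # -- clustering --------------------------------------------------------
    if not failed and config.stages.get("cluster", True):
        try:
            gi = pd.DataFrame(
                {s.drug: pd.Series(s.gi) for s in screens}
            )
            scaled = scale_profiles(gi)
            if len(scaled.drugs) >= 2:
                tree = hierarchical_cluster(scaled, axis="drugs")
                tables["clusters"] = pd.DataFrame(
                    {
                        "merge": range(len(tree.merges)),
                        "left": tree.merges[:, 0].astype(int),
                        "right": tree.merges[:, 1].astype(int),
                        "height": tree.merges[:, 2],
                        "size": tree.merges[:, 3].astype(int),
                    }
                )
                record("cluster", "ok", leaf_order=tree.leaf_order)
            else:
                record("cluster", "skipped: fewer than two drug profiles")
        except Exception as exc:  # noqa: BLE001
            record("cluster", f"failed: {exc}")
            failed = True

    paths = write_reports(tables, config.out_dir)
    manifest["row_counts"] = {name: int(len(tables[name])) for name in tables}
    manifest["outputs"] = {k: str(v) for k, v in paths.items()}
    manifest["status"] = "failed" if failed else "ok"
    with open(Path(config.out_dir) / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
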
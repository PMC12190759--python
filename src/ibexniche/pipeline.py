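"""End-to-end orchestration: simulate/measure -> phenotype -> lesions ->
niches -> models, with config round-tripping and a run manifest."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import lesions as lesions_mod
from . import models as models_mod
from . import niches as niches_mod
from . import phenotype as phenotype_mod
from . import synthdata as synthdata_mod

logger = logging.getLogger(__name__)

REQUIRED_CELL_COLUMNS = ["sample_id", "genotype", "cell_id", "x_um", "y_um",
                         "nucleus_area_um2"]


@dataclass
class RunConfig:
    """Parameters of one pipeline run; round-trippable via YAML."""

    input_mode: str = "simulate"            # simulate | cell-table
    cell_table_path: str | None = None
    panel_path: str | None = None
    out_dir: str = "runs"
    seed: int = 0
    # stage parameters
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    alpha: float = 0.05
    min_matched: int = 20
    triage_k: int = 5
    lesion_radius_um: float = 200.0
    pseudocount: float = 1.0
    n_modules: int = 2
    grouping_fraction: str = "random_intercept"
    grouping_size: str = "fixed_sample"
    grouping_pc1: str = "random_intercept"
    size_scale: str = "log"

    def __post_init__(self):
        if self.input_mode not in ("simulate", "cell-table"):
            raise ValueError(f"unknown input_mode {self.input_mode!r}")
        if self.input_mode == "cell-table" and not self.cell_table_path:
            raise ValueError("cell-table mode needs cell_table_path")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def stage_seed(root_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the root seed (documented fan-out:
    SeedSequence spawned from [root, crc32(stage name)])."""
    import zlib

    ss = np.random.SeedSequence([root_seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def validate_cell_table(path) -> dict:
    """Schema check for externally supplied cell tables."""
    messages, ok = [], True
    try:
        df = pd.read_csv(path) if str(path).endswith(".csv") else pd.read_parquet(path)
    except Exception as e:  # unreadable file
        raise IOError(f"cannot read cell table {path}: {e}") from e
    missing = [c for c in REQUIRED_CELL_COLUMNS if c not in df.columns]
    if missing:
        ok = False
        messages.append(f"missing required columns: {missing}")
    mfi_cols = [c for c in df.columns if c.startswith("mfi_")]
    if not mfi_cols:
        ok = False
        messages.append("no mfi_<marker> columns found")
    for c in mfi_cols:
        if (df[c] < 0).any():
            ok = False
            messages.append(f"negative MFI values in column {c}")
    if "cell_id" in df.columns and df["cell_id"].duplicated().any():
        dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
        ok = False
        messages.append(f"duplicated cell id: {dup}")
    for c in ("x_um", "y_um"):
        if c in df.columns and len(df) and (df[c].abs() > 1e6).any():
            ok = False
            messages.append(f"{c} outside a plausible um range (|x| > 1e6)")
    return {"ok": ok, "messages": messages, "n_rows": len(df)}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order, writing each stage's outputs as it goes.

    Returns the run manifest (also written to ``manifest.json``): seed,
    parameter values, per-stage row counts, model summaries, warnings.
    """
    from . import __version__

    run_dir = Path(config.out_dir) / time.strftime("run_%Y%m%d_%H%M%S")
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")
    manifest: dict = {
        "version": __version__, "seed": config.seed,
        "config": dataclasses.asdict(config), "stages": {}, "warnings": [],
    }

    panel = (phenotype_mod.PhenotypePanel.from_yaml(config.panel_path)
             if config.panel_path else phenotype_mod.default_panel())

    # --- input stage ------------------------------------------------------
    truth = None
    if config.input_mode == "simulate":
        sim_cfg = synthdata_mod.SimConfig(
            marker_panel=panel, seed=stage_seed(config.seed, "simulate"),
            **config.sim,
        )
        cells, truth = synthdata_mod.simulate_cells(sim_cfg)
        synthdata_mod.write_cell_table(cells, run_dir / "cells.csv",
                                       run_dir / "cells.parquet")
        synthdata_mod.write_ground_truth(truth, run_dir / "truth_cells.csv",
                                         run_dir / "truth_lesions.csv")
    else:
        report = validate_cell_table(config.cell_table_path)
        if not report["ok"]:
            raise ValueError(f"cell table failed validation: {report['messages']}")
        p = str(config.cell_table_path)
        cells = pd.read_csv(p) if p.endswith(".csv") else pd.read_parquet(p)
    manifest["stages"]["cells"] = {"rows": len(cells)}

    # --- phenotype --------------------------------------------------------
    calls, report = phenotype_mod.classify_cells(
        cells, panel, alpha=config.alpha, min_matched=config.min_matched,
        triage_k=config.triage_k, seed=stage_seed(config.seed, "phenotype"),
    )
    synthdata_mod.write_cell_table(calls, run_dir / "phenotype_calls.csv")
    stage_counts = calls["stage"].value_counts().to_dict()
    manifest["stages"]["phenotype"] = {
        "rows": len(calls), "stage_counts": stage_counts,
        "fraction_unmatched_excluded": report["fraction_unmatched_excluded"],
        "thresholds": {k: float(v) for k, v in report["thresholds"].items()},
    }

    # --- lesions ----------------------------------------------------------
    les = lesions_mod.build_lesions(cells, calls, panel.tumor_type_name,
                                    radius=config.lesion_radius_um)
    les = lesions_mod.assign_immune(cells, calls, les, panel.tumor_type_name,
                                    radius=config.lesion_radius_um)
    immune_types = [t for t in panel.immune_types()
                    if t not in panel.exclusion_list]
    lesion_df = lesions_mod.lesion_table(les, immune_types)
    lesion_df.to_csv(run_dir / "lesions.csv", index=False)
    lesions_mod.membership_edges(les).to_csv(run_dir / "lesion_members.csv",
                                             index=False)
    summaries = lesions_mod.classify_and_summarize(les)
    summaries["per_sample"].to_csv(run_dir / "lesion_summary_per_sample.csv",
                                   index=False)
    summaries["per_genotype"].to_csv(run_dir / "lesion_summary_per_genotype.csv",
                                     index=False)
    manifest["stages"]["lesions"] = {
        "rows": len(lesion_df),
        "per_genotype": summaries["per_genotype"].to_dict("records"),
    }

    # --- niches -----------------------------------------------------------
    table = niches_mod.build_niche_table(lesion_df, pseudocount=config.pseudocount)
    modules = niches_mod.analyze_niches(table, n_modules=config.n_modules)
    table.standardized.to_csv(run_dir / "niche_standardized_clr.csv")
    modules.correlation.to_csv(run_dir / "niche_correlation.csv")
    modules.modules.to_csv(run_dir / "niche_modules.csv")
    modules.loadings.to_csv(run_dir / "niche_loadings.csv")
    modules.scores.to_csv(run_dir / "niche_scores.csv", index=False)
    niches_mod.plot_niches(modules, run_dir / "niche_heatmap.svg",
                           run_dir / "niche_pca.svg")
    manifest["stages"]["niches"] = {
        "rows": len(table.counts),
        "modules": modules.modules.to_dict(),
        "pc1_variance_explained": float(modules.variance_explained[0]),
    }

    # --- models -----------------------------------------------------------
    cells_flagged = cells.merge(calls[["cell_id", "assigned_type"]], on="cell_id")
    cells_flagged["is_tumor"] = cells_flagged["assigned_type"] == panel.tumor_type_name
    fits = {}
    fits["tumor_fraction"] = models_mod.fit_tumor_fraction(
        cells_flagged, grouping_mode=config.grouping_fraction)
    fits["lesion_size"] = models_mod.fit_lesion_size(
        lesion_df, grouping_mode=config.grouping_size,
        seed=stage_seed(config.seed, "ztnb"))
    fits["pc1"] = models_mod.fit_pc1(
        modules.scores, grouping_mode=config.grouping_pc1,
        size_scale=config.size_scale)
    coef_tables = pd.concat([f.to_frame() for f in fits.values()])
    coef_tables.to_csv(run_dir / "model_coefficients.csv", index=False)
    manifest["stages"]["models"] = {
        name: {
            "genotype_coef": (f.coef("genotype_ko")
                              if "genotype_ko" in f.params.index else None),
            "genotype_p": (f.pvalue("genotype_ko")
                           if "genotype_ko" in f.params.index else None),
            "loglik": f.loglik, "converged": f.converged,
            "grouping": f.grouping,
        }
        for name, f in fits.items()
    }

    manifest["run_dir"] = str(run_dir)
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest
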
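"""End-to-end orchestration: cohort on disk -> sweeps, tables, figures.

``run_analysis`` loads the clinical table, computes per-patient enhancement
maps and FTV surfaces for every available visit, derives the three survival
predictors per grid cell, runs a Cox sweep per (subset x predictor), selects
optimized cells, renders heat maps, and writes:

- ``sweeps/<subset>_<predictor>.csv`` — the full per-cell sweep table;
- ``comparison.csv`` — one optimized-vs-default row per subset x predictor;
- ``figures/`` — HR and p heat maps with default/optimized markers;
- ``report.json`` — machine-readable run summary (patients, events, cells
  fit, cells with p < 0.05, flagged cells);
- ``manifest.json`` — config echo plus SHA-256 of every input consumed.

Patients with an unknown subtype enter the full-cohort sweep but no subtype
sweep.  A patient without baseline images is dropped with a logged warning;
a subset with no patients is skipped and noted in the report.  Output
depends only on (inputs, config); imaging stages are per-patient, so
dropping one patient never changes another's predictors.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enhancement import compute_enhancement_maps
from .ftv import (
    DEFAULT_MIN_CLUSTER_VOXELS,
    PREDICTOR_KINDS,
    ThresholdGrid,
    build_predictors,
    default_grid,
    ftv_surface,
)
from .io import load_clinical_table, load_study, load_voi_spec
from .survival import DEFAULT_SCALES, SubsetError, SweepResult, sweep
from .viz import HeatmapStyle, render_heatmaps
from .voi import voi_mask

logger = logging.getLogger("ftvsweep")

__all__ = ["RunConfig", "run_analysis", "collect_report", "sweep_to_frame"]

VISIT_COLUMNS = {"MRI_1": "mri_1_file", "MRI_2": "mri_2_file", "MRI_f": "mri_f_file"}
DEFAULT_SUBSETS = ("full", "HRpos_HER2neg", "HER2pos", "TN")


@dataclass(frozen=True)
class RunConfig:
    clinical_csv: str
    data_dir: str = "."
    out_dir: str = "ftvsweep_run"
    grid: ThresholdGrid = field(default_factory=default_grid)
    default_cell: tuple[float, float] = (70.0, 0.0)
    s0_floor: float | None = None
    min_cluster_voxels: int = DEFAULT_MIN_CLUSTER_VOXELS
    connectivity: int = 26
    washout_cap_policy: str = "cap"
    scales: tuple[tuple[str, float], ...] = tuple(DEFAULT_SCALES.items())
    subsets: tuple[str, ...] = DEFAULT_SUBSETS
    predictors: tuple[str, ...] = PREDICTOR_KINDS
    seed: int = 0
    log_level: str = "INFO"
    export_surfaces: bool = False  # long-format ftv_surfaces.csv (can be large)

    def __post_init__(self) -> None:
        self.grid.index_of(*self.default_cell)  # default cell must be on the grid
        for s in self.subsets:
            if s != "full" and s not in ("HRpos_HER2neg", "HER2pos", "TN", "unknown"):
                raise ValueError(f"unknown subset label {s!r}")
        for p in self.predictors:
            if p not in PREDICTOR_KINDS:
                raise ValueError(f"unknown predictor {p!r}")

    @property
    def scale_map(self) -> dict[str, float]:
        return dict(self.scales)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def sweep_to_frame(result: SweepResult) -> pd.DataFrame:
    """Long-format per-cell sweep table."""
    rows = []
    for i, pe_t in enumerate(result.grid.pe_thresholds):
        for j, ser_t in enumerate(result.grid.ser_thresholds):
            r = result.results[i][j]
            rows.append(
                {
                    "subset": result.subset,
                    "predictor": result.predictor,
                    "pe_t": pe_t,
                    "ser_t": ser_t,
                    "n": r.n_used,
                    "events": r.n_events,
                    "beta": r.beta,
                    "hr": r.hazard_ratio,
                    "ci_lo": r.wald_ci_lo,
                    "ci_hi": r.wald_ci_hi,
                    "lr_p": r.lr_pvalue,
                    "converged": r.converged,
                    "degenerate": r.degenerate,
                }
            )
    return pd.DataFrame(rows)


def _comparison_row(result: SweepResult) -> dict:
    """Optimized-vs-default cells side by side (the shape of the result tables)."""
    row = {
        "subset": result.subset,
        "predictor": result.predictor,
        "scale": result.scale,
    }
    cells = {"default": result.default_cell, "optimized": result.optimized_cell}
    for name, cell in cells.items():
        if cell is None:
            row.update({f"{name}_{k}": np.nan for k in
                        ("pe_t", "ser_t", "hr", "ci_lo", "ci_hi", "p")})
            continue
        r = result.result_at(*cell)
        row.update(
            {
                f"{name}_pe_t": cell[0],
                f"{name}_ser_t": cell[1],
                f"{name}_hr": r.hazard_ratio,
                f"{name}_ci_lo": r.wald_ci_lo,
                f"{name}_ci_hi": r.wald_ci_hi,
                f"{name}_p": r.lr_pvalue,
            }
        )
    return row


def run_analysis(cfg: RunConfig) -> dict:
    """Run the full analysis; returns the report dict (also written as JSON)."""
    logging.basicConfig(level=cfg.log_level)
    data_dir = Path(cfg.data_dir)
    out_dir = Path(cfg.out_dir)
    (out_dir / "sweeps").mkdir(parents=True, exist_ok=True)
    (out_dir / "figures").mkdir(parents=True, exist_ok=True)

    clinical_path = Path(cfg.clinical_csv)
    table, survival_records = load_clinical_table(clinical_path)
    input_hashes = {str(clinical_path): _sha256(clinical_path)}

    predictors = []
    dropped = []
    exported_surfaces = []
    for _, row in table.iterrows():
        pid = str(row["patient_id"])
        base_col = VISIT_COLUMNS["MRI_1"]
        base_raw = row.get(base_col, "")
        base_file = "" if pd.isna(base_raw) else str(base_raw)
        if not base_file:
            logger.warning("patient %s has no baseline image; dropped", pid)
            dropped.append(pid)
            continue
        voi_file = data_dir / str(row["voi_file"])
        spec = load_voi_spec(voi_file)
        input_hashes[str(voi_file)] = _sha256(voi_file)
        surfaces = {}
        for visit, col in VISIT_COLUMNS.items():
            raw = row.get(col, "")
            fname = "" if pd.isna(raw) else str(raw)
            if not fname:
                continue
            path = data_dir / fname
            study = load_study(path, patient_id=pid, visit=visit)
            input_hashes[str(path)] = _sha256(path)
            maps = compute_enhancement_maps(
                study, s0_floor=cfg.s0_floor, washout_cap_policy=cfg.washout_cap_policy
            )
            voi = voi_mask(spec, study.shape)
            surfaces[visit] = ftv_surface(
                study, maps, voi, cfg.grid, cfg.min_cluster_voxels, cfg.connectivity
            )
            logger.debug("patient %s visit %s: surface computed", pid, visit)
        predictors.append(build_predictors(surfaces, subtype=str(row["subtype"])))
        if cfg.export_surfaces:
            exported_surfaces.extend(surfaces.values())

    if cfg.export_surfaces and exported_surfaces:
        from .ftv import surfaces_to_frame

        surfaces_to_frame(exported_surfaces).to_csv(
            out_dir / "ftv_surfaces.csv", index=False
        )

    surv_by_id = {r.patient_id: r for r in survival_records}
    used_ids = [p.patient_id for p in predictors]
    report: dict = {
        "n_patients_in_table": int(len(table)),
        "n_patients_used": len(used_ids),
        "n_events": int(sum(surv_by_id[i].event for i in used_ids if i in surv_by_id)),
        "dropped_patients": dropped,
        "grid_cells": int(np.prod(cfg.grid.shape)),
        "sweeps": [],
    }

    comparison_rows = []
    for subset in cfg.subsets:
        for predictor in cfg.predictors:
            try:
                result = sweep(
                    predictors, survival_records, cfg.grid, predictor,
                    subset=subset, scale=cfg.scale_map[predictor],
                    default_cell=cfg.default_cell,
                )
            except SubsetError:
                logger.warning("subset %r is empty; skipped", subset)
                report["sweeps"].append(
                    {"subset": subset, "predictor": predictor, "skipped": "empty subset"}
                )
                continue
            sweep_to_frame(result).to_csv(
                out_dir / "sweeps" / f"{subset}_{predictor}.csv", index=False
            )
            render_heatmaps(result, HeatmapStyle(), out_dir / "figures")
            comparison_rows.append(_comparison_row(result))
            report["sweeps"].append(
                {
                    "subset": subset,
                    "predictor": predictor,
                    "n_patients": result.results[0][0].n_used,
                    "cells_attempted": int(np.prod(cfg.grid.shape)),
                    "cells_fit": result.n_fit,
                    "cells_significant_p05": result.n_significant,
                    "cells_degenerate": result.n_degenerate,
                    "optimized_cell": list(result.optimized_cell)
                    if result.optimized_cell
                    else None,
                }
            )
            logger.info(
                "sweep %s/%s: %d cells fit, %d significant, optimized=%s",
                subset, predictor, result.n_fit, result.n_significant,
                result.optimized_cell,
            )

    pd.DataFrame(comparison_rows).to_csv(out_dir / "comparison.csv", index=False)
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    manifest = {
        "config": {
            **{k: v for k, v in cfg.__dict__.items() if k != "grid"},
            "grid": {
                "pe_thresholds": list(cfg.grid.pe_thresholds),
                "ser_thresholds": list(cfg.grid.ser_thresholds),
            },
        },
        "input_sha256": input_hashes,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return report


def collect_report(run_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Assemble the optimized-vs-default comparison tables of a finished run.

    Returns one small table per subset, indexed by predictor.
    """
    run_dir = Path(run_dir)
    comparison = pd.read_csv(run_dir / "comparison.csv")
    tables = {}
    for subset, group in comparison.groupby("subset"):
        tables[str(subset)] = group.set_index("predictor")
    return tables
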
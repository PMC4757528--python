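"""Hazard-ratio and p-value heat maps over the threshold grid.

Layout follows the study's figures: PE_t on the y axis (30–200%), SER_t on
the x axis (0–2.0).  Hazard ratios are clamped to [0.9, 1.2] and colored
blue -> red; p-values are clamped to [0.001, 0.1] and colored red -> blue on
a log10 scale (a linear map would spend nearly the whole range on p > 0.01).
The default threshold cell is marked with a circle and the optimized cell
with a star.  Degenerate (monotone-likelihood) cells are overlaid with an
'x'.  The renderer returns the exact clamped matrices it plotted, so tests
assert on numbers rather than pixels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .survival import SweepResult

__all__ = ["HeatmapStyle", "clamp", "render_heatmaps"]


@dataclass(frozen=True)
class HeatmapStyle:
    hr_color_range: tuple[float, float] = (0.9, 1.2)
    p_color_range: tuple[float, float] = (0.001, 0.1)
    log10_p: bool = True
    hr_cmap: str = "coolwarm"  # blue -> red with increasing hazard ratio
    p_cmap: str = "coolwarm_r"  # red (low p) -> blue (high p)
    default_marker: str = "o"
    optimized_marker: str = "*"
    filled_contour: bool = False  # per-cell raster by default (deterministic tests)
    dpi: int = 120
    save_svg: bool = False


def clamp(matrix: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Clip to [lo, hi]; NaNs pass through so missing cells stay blank."""
    return np.clip(matrix, lo, hi)


def _cell_centers(values: tuple[float, ...]) -> np.ndarray:
    return np.arange(len(values), dtype=float)


def render_heatmaps(
    sweep: SweepResult,
    style: HeatmapStyle | None = None,
    out_dir: str | Path = ".",
    prefix: str | None = None,
) -> dict[str, np.ndarray]:
    """Write one HR map and one p map (PNG + JSON sidecar) for a sweep.

    Returns ``{"hr": ..., "p": ...}`` — the clamped matrices exactly as
    plotted.  The sweep itself is never modified.  A sweep with no eligible
    optimized cell renders without the star and warns.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if style is None:
        style = HeatmapStyle()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if prefix is None:
        prefix = f"{sweep.subset}_{sweep.predictor}"

    grid = sweep.grid
    hr_clamped = clamp(sweep.hr_matrix, *style.hr_color_range)
    p_clamped = clamp(sweep.p_matrix, *style.p_color_range)
    plotted = {"hr": hr_clamped, "p": p_clamped}

    if sweep.optimized_cell is None:
        warnings.warn(
            f"sweep {sweep.subset}/{sweep.predictor} has no optimized cell; "
            "rendering without the star marker"
        )

    def marker_xy(cell: tuple[float, float]) -> tuple[float, float]:
        i, j = grid.index_of(*cell)
        return float(j), float(i)

    written: list[str] = []
    for kind in ("hr", "p"):
        if kind == "hr":
            shown = hr_clamped
            vmin, vmax = style.hr_color_range
            cmap, label = style.hr_cmap, "hazard ratio"
            norm = None
        else:
            shown = p_clamped
            vmin, vmax = style.p_color_range
            cmap, label = style.p_cmap, "likelihood-ratio p"
            if style.log10_p:
                from matplotlib.colors import LogNorm

                norm = LogNorm(vmin=vmin, vmax=vmax)
            else:
                norm = None

        fig, ax = plt.subplots(figsize=(5.0, 6.0))
        if style.filled_contour:
            xx, yy = np.meshgrid(
                _cell_centers(grid.ser_thresholds), _cell_centers(grid.pe_thresholds)
            )
            im = ax.contourf(
                xx, yy, shown, levels=12, cmap=cmap, norm=norm,
                vmin=None if norm is not None else vmin,
                vmax=None if norm is not None else vmax,
            )
        else:
            im = ax.imshow(
                shown,
                origin="lower",
                aspect="auto",
                cmap=cmap,
                norm=norm,
                vmin=None if norm is not None else vmin,
                vmax=None if norm is not None else vmax,
                interpolation="nearest",
            )
        ax.set_xticks(_cell_centers(grid.ser_thresholds))
        ax.set_xticklabels([f"{v:g}" for v in grid.ser_thresholds], fontsize=7)
        ax.set_yticks(_cell_centers(grid.pe_thresholds))
        ax.set_yticklabels([f"{v:g}" for v in grid.pe_thresholds], fontsize=7)
        ax.set_xlabel("SER$_t$")
        ax.set_ylabel("PE$_t$ (%)")
        ax.set_title(f"{label} — {sweep.subset}, {sweep.predictor}", fontsize=10)
        fig.colorbar(im, ax=ax, label=label)

        if sweep.degenerate_matrix.any():
            yy, xx = np.nonzero(sweep.degenerate_matrix)
            ax.scatter(xx, yy, marker="x", s=18, c="k", linewidths=0.8)
        x, y = marker_xy(sweep.default_cell)
        ax.scatter([x], [y], marker=style.default_marker, s=90, facecolors="none",
                   edgecolors="k", linewidths=1.5)
        if sweep.optimized_cell is not None:
            x, y = marker_xy(sweep.optimized_cell)
            ax.scatter([x], [y], marker=style.optimized_marker, s=140, c="k")

        base = out_dir / f"{prefix}_{kind}"
        fig.savefig(base.with_suffix(".png"), dpi=style.dpi, bbox_inches="tight")
        if style.save_svg:
            fig.savefig(base.with_suffix(".svg"), bbox_inches="tight")
        plt.close(fig)
        written.append(str(base.with_suffix(".png")))

    sidecar = {
        "subset": sweep.subset,
        "predictor": sweep.predictor,
        "scale": sweep.scale,
        "hr_color_range": list(style.hr_color_range),
        "p_color_range": list(style.p_color_range),
        "p_log10_scale": style.log10_p,
        "default_cell": list(sweep.default_cell),
        "optimized_cell": list(sweep.optimized_cell) if sweep.optimized_cell else None,
        "n_degenerate_cells": int(sweep.degenerate_matrix.sum()),
        "figures": written,
    }
    (out_dir / f"{prefix}_style.json").write_text(json.dumps(sidecar, indent=2))
    return plotted
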
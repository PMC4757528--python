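"""Functional tumor volume (FTV) at threshold pairs and over the full grid.

FTV at a threshold pair (PE_t, SER_t) is the total volume, in cc, of VOI
voxels that survive three gates applied strictly in order:

1. early percent enhancement at or above ``PE_t``;
2. a connected-component test removing components smaller than a minimum
   cluster size (suppresses speckle from noise voxels);
3. SER at or above ``SER_t``.

Both comparisons are closed (``>=``) so that the conventional default
``SER_t = 0`` gates out nothing with non-negative SER.

The threshold grid sweeps PE_t over 30–200% in steps of 10 and SER_t over
0.0–2.0 in steps of 0.2 (18 x 11 = 198 cells).  Three survival predictors
are derived per grid cell from the per-visit FTV surfaces:

- ``delta_ftv2``: percent FTV change, baseline -> early-treatment visit;
- ``delta_ftvf``: percent FTV change, baseline -> pre-surgical visit;
- ``ftv_f``: absolute FTV (cc) at the pre-surgical visit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

from .enhancement import DCEStudy, EnhancementMaps

__all__ = [
    "ThresholdGrid",
    "FTVSurface",
    "PredictorRecord",
    "PREDICTOR_KINDS",
    "SUBTYPES",
    "default_grid",
    "enhancing_mask",
    "compute_ftv",
    "ftv_surface",
    "build_predictors",
]

PREDICTOR_KINDS = ("delta_ftv2", "delta_ftvf", "ftv_f")
SUBTYPES = ("HRpos_HER2neg", "HER2pos", "TN", "unknown")

#: Default minimum cluster size: ~0.01 cc at 0.7 x 0.94 x 2.0 mm voxels.
DEFAULT_MIN_CLUSTER_VOXELS = 8

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class ThresholdGrid:
    """Ordered PE (percent) and SER (ratio) threshold values."""

    pe_thresholds: tuple[float, ...]
    ser_thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, vals in (
            ("pe_thresholds", self.pe_thresholds),
            ("ser_thresholds", self.ser_thresholds),
        ):
            if len(vals) == 0 or any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"{name} must be non-empty and strictly increasing")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.pe_thresholds), len(self.ser_thresholds))

    def index_of(self, pe_t: float, ser_t: float, atol: float = 1e-9) -> tuple[int, int]:
        """Indices of the grid cell matching (pe_t, ser_t)."""
        i = int(np.argmin(np.abs(np.array(self.pe_thresholds) - pe_t)))
        j = int(np.argmin(np.abs(np.array(self.ser_thresholds) - ser_t)))
        if abs(self.pe_thresholds[i] - pe_t) > atol or abs(self.ser_thresholds[j] - ser_t) > atol:
            raise KeyError(f"({pe_t}, {ser_t}) is not a grid cell")
        return i, j


def default_grid() -> ThresholdGrid:
    """The study grid: PE_t 30–200% step 10, SER_t 0.0–2.0 step 0.2."""
    return ThresholdGrid(
        pe_thresholds=tuple(float(v) for v in range(30, 201, 10)),
        ser_thresholds=tuple(np.round(np.linspace(0.0, 2.0, 11), 10)),
    )


@dataclass
class FTVSurface:
    """FTV in cc at every (PE_t, SER_t) grid cell for one study visit."""

    ftv_cc: np.ndarray  # shape grid.shape
    grid: ThresholdGrid
    patient_id: str
    visit: str

    def at(self, pe_t: float, ser_t: float) -> float:
        i, j = self.grid.index_of(pe_t, ser_t)
        return float(self.ftv_cc[i, j])


@dataclass
class PredictorRecord:
    """Per-patient survival predictors over the grid (NaN where missing)."""

    patient_id: str
    subtype: str
    grid: ThresholdGrid
    delta_ftv2: np.ndarray = field(repr=False)
    delta_ftvf: np.ndarray = field(repr=False)
    ftv_f: np.ndarray = field(repr=False)

    def values(self, kind: str) -> np.ndarray:
        if kind not in PREDICTOR_KINDS:
            raise KeyError(f"unknown predictor kind {kind!r}")
        return getattr(self, kind)


def _binary_structure(connectivity: int) -> np.ndarray:
    try:
        rank = _CONNECTIVITY_RANK[connectivity]
    except KeyError:
        raise ValueError(
            f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}, got {connectivity}"
        ) from None
    return ndimage.generate_binary_structure(3, rank)


def _remove_small_components(
    mask: np.ndarray, min_cluster_voxels: int, connectivity: int
) -> np.ndarray:
    if min_cluster_voxels <= 1 or not mask.any():
        return mask
    labels, n = ndimage.label(mask, structure=_binary_structure(connectivity))
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_cluster_voxels
    keep[0] = False
    return keep[labels]


def enhancing_mask(
    maps: EnhancementMaps,
    voi: np.ndarray,
    pe_t: float,
    min_cluster_voxels: int = DEFAULT_MIN_CLUSTER_VOXELS,
    connectivity: int = 26,
) -> np.ndarray:
    """PE-thresholded VOI mask with small connected components removed.

    A voxel enters the raw mask iff it is valid, inside the VOI, and has
    ``pe_early >= pe_t``.  Every connected component (26-neighborhood by
    default) smaller than ``min_cluster_voxels`` is then discarded.  An empty
    mask is a legal output.
    """
    if maps.shape != voi.shape:
        raise ValueError(f"VOI shape {voi.shape} != map shape {maps.shape}")
    if min_cluster_voxels < 1:
        raise ValueError("min_cluster_voxels must be >= 1")
    raw = maps.valid & voi & (maps.pe_early >= pe_t)
    return _remove_small_components(raw, min_cluster_voxels, connectivity)


def compute_ftv(
    study: DCEStudy,
    maps: EnhancementMaps,
    voi: np.ndarray,
    pe_t: float,
    ser_t: float,
    min_cluster_voxels: int = DEFAULT_MIN_CLUSTER_VOXELS,
    connectivity: int = 26,
) -> float:
    """FTV in cc at one threshold pair (PE gate -> connectivity -> SER gate)."""
    if maps.ser is None:
        raise ValueError("maps.ser not computed; call compute_ser_map first")
    mask = enhancing_mask(maps, voi, pe_t, min_cluster_voxels, connectivity)
    count = int(np.count_nonzero(mask & (maps.ser >= ser_t)))
    return count * study.voxel_volume_cc


def ftv_surface(
    study: DCEStudy,
    maps: EnhancementMaps,
    voi: np.ndarray,
    grid: ThresholdGrid | None = None,
    min_cluster_voxels: int = DEFAULT_MIN_CLUSTER_VOXELS,
    connectivity: int = 26,
) -> FTVSurface:
    """FTV at every grid cell.

    One connectivity pass per PE threshold; the SER counts per row come from
    a sorted-search over the surviving voxels' SER values, which is exactly
    equivalent to counting ``ser >= ser_t`` per cell.
    """
    if maps.ser is None:
        raise ValueError("maps.ser not computed; call compute_ser_map first")
    if grid is None:
        grid = default_grid()
    out = np.zeros(grid.shape, dtype=np.float64)
    ser_ts = np.array(grid.ser_thresholds)
    for i, pe_t in enumerate(grid.pe_thresholds):
        mask = enhancing_mask(maps, voi, pe_t, min_cluster_voxels, connectivity)
        ser_vals = np.sort(maps.ser[mask])
        # voxels with ser >= t: those at/after the left insertion point of t
        counts = ser_vals.size - np.searchsorted(ser_vals, ser_ts, side="left")
        out[i, :] = counts * study.voxel_volume_cc
    return FTVSurface(ftv_cc=out, grid=grid, patient_id=study.patient_id, visit=study.visit)


def surfaces_to_frame(surfaces: "list[FTVSurface]"):
    """Long-format table of FTV surfaces: patient_id, visit, pe_t, ser_t, ftv_cc."""
    import pandas as pd

    rows = []
    for surface in surfaces:
        grid = surface.grid
        for i, pe_t in enumerate(grid.pe_thresholds):
            for j, ser_t in enumerate(grid.ser_thresholds):
                rows.append(
                    {
                        "patient_id": surface.patient_id,
                        "visit": surface.visit,
                        "pe_t": pe_t,
                        "ser_t": ser_t,
                        "ftv_cc": float(surface.ftv_cc[i, j]),
                    }
                )
    return pd.DataFrame(rows)


def build_predictors(
    surfaces: Mapping[str, FTVSurface | None],
    subtype: str = "unknown",
) -> PredictorRecord:
    """Derive the three per-cell survival predictors from per-visit surfaces.

    ``surfaces`` maps visit name to its FTV surface; ``MRI_1`` (baseline) is
    required.  A missing visit yields all-missing predictors for that visit;
    a zero baseline FTV at a cell yields missing percent-change predictors at
    that cell only (``ftv_f`` is unaffected).
    """
    base = surfaces.get("MRI_1")
    if base is None:
        raise ValueError("baseline surface (MRI_1) is required to build predictors")
    grid = base.grid
    nan = np.full(grid.shape, np.nan)

    def pct_change(later: FTVSurface | None) -> np.ndarray:
        if later is None:
            return nan.copy()
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = (later.ftv_cc - base.ftv_cc) / base.ftv_cc * 100.0
        delta[base.ftv_cc == 0] = np.nan
        return delta

    final = surfaces.get("MRI_f")
    return PredictorRecord(
        patient_id=base.patient_id,
        subtype=subtype,
        grid=grid,
        delta_ftv2=pct_change(surfaces.get("MRI_2")),
        delta_ftvf=pct_change(final),
        ftv_f=final.ftv_cc.copy() if final is not None else nan.copy(),
    )
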
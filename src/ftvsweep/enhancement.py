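"""Voxelwise percent-enhancement (PE) and signal-enhancement-ratio (SER) maps.

A three-timepoint DCE-MRI series (pre-contrast ``S0``, early post-contrast
``SE``, late post-contrast ``SL``) is summarized voxelwise as

    PE_early = (SE - S0) / S0 * 100
    PE_late  = (SL - S0) / S0 * 100
    SER      = PE_early / PE_late

PE measures contrast uptake relative to baseline; SER > 1 indicates signal
washout between the early and late phases, a kinetic pattern associated with
malignancy.  Maps are stored in percent (not fraction) so that threshold
values carry the units in which they are conventionally quoted.

Baselines at noise level (fat-suppressed voxels) make the PE quotient
unstable, so voxels whose ``S0`` falls at or below a configurable intensity
floor are flagged invalid and excluded from all downstream masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DCEStudy",
    "EnhancementMaps",
    "ShapeMismatchError",
    "SER_CAP",
    "default_s0_floor",
    "compute_pe_maps",
    "compute_ser_map",
    "compute_enhancement_maps",
]

VISITS = ("MRI_1", "MRI_2", "MRI_f")

#: Sentinel SER assigned to complete-washout voxels (PE_late <= 0 < PE_early).
#: Infinite, so such voxels pass every finite SER threshold.
SER_CAP = np.inf


class ShapeMismatchError(ValueError):
    """Raised when the three timepoint volumes do not share one shape."""


@dataclass(frozen=True)
class DCEStudy:
    """One visit's three co-registered 3D volumes plus voxel geometry.

    Intensities are in arbitrary scanner units and must be non-negative.
    ``voxel_size_mm`` is the (dz, dy, dx)-style edge length triple; voxel
    volume in cc is their product divided by 1000.
    """

    patient_id: str
    visit: str
    s0: np.ndarray
    s_early: np.ndarray
    s_late: np.ndarray
    voxel_size_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        for name in ("s_early", "s_late"):
            vol = getattr(self, name)
            if vol.shape != self.s0.shape:
                raise ShapeMismatchError(
                    f"volume {name!r} has shape {vol.shape}, "
                    f"expected {self.s0.shape} (from s0)"
                )
        if self.s0.ndim != 3:
            raise ShapeMismatchError(f"expected 3D volumes, got {self.s0.ndim}D")
        if len(self.voxel_size_mm) != 3 or any(d <= 0 for d in self.voxel_size_mm):
            raise ValueError(f"voxel dimensions must be positive, got {self.voxel_size_mm}")
        if self.visit not in VISITS:
            raise ValueError(f"unknown visit {self.visit!r}, expected one of {VISITS}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.s0.shape

    @property
    def voxel_volume_cc(self) -> float:
        d = self.voxel_size_mm
        return float(d[0] * d[1] * d[2] / 1000.0)


@dataclass
class EnhancementMaps:
    """Voxelwise PE/SER maps with a validity mask.

    ``ser`` is ``None`` until :func:`compute_ser_map` fills it.  Invalid
    voxels (baseline at or below the floor) hold zeros in every map and are
    never counted downstream.
    """

    pe_early: np.ndarray
    pe_late: np.ndarray
    valid: np.ndarray
    ser: np.ndarray | None = None
    s0_floor: float = field(default=0.0)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pe_early.shape


def default_s0_floor(s0: np.ndarray) -> float:
    """Default validity floor: 5% of the volume's 98th intensity percentile.

    Scales with the scanner's arbitrary intensity units, sits well above the
    fat-suppressed noise floor, and well below enhancing-tissue baselines.
    """
    return float(0.05 * np.percentile(s0, 98))


def compute_pe_maps(study: DCEStudy, s0_floor: float | None = None) -> EnhancementMaps:
    """Compute early and late percent-enhancement maps.

    Parameters
    ----------
    study:
        The three-timepoint series.
    s0_floor:
        Absolute intensity floor; voxels with ``s0 <= s0_floor`` are marked
        invalid.  ``None`` selects :func:`default_s0_floor`.

    Returns
    -------
    EnhancementMaps
        With ``pe_early``/``pe_late``/``valid`` filled and ``ser=None``.
    """
    if s0_floor is None:
        s0_floor = default_s0_floor(study.s0)
    if s0_floor < 0:
        raise ValueError(f"s0_floor must be non-negative, got {s0_floor}")

    s0 = np.asarray(study.s0, dtype=np.float64)
    valid = s0 > s0_floor
    safe_s0 = np.where(valid, s0, 1.0)
    pe_early = np.where(valid, (study.s_early - s0) / safe_s0 * 100.0, 0.0)
    pe_late = np.where(valid, (study.s_late - s0) / safe_s0 * 100.0, 0.0)
    return EnhancementMaps(
        pe_early=pe_early, pe_late=pe_late, valid=valid, s0_floor=float(s0_floor)
    )


def compute_ser_map(maps: EnhancementMaps, washout_cap_policy: str = "cap") -> EnhancementMaps:
    """Fill the SER map as ``pe_early / pe_late`` under a washout policy.

    The ratio is undefined where the late signal has returned to (or below)
    baseline.  Policies for ``pe_late <= 0 < pe_early`` ("complete washout",
    the extreme of the behavior SER flags):

    - ``"cap"`` (default): assign :data:`SER_CAP` (+inf) so the voxel passes
      every finite SER threshold;
    - ``"exclude"``: mark the voxel invalid instead.

    Voxels with ``pe_early <= 0`` (non-enhancing) get SER = 0 everywhere.
    Returns a new :class:`EnhancementMaps`; the input is not modified.
    """
    if washout_cap_policy not in ("cap", "exclude"):
        raise ValueError(f"unknown washout_cap_policy {washout_cap_policy!r}")

    pe_e, pe_l = maps.pe_early, maps.pe_late
    valid = maps.valid.copy()
    enhancing = pe_e > 0
    positive_late = pe_l > 0

    ser = np.zeros_like(pe_e, dtype=np.float64)
    ratio_ok = enhancing & positive_late
    ser[ratio_ok] = pe_e[ratio_ok] / pe_l[ratio_ok]

    washout = enhancing & ~positive_late
    if washout_cap_policy == "cap":
        ser[washout] = SER_CAP
    else:
        valid &= ~washout
        ser[washout] = 0.0
    ser[~valid] = 0.0

    return EnhancementMaps(
        pe_early=pe_e, pe_late=pe_l, valid=valid, ser=ser, s0_floor=maps.s0_floor
    )


def compute_enhancement_maps(
    study: DCEStudy,
    s0_floor: float | None = None,
    washout_cap_policy: str = "cap",
) -> EnhancementMaps:
    """Convenience: PE maps followed by the SER map."""
    return compute_ser_map(compute_pe_maps(study, s0_floor), washout_cap_policy)
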
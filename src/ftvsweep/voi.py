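"""Volume-of-interest construction from orthogonal projection ROIs.

The tumor-enclosing VOI is defined the way reader workstations do it: two
rectangular ROIs drawn on maximum-intensity-projection (MIP) images along two
different axes; each rectangle back-projects to a slab through the volume and
the VOI is the intersection of the two slabs.  Enhancing non-tumor structures
(vessels, heart) that intrude on the VOI are removed afterwards via declarative
exclusion regions — axis-aligned 3D boxes or per-axis 2D polygons rasterized
and back-projected.

Coordinates are 0-based, half-open ``[lo, hi)`` voxel indices in array order.
For a rectangle on projection axis ``k``, ``rect[0]`` indexes the first and
``rect[1]`` the second of the remaining axes in array order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from skimage.draw import polygon as _raster_polygon

__all__ = [
    "ProjectionROI",
    "BoxExclusion",
    "PolygonExclusion",
    "VOISpec",
    "EmptyVOIWarning",
    "project_mip",
    "roi_slab_mask",
    "voi_mask",
    "spec_to_dict",
    "spec_from_dict",
]


class EmptyVOIWarning(UserWarning):
    """The requested VOI contains no voxels."""


@dataclass(frozen=True)
class ProjectionROI:
    """A rectangle on the MIP along ``axis``, as ``((r0, r1), (c0, c1))``."""

    axis: int
    rect: tuple[tuple[int, int], tuple[int, int]]


@dataclass(frozen=True)
class BoxExclusion:
    """Axis-aligned 3D box, ``((z0, z1), (y0, y1), (x0, x1))`` half-open."""

    bounds: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


@dataclass(frozen=True)
class PolygonExclusion:
    """2D polygon in the projection plane of ``axis``, back-projected.

    ``vertices`` are (row, col) pairs in the plane's in-order remaining axes.
    """

    axis: int
    vertices: tuple[tuple[float, float], ...]


@dataclass(frozen=True)
class VOISpec:
    roi_a: ProjectionROI
    roi_b: ProjectionROI
    exclusions: tuple[Any, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.roi_a.axis == self.roi_b.axis:
            raise ValueError(
                f"the two projection axes must differ, both are {self.roi_a.axis}"
            )


def project_mip(volume: np.ndarray, axis: int) -> np.ndarray:
    """Maximum intensity projection: collapse ``axis`` by elementwise max."""
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3D volume, got {volume.ndim}D")
    if not -3 <= axis < 3:
        raise ValueError(f"axis {axis} invalid for a 3D volume")
    return volume.max(axis=axis)


def _plane_axes(axis: int) -> tuple[int, int]:
    rest = [a for a in range(3) if a != axis % 3]
    return rest[0], rest[1]


def roi_slab_mask(roi: ProjectionROI, shape: Sequence[int]) -> np.ndarray:
    """Back-project one rectangular ROI into a 3D slab mask.

    The rectangle is clipped to the volume bounds; a rectangle that is empty
    after clipping is degenerate and rejected.
    """
    if not -3 <= roi.axis < 3:
        raise ValueError(f"projection axis {roi.axis} invalid for a 3D volume")
    ax_r, ax_c = _plane_axes(roi.axis)
    (r0, r1), (c0, c1) = roi.rect
    r0, r1 = max(int(r0), 0), min(int(r1), shape[ax_r])
    c0, c1 = max(int(c0), 0), min(int(c1), shape[ax_c])
    if r0 >= r1 or c0 >= c1:
        raise ValueError(
            f"degenerate (zero-area) rectangle {roi.rect} on axis {roi.axis} "
            f"after clipping to shape {tuple(shape)}"
        )
    mask = np.zeros(tuple(shape), dtype=bool)
    index: list[Any] = [slice(None)] * 3
    index[ax_r] = slice(r0, r1)
    index[ax_c] = slice(c0, c1)
    mask[tuple(index)] = True
    return mask


def _exclusion_mask(exc: Any, shape: Sequence[int]) -> np.ndarray:
    mask = np.zeros(tuple(shape), dtype=bool)
    if isinstance(exc, BoxExclusion):
        slices = tuple(
            slice(max(int(lo), 0), min(int(hi), shape[i]))
            for i, (lo, hi) in enumerate(exc.bounds)
        )
        mask[slices] = True
    elif isinstance(exc, PolygonExclusion):
        ax_r, ax_c = _plane_axes(exc.axis)
        rows = np.array([v[0] for v in exc.vertices], dtype=float)
        cols = np.array([v[1] for v in exc.vertices], dtype=float)
        rr, cc = _raster_polygon(rows, cols, shape=(shape[ax_r], shape[ax_c]))
        plane = np.zeros((shape[ax_r], shape[ax_c]), dtype=bool)
        plane[rr, cc] = True
        mask = np.moveaxis(
            np.broadcast_to(plane, (shape[exc.axis % 3], *plane.shape)).copy(),
            0,
            exc.axis % 3,
        )
    else:
        raise TypeError(f"unsupported exclusion type {type(exc).__name__}")
    return mask


def voi_mask(spec: VOISpec, shape: Sequence[int]) -> np.ndarray:
    """Build the 3D VOI mask: slab(roi_a) ∧ slab(roi_b), minus exclusions.

    Exclusions are removed after the intersection.  An empty result is legal
    and raises :class:`EmptyVOIWarning` rather than an error.
    """
    mask = roi_slab_mask(spec.roi_a, shape) & roi_slab_mask(spec.roi_b, shape)
    for exc in spec.exclusions:
        mask &= ~_exclusion_mask(exc, shape)
    if not mask.any():
        warnings.warn("VOI is empty after intersection/exclusions", EmptyVOIWarning)
    return mask


# ---------------------------------------------------------------------------
# JSON-friendly (de)serialization


def spec_to_dict(spec: VOISpec) -> dict:
    def roi(r: ProjectionROI) -> dict:
        return {"axis": r.axis, "rect": [list(r.rect[0]), list(r.rect[1])]}

    exclusions = []
    for exc in spec.exclusions:
        if isinstance(exc, BoxExclusion):
            exclusions.append({"type": "box", "bounds": [list(b) for b in exc.bounds]})
        elif isinstance(exc, PolygonExclusion):
            exclusions.append(
                {
                    "type": "polygon",
                    "axis": exc.axis,
                    "vertices": [list(v) for v in exc.vertices],
                }
            )
        else:
            raise TypeError(f"unsupported exclusion type {type(exc).__name__}")
    return {"roi_a": roi(spec.roi_a), "roi_b": roi(spec.roi_b), "exclusions": exclusions}


def spec_from_dict(data: dict) -> VOISpec:
    def roi(d: dict) -> ProjectionROI:
        (r0, r1), (c0, c1) = d["rect"]
        return ProjectionROI(axis=int(d["axis"]), rect=((r0, r1), (c0, c1)))

    exclusions: list[Any] = []
    for exc in data.get("exclusions", ()):
        if exc["type"] == "box":
            exclusions.append(
                BoxExclusion(bounds=tuple(tuple(b) for b in exc["bounds"]))
            )
        elif exc["type"] == "polygon":
            exclusions.append(
                PolygonExclusion(
                    axis=int(exc["axis"]),
                    vertices=tuple(tuple(v) for v in exc["vertices"]),
                )
            )
        else:
            raise ValueError(f"unknown exclusion type {exc['type']!r}")
    return VOISpec(roi_a=roi(data["roi_a"]), roi_b=roi(data["roi_b"]), exclusions=tuple(exclusions))
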
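"""Reading and writing the pipeline's on-disk formats.

Images are NIfTI-1: either one 4D file with the timepoint axis last in
acquisition order (pre-contrast, early, late), or three 3D files.  Affines
must agree across timepoints to 1e-4.  VOI specifications are JSON; the
clinical table is CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .enhancement import DCEStudy
from .ftv import SUBTYPES
from .survival import SurvivalRecord
from .voi import VOISpec, spec_from_dict, spec_to_dict

__all__ = [
    "load_study",
    "save_study",
    "load_voi_spec",
    "save_voi_spec",
    "load_clinical_table",
    "ClinicalTableError",
]

AFFINE_ATOL = 1e-4


class ClinicalTableError(ValueError):
    """Malformed clinical CSV; the message names the offending row."""


def _voxel_size_from_affine(img: nib.Nifti1Image) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return (float(zooms[0]), float(zooms[1]), float(zooms[2]))


def load_study(
    path: str | Path | Sequence[str | Path],
    patient_id: str,
    visit: str,
) -> DCEStudy:
    """Load one visit's series from a 4D NIfTI or a (t0, t1, t2) file triple."""
    if isinstance(path, (str, Path)):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        if data.ndim != 4 or data.shape[-1] != 3:
            raise ValueError(
                f"{path}: expected a 4D volume with 3 timepoints last, got shape {data.shape}"
            )
        vols = [data[..., t] for t in range(3)]
        voxel = _voxel_size_from_affine(img)
    else:
        if len(path) != 3:
            raise ValueError(f"expected 3 files (t0, t1, t2), got {len(path)}")
        imgs = [nib.load(str(p)) for p in path]
        ref = imgs[0].affine
        for p, img in zip(path[1:], imgs[1:]):
            if not np.allclose(img.affine, ref, atol=AFFINE_ATOL):
                raise ValueError(f"{p}: affine does not match the pre-contrast volume")
        vols = [np.asarray(img.dataobj, dtype=np.float64) for img in imgs]
        voxel = _voxel_size_from_affine(imgs[0])
    return DCEStudy(
        patient_id=patient_id, visit=visit,
        s0=vols[0], s_early=vols[1], s_late=vols[2], voxel_size_mm=voxel,
    )


def save_study(study: DCEStudy, path: str | Path) -> None:
    """Write the three timepoints as one 4D NIfTI (timepoint axis last)."""
    data = np.stack([study.s0, study.s_early, study.s_late], axis=-1).astype(np.float32)
    affine = np.diag([*study.voxel_size_mm, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((*study.voxel_size_mm, 1.0))
    nib.save(img, str(path))


def load_voi_spec(path: str | Path) -> VOISpec:
    return spec_from_dict(json.loads(Path(path).read_text()))


def save_voi_spec(spec: VOISpec, path: str | Path) -> None:
    Path(path).write_text(json.dumps(spec_to_dict(spec), indent=2))


REQUIRED_CLINICAL_COLUMNS = ("patient_id", "subtype", "rfs_months", "event")


def load_clinical_table(path: str | Path) -> tuple[pd.DataFrame, list[SurvivalRecord]]:
    """Read the clinical CSV; returns the frame and parsed survival records.

    Required columns: patient_id, subtype (HRpos_HER2neg / HER2pos / TN /
    unknown), rfs_months (> 0), event (0/1).  Visit-to-file mapping columns
    (``mri_1_file`` etc.) are passed through untouched.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ClinicalTableError(f"{path}: missing required column(s) {missing}")
    records = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        subtype = str(row["subtype"])
        if subtype not in SUBTYPES:
            raise ClinicalTableError(f"{path} line {line}: unknown subtype {subtype!r}")
        try:
            rfs = float(row["rfs_months"])
            event = int(row["event"])
        except (TypeError, ValueError) as exc:
            raise ClinicalTableError(f"{path} line {line}: {exc}") from exc
        if rfs <= 0:
            raise ClinicalTableError(f"{path} line {line}: rfs_months must be > 0, got {rfs}")
        if event not in (0, 1):
            raise ClinicalTableError(f"{path} line {line}: event must be 0 or 1, got {event}")
        records.append(
            SurvivalRecord(
                patient_id=str(row["patient_id"]), rfs_months=rfs,
                event=bool(event), subtype=subtype,
            )
        )
    return df, records
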
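"""File formats: cohort CSV, model JSON, and dose-grid/mask round-tripping.

Grid formats, dispatched on extension:

* ``.raw`` — raw little-endian float64 voxel values (C order) with a JSON
  sidecar ``<name>.json`` holding ``{shape, spacing_mm, origin_mm,
  dose_kind}``; masks use uint8 values.
* ``.nrrd`` (and anything else SimpleITK can write) — geometry carried by
  the image header; ``dose_kind`` in a sidecar JSON next to the file.

An optional DICOM-RT reader (``read_dicom_rt_dose``) converts an RT Dose
file via pydicom; it is an adapter for clinical exports and is not required
by any analysis path.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dose import DoseGrid, DoseKind, StructureMask

__all__ = [
    "COHORT_COLUMNS",
    "read_cohort",
    "write_cohort",
    "read_grid",
    "write_grid",
    "read_mask",
    "write_mask",
]

#: versioned cohort-CSV schema (header order)
COHORT_SCHEMA_VERSION = 1
COHORT_COLUMNS = (
    "id", "gender", "age", "t_stage", "n_stage", "clinical_stage",
    "chemotherapy", "volume_cc", "dmin_gy", "dmax_gy", "dmean_gy",
    "fx_dose_gy", "v10", "v20", "v30", "v40", "v45", "v50", "v60", "v70",
    "outcome_12m",
)


class SchemaError(ValueError):
    """A table or file does not conform to its documented schema."""


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV (schema in :data:`COHORT_COLUMNS`)."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file {path}: missing column(s) {missing}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].tolist()
        raise SchemaError(f"cohort file {path}: duplicate patient id(s) {dup}")
    bad = ~df["outcome_12m"].isin([0, 1])
    if bad.any():
        rows = (df.index[bad] + 2).tolist()  # 1-based incl. header
        raise SchemaError(
            f"cohort file {path}: outcome_12m must be 0/1 (bad rows {rows})")
    for col, lo in (("volume_cc", 0.0), ("age", 0.0)):
        nonpos = df[col] <= lo
        if nonpos.any():
            rows = (df.index[nonpos] + 2).tolist()
            raise SchemaError(f"cohort file {path}: {col} must be > {lo} (rows {rows})")
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table missing column(s) {missing}")
    df.loc[:, COHORT_COLUMNS].to_csv(path, index=False)


# -- dose grids and masks ----------------------------------------------------

def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_grid(grid: DoseGrid, path: str | Path) -> None:
    path = Path(path)
    meta = {
        "schema_version": COHORT_SCHEMA_VERSION,
        "shape": list(grid.shape),
        "spacing_mm": list(grid.spacing),
        "origin_mm": list(grid.origin),
        "dose_kind": grid.dose_kind.value,
    }
    if path.suffix == ".raw":
        grid.values.astype("<f8").tofile(path)
    else:
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(grid.values)
        img.SetSpacing(tuple(reversed(grid.spacing)))
        img.SetOrigin(tuple(reversed(grid.origin)))
        sitk.WriteImage(img, str(path))
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_grid(path: str | Path) -> DoseGrid:
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise SchemaError(f"missing sidecar header {side}")
    meta = json.loads(side.read_text())
    if path.suffix == ".raw":
        values = np.fromfile(path, dtype="<f8").reshape(meta["shape"])
        spacing, origin = meta["spacing_mm"], meta["origin_mm"]
    else:
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        values = sitk.GetArrayFromImage(img).astype(float)
        spacing = list(reversed(img.GetSpacing()))
        origin = list(reversed(img.GetOrigin()))
    return DoseGrid(values=values, spacing=tuple(spacing), origin=tuple(origin),
                    dose_kind=DoseKind(meta["dose_kind"]))


def write_mask(mask: StructureMask, grid: DoseGrid, path: str | Path) -> None:
    path = Path(path)
    meta = {
        "shape": list(mask.include.shape),
        "spacing_mm": list(grid.spacing),
        "origin_mm": list(grid.origin),
        "name": mask.name,
    }
    if path.suffix == ".raw":
        mask.include.astype(np.uint8).tofile(path)
    else:
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(mask.include.astype(np.uint8))
        img.SetSpacing(tuple(reversed(grid.spacing)))
        img.SetOrigin(tuple(reversed(grid.origin)))
        sitk.WriteImage(img, str(path))
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_mask(path: str | Path) -> StructureMask:
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise SchemaError(f"missing sidecar header {side}")
    meta = json.loads(side.read_text())
    if path.suffix == ".raw":
        values = np.fromfile(path, dtype=np.uint8).reshape(meta["shape"])
    else:
        import SimpleITK as sitk

        values = sitk.GetArrayFromImage(sitk.ReadImage(str(path)))
    return StructureMask(include=values.astype(bool), name=meta.get("name", "structure"))


def read_dicom_rt_dose(path: str | Path) -> DoseGrid:
    """Optional adapter: read a DICOM RT Dose file as a physical dose grid."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    scale = float(getattr(ds, "DoseGridScaling", 1.0))
    values = ds.pixel_array.astype(float) * scale
    dz = float(ds.GridFrameOffsetVector[1] - ds.GridFrameOffsetVector[0]) \
        if len(getattr(ds, "GridFrameOffsetVector", [])) > 1 else 1.0
    spacing = (dz, float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
    origin = tuple(float(v) for v in reversed(ds.ImagePositionPatient))
    return DoseGrid(values=values, spacing=spacing, origin=origin,
                    dose_kind=DoseKind.PHYSICAL)
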
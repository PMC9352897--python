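"""Volumetric and tabular I/O for the body-composition pipeline.

CT volumes and semantic region-label volumes are exchanged as NIfTI files
(voxel spacing taken from the header), per-subject measurements as CSV.
CT and label volumes are assumed co-registered voxel-for-voxel; no
resampling is performed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "HU_MIN",
    "HU_MAX",
    "REGION_CODES",
    "REGION_NAMES",
    "CTVolume",
    "RegionLabelVolume",
    "InputFormatError",
    "MetadataError",
    "LegendError",
    "ValidationError",
    "GeometryError",
    "read_volume",
    "write_volume",
    "read_region_labels",
    "write_region_labels",
    "read_measurements",
    "write_measurements",
    "load_config",
]

# 12-bit CT convention; the air-exclusion window's floor (-1024 HU) sets the clamp.
HU_MIN = -1024.0
HU_MAX = 3071.0

#: Canonical semantic body-region legend (code -> name). Background is always 0.
REGION_CODES: dict[str, int] = {
    "background": 0,
    "subcutaneous_tissue": 1,
    "muscle": 2,
    "abdominal_cavity": 3,
    "thoracic_cavity": 4,
    "mediastinum": 5,
    "pericardium": 6,
    "bone": 7,
}
REGION_NAMES: dict[int, str] = {v: k for k, v in REGION_CODES.items()}


class InputFormatError(ValueError):
    """Raised when a file cannot be parsed as the expected format."""


class MetadataError(ValueError):
    """Raised when required header metadata (e.g. voxel spacing) is absent."""


class LegendError(ValueError):
    """Raised when a label volume contains codes missing from its legend."""


class ValidationError(ValueError):
    """Raised when a measurement table violates its invariants."""


class GeometryError(ValueError):
    """Raised when paired volumes disagree in shape."""


@dataclasses.dataclass(frozen=True)
class CTVolume:
    """A 3-D scalar field of Hounsfield units with voxel spacing in mm."""

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float32)
        if values.ndim != 3:
            raise InputFormatError(f"CT volume must be 3-D, got ndim={values.ndim}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise MetadataError(f"voxel spacing must be 3 positive lengths, got {spacing}")
        object.__setattr__(self, "values", np.clip(values, HU_MIN, HU_MAX))
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclasses.dataclass(frozen=True)
class RegionLabelVolume:
    """A 3-D categorical field of semantic body regions with its legend."""

    labels: np.ndarray
    legend: Mapping[int, str] = dataclasses.field(
        default_factory=lambda: dict(REGION_NAMES)
    )

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise InputFormatError(f"label volume must be 3-D, got ndim={labels.ndim}")
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.array_equal(labels, np.round(labels)):
                raise InputFormatError("region labels must be integer codes")
            labels = labels.astype(np.int32)
        legend = {int(k): str(v) for k, v in self.legend.items()}
        if legend.get(0, "background") != "background":
            raise LegendError("code 0 must map to 'background'")
        legend.setdefault(0, "background")
        present = np.unique(labels)
        missing = sorted(int(c) for c in present if int(c) not in legend)
        if missing:
            raise LegendError(f"label codes {missing} present in data but absent from legend")
        object.__setattr__(self, "labels", labels.astype(np.int32))
        object.__setattr__(self, "legend", legend)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def code_of(self, name: str) -> int:
        for code, n in self.legend.items():
            if n == name:
                return code
        raise LegendError(f"region {name!r} not in legend")


def _spacing_from_header(img: nib.Nifti1Image, path: Path) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise MetadataError(f"{path}: header lacks positive voxel spacing (pixdim={zooms})")
    return tuple(float(z) for z in zooms)


def read_volume(path: str | Path) -> CTVolume:
    """Read a CT volume from a NIfTI file, clamping HU to [-1024, 3071]."""
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise InputFormatError(f"cannot read {path} as a volumetric image: {exc}") from exc
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return CTVolume(values=data, spacing=_spacing_from_header(img, path))


def write_volume(vol: CTVolume, path: str | Path) -> None:
    """Write a CT volume as NIfTI; spacing goes into the header zooms/affine."""
    affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(vol.values.astype(np.float32), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(Path(path)))


def read_region_labels(
    path: str | Path, legend: Mapping[int, str] | None = None
) -> RegionLabelVolume:
    """Read a semantic region-label volume and validate it against ``legend``."""
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise InputFormatError(f"cannot read {path} as a volumetric image: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if legend is None:
        legend = dict(REGION_NAMES)
    return RegionLabelVolume(labels=data, legend=legend)


def write_region_labels(regions: RegionLabelVolume, path: str | Path) -> None:
    affine = np.eye(4)
    img = nib.Nifti1Image(regions.labels.astype(np.int16), affine)
    nib.save(img, str(Path(path)))


#: Columns of the per-subject measurement table.
RATIO_COLUMNS = ("bfr_bca", "bfr_dxa", "bfr_bia", "smr_bca", "smr_bia")
MEASUREMENT_COLUMNS = (
    "subject_id",
    "sex",
    "age",
    "height",
    "weight",
    "bmi",
) + RATIO_COLUMNS


def validate_measurements(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a measurement table in place and return it.

    Enforces unique subject ids, ratio columns in [0, 100] (missing allowed),
    and BMI consistency with weight/height to within 0.1 kg/m².
    """
    missing_cols = [c for c in ("subject_id", "sex", "bmi") if c not in table.columns]
    if missing_cols:
        raise ValidationError(f"measurement table lacks required columns {missing_cols}")
    dup = table["subject_id"][table["subject_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate subject_id values: {sorted(dup.unique().tolist())}")
    bad_sex = set(table["sex"].dropna().unique()) - {"male", "female"}
    if bad_sex:
        raise ValidationError(f"sex must be male/female, got {sorted(bad_sex)}")
    for col in RATIO_COLUMNS:
        if col not in table.columns:
            continue
        vals = pd.to_numeric(table[col], errors="coerce")
        out = table.index[vals.notna() & ((vals < 0) | (vals > 100))]
        if len(out):
            row = int(out[0])
            raise ValidationError(
                f"{col} outside [0, 100] in row {row} "
                f"(subject {table.loc[row, 'subject_id']}): {vals[row]}"
            )
        table[col] = vals
    if {"height", "weight", "bmi"} <= set(table.columns):
        h = pd.to_numeric(table["height"], errors="coerce") / 100.0
        w = pd.to_numeric(table["weight"], errors="coerce")
        b = pd.to_numeric(table["bmi"], errors="coerce")
        complete = h.notna() & w.notna() & b.notna()
        mismatch = complete & ((w / h**2 - b).abs() > 0.1)
        if mismatch.any():
            row = int(table.index[mismatch][0])
            raise ValidationError(
                f"bmi inconsistent with weight/height in row {row} "
                f"(subject {table.loc[row, 'subject_id']})"
            )
    return table


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a per-subject measurement CSV into a typed, validated DataFrame.

    Empty cells and "NA" are treated as missing, never as zero.
    """
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"no such file: {path}")
    table = pd.read_csv(
        path, na_values=["", "NA"], keep_default_na=True, dtype={"subject_id": str}
    )
    return validate_measurements(table)


def write_measurements(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(Path(path), index=False, na_rep="")


def load_config(path: str | Path) -> dict:
    """Load a configuration mapping from a YAML or TOML file."""
    path = Path(path)
    if path.suffix in {".toml", ".tml"}:
        import tomllib

        with open(path, "rb") as fh:
            return tomllib.load(fh)
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InputFormatError(f"{path}: config must be a mapping")
    return cfg
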
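"""Voxel-level tissue subclassification and BFR/SMR computation.

Tissues are identified by thresholding Hounsfield units within semantic
body regions: an adipose window of [-190, -30] HU and a muscle window of
[-29, 150] HU (inclusive at integer HU; at float HU the two windows meet
at -29.5). Adipose voxels are subclassified by region into SAT, VAT, IMAT,
EAT and PAT. Air-window voxels ([-1024, -800] HU) are excluded from the
body-voxel denominator, so

    BFR = 100 * (SAT + VAT + IMAT + EAT + PAT voxels) / body voxels
    SMR = 100 * muscle voxels / body voxels

with body voxels = non-background voxels minus excluded-air voxels.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np

from .io_core import (
    CTVolume,
    GeometryError,
    REGION_CODES,
    RegionLabelVolume,
    read_region_labels,
    read_volume,
)

__all__ = [
    "TISSUE_CODES",
    "TISSUE_NAMES",
    "ADIPOSE_TISSUES",
    "HUWindows",
    "DEFAULT_REGION_TISSUE_MAP",
    "TissueLabelVolume",
    "BodyCompositionReport",
    "DegenerateInputError",
    "classify_tissues",
    "quantify_tissues",
    "run_bca",
]

#: Tissue label codes used in TissueLabelVolume arrays.
TISSUE_CODES: dict[str, int] = {
    "background": 0,
    "SAT": 1,
    "VAT": 2,
    "IMAT": 3,
    "EAT": 4,
    "PAT": 5,
    "muscle": 6,
    "bone": 7,
    "excluded_air": 8,
    "unclassified": 9,
}
TISSUE_NAMES: dict[int, str] = {v: k for k, v in TISSUE_CODES.items()}
ADIPOSE_TISSUES = ("SAT", "VAT", "IMAT", "EAT", "PAT")


class DegenerateInputError(ValueError):
    """Raised when a volume has no body voxels to quantify."""


@dataclasses.dataclass(frozen=True)
class HUWindows:
    """Inclusive HU windows for tissue classes.

    At integer HU the printed windows [-190, -30] and [-29, 150] are
    contiguous; for float HU the adipose/muscle boundary is split at the
    midpoint -29.5 (adipose below, muscle at or above).
    """

    adipose: tuple[float, float] = (-190.0, -30.0)
    muscle: tuple[float, float] = (-29.0, 150.0)
    air: tuple[float, float] = (-1024.0, -800.0)

    def __post_init__(self) -> None:
        for name in ("adipose", "muscle", "air"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} window has lower > upper: ({lo}, {hi})")
        intervals = sorted([self.air, self.adipose, self.muscle])
        for (lo1, hi1), (lo2, hi2) in zip(intervals, intervals[1:]):
            if hi1 >= lo2 and not np.isclose(hi1 + 1, lo2):
                if hi1 >= lo2:
                    raise ValueError("HU windows must be pairwise disjoint")

    @property
    def adipose_muscle_split(self) -> float:
        """Float boundary between the adipose and muscle windows."""
        return (self.adipose[1] + self.muscle[0]) / 2.0


#: (region name, HU class) -> tissue. HU classes: "adipose", "muscle".
#: Adipose is subclassified by region; muscle-window HU counts as muscle
#: only inside the muscle region. Bone is taken from the bone region label
#: directly (no HU window is defined for bone).
DEFAULT_REGION_TISSUE_MAP: dict[tuple[str, str], str] = {
    ("subcutaneous_tissue", "adipose"): "SAT",
    ("abdominal_cavity", "adipose"): "VAT",
    ("muscle", "adipose"): "IMAT",
    ("pericardium", "adipose"): "EAT",
    ("mediastinum", "adipose"): "PAT",
    ("thoracic_cavity", "adipose"): "unclassified",
    ("bone", "adipose"): "unclassified",
    ("muscle", "muscle"): "muscle",
}


@dataclasses.dataclass(frozen=True)
class TissueLabelVolume:
    """3-D categorical field over the tissue classes of TISSUE_CODES."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise GeometryError(f"tissue labels must be 3-D, got ndim={labels.ndim}")
        object.__setattr__(self, "labels", labels.astype(np.int8))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]


@dataclasses.dataclass(frozen=True)
class BodyCompositionReport:
    """Per-scan voxel counts, volumes in litres, and the BFR/SMR biomarkers."""

    voxel_counts: dict[str, int]
    volumes_l: dict[str, float]
    body_voxels: int
    bfr: float
    smr: float
    spacing: tuple[float, float, float]

    def to_dict(self) -> dict:
        return {
            "voxel_counts": dict(self.voxel_counts),
            "volumes_l": {k: round(v, 9) for k, v in self.volumes_l.items()},
            "body_voxels": self.body_voxels,
            "bfr": self.bfr,
            "smr": self.smr,
            "spacing_mm": list(self.spacing),
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


def classify_tissues(
    ct: CTVolume,
    regions: RegionLabelVolume,
    windows: HUWindows | None = None,
    region_tissue_map: Mapping[tuple[str, str], str] | None = None,
    air_exclusion_scope: str = "global",
) -> TissueLabelVolume:
    """Assign each voxel exactly one tissue class.

    Precedence: background region -> background; air-window HU -> excluded_air
    (everywhere when ``air_exclusion_scope="global"``, only inside the
    abdominal cavity when ``"abdominal"``); bone region -> bone; adipose-window
    HU -> adipose subclass per region; muscle-window HU in the muscle region
    -> muscle; everything else -> unclassified.
    """
    windows = windows or HUWindows()
    ttmap = dict(DEFAULT_REGION_TISSUE_MAP)
    if region_tissue_map:
        ttmap.update(region_tissue_map)
    if air_exclusion_scope not in {"global", "abdominal"}:
        raise ValueError(f"air_exclusion_scope must be global|abdominal, got {air_exclusion_scope!r}")
    if ct.shape != regions.shape:
        raise GeometryError(f"CT shape {ct.shape} != region shape {regions.shape}")

    hu = ct.values
    reg = regions.labels
    name_of = regions.legend
    out = np.full(ct.shape, TISSUE_CODES["unclassified"], dtype=np.int8)

    background = reg == 0
    split = windows.adipose_muscle_split
    in_air = (hu >= windows.air[0]) & (hu <= windows.air[1])
    in_adipose = (hu >= windows.adipose[0]) & (hu < split)
    in_muscle = (hu >= split) & (hu <= windows.muscle[1])

    # Lowest precedence first; later assignments overwrite earlier ones.
    for code in np.unique(reg):
        code = int(code)
        if code == 0:
            continue
        region_name = name_of[code]
        region_mask = reg == code
        tissue = ttmap.get((region_name, "adipose"), "unclassified")
        out[region_mask & in_adipose] = TISSUE_CODES[tissue]
        tissue = ttmap.get((region_name, "muscle"), "unclassified")
        out[region_mask & in_muscle] = TISSUE_CODES[tissue]
    bone_region = reg == regions.code_of("bone") if "bone" in name_of.values() else np.zeros_like(background)
    out[bone_region] = TISSUE_CODES["bone"]
    if air_exclusion_scope == "global":
        out[in_air & ~background] = TISSUE_CODES["excluded_air"]
    else:
        abdominal = (
            reg == regions.code_of("abdominal_cavity")
            if "abdominal_cavity" in name_of.values()
            else np.zeros_like(background)
        )
        out[in_air & abdominal] = TISSUE_CODES["excluded_air"]
    out[background] = TISSUE_CODES["background"]
    return TissueLabelVolume(labels=out)


def quantify_tissues(
    labels: TissueLabelVolume, spacing: tuple[float, float, float]
) -> BodyCompositionReport:
    """Count voxels per tissue class and derive volumes, BFR and SMR.

    The denominator (body voxels) is all non-background voxels minus the
    excluded-air voxels; volumes are count x voxel volume, in litres.
    """
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 positive mm lengths, got {spacing}")
    counts_arr = np.bincount(labels.labels.ravel(), minlength=len(TISSUE_CODES))
    counts = {TISSUE_NAMES[i]: int(counts_arr[i]) for i in range(len(TISSUE_CODES))}
    non_background = int(counts_arr.sum()) - counts["background"]
    body_voxels = non_background - counts["excluded_air"]
    if body_voxels <= 0:
        raise DegenerateInputError(
            "no body voxels after air exclusion; cannot compute ratios"
        )
    voxel_l = float(np.prod(spacing)) / 1e6  # mm^3 -> L
    volumes = {name: counts[name] * voxel_l for name in TISSUE_CODES}
    adipose = sum(counts[t] for t in ADIPOSE_TISSUES)
    bfr = 100.0 * adipose / body_voxels
    smr = 100.0 * counts["muscle"] / body_voxels
    return BodyCompositionReport(
        voxel_counts=counts,
        volumes_l=volumes,
        body_voxels=body_voxels,
        bfr=bfr,
        smr=smr,
        spacing=spacing,
    )


def run_bca(
    ct_path: str | Path,
    seg_path: str | Path,
    legend: Mapping[int, str] | None = None,
    config: Mapping | None = None,
) -> BodyCompositionReport:
    """End-to-end per-scan body composition analysis from files on disk.

    Deterministic: identical inputs yield an identical report. ``config`` may
    override ``windows.adipose``/``windows.muscle``/``windows.air`` (each a
    2-list of HU) and ``air-exclusion-scope``.
    """
    config = dict(config or {})
    win_cfg = config.get("windows", {})
    windows = HUWindows(
        adipose=tuple(win_cfg.get("adipose", (-190.0, -30.0))),
        muscle=tuple(win_cfg.get("muscle", (-29.0, 150.0))),
        air=tuple(win_cfg.get("air", (-1024.0, -800.0))),
    )
    scope = config.get("air-exclusion-scope", "global")
    ct = read_volume(ct_path)
    regions = read_region_labels(seg_path, legend=legend)
    tissues = classify_tissues(ct, regions, windows=windows, air_exclusion_scope=scope)
    return quantify_tissues(tissues, ct.spacing)


def reference_classify(
    ct: CTVolume,
    regions: RegionLabelVolume,
    windows: HUWindows | None = None,
    air_exclusion_scope: str = "global",
) -> np.ndarray:
    """Brute-force per-voxel reference classifier (for verification only).

    Applies the classification rules one voxel at a time with plain Python
    branching; intentionally independent of the vectorised implementation.
    """
    windows = windows or HUWindows()
    split = windows.adipose_muscle_split
    out = np.empty(ct.shape, dtype=np.int8)
    name_of = regions.legend
    for idx in np.ndindex(*ct.shape):
        hu = float(ct.values[idx])
        region = name_of[int(regions.labels[idx])]
        if region == "background":
            tissue = "background"
        elif (
            windows.air[0] <= hu <= windows.air[1]
            and (air_exclusion_scope == "global" or region == "abdominal_cavity")
        ):
            tissue = "excluded_air"
        elif region == "bone":
            tissue = "bone"
        elif windows.adipose[0] <= hu < split:
            tissue = {
                "subcutaneous_tissue": "SAT",
                "abdominal_cavity": "VAT",
                "muscle": "IMAT",
                "pericardium": "EAT",
                "mediastinum": "PAT",
            }.get(region, "unclassified")
        elif split <= hu <= windows.muscle[1] and region == "muscle":
            tissue = "muscle"
        else:
            tissue = "unclassified"
        out[idx] = TISSUE_CODES[tissue]
    return out
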
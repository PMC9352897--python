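"""Synthetic phantoms and cohorts with known ground truth.

Two generators stand in for clinical data:

``generate_phantom`` builds a CT volume plus a consistent semantic
region-label volume whose tissue composition is known exactly by
construction: body voxels are partitioned into the requested tissue
counts, each voxel's HU is drawn strictly inside its tissue's HU window
(noise is truncated so no voxel ever crosses a window boundary), and the
region label matches the intended subclass (a SAT voxel carries the
subcutaneous-tissue region label, and so on). Quantifying a phantom must
therefore reproduce the ground-truth counts with zero error.

``generate_cohort`` simulates the paired multi-modality measurement table
of a method-comparison study: per subject a BMI group, a latent true BFR
and SMR drawn from per-group Gaussians, and per-modality readings equal to
the latent value plus a configurable bias (intercept + BMI-group slope)
plus Gaussian noise. The shared latent value induces the cross-method
correlation; the injected bias is what a Bland-Altman analysis should
recover.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import CTVolume, REGION_CODES, RegionLabelVolume
from .quantify import HUWindows

__all__ = [
    "PhantomSpec",
    "MethodErrorModel",
    "GroupGaussian",
    "CohortSpec",
    "PhantomSpecError",
    "generate_phantom",
    "generate_cohort",
    "DEFAULT_ERROR_MODELS",
    "BMI_GROUP_RANGES",
]

#: Sampling interval (strictly inside the HU window) and region label per tissue.
#: "other" emulates unclassified soft tissue (organ HU inside the muscle
#: window but outside the muscle region).
_TISSUE_RECIPES: dict[str, tuple[tuple[float, float], str]] = {
    "sat": ((-185.0, -35.0), "subcutaneous_tissue"),
    "vat": ((-185.0, -35.0), "abdominal_cavity"),
    "imat": ((-185.0, -35.0), "muscle"),
    "eat": ((-185.0, -35.0), "pericardium"),
    "pat": ((-185.0, -35.0), "mediastinum"),
    "adipose": ((-185.0, -35.0), "subcutaneous_tissue"),
    "muscle": ((-25.0, 145.0), "muscle"),
    "bone": ((250.0, 1200.0), "bone"),
    "air_pockets": ((-1000.0, -820.0), "abdominal_cavity"),
    "other": ((10.0, 140.0), "abdominal_cavity"),
}
_ADIPOSE_KEYS = {"sat", "vat", "imat", "eat", "pat", "adipose"}

#: Truncation bounds keeping noisy HU inside the classification window
#: (float windows: adipose [-190, -29.5), muscle [-29.5, 150], air
#: [-1024, -800]); a small margin keeps values off the exact boundary.
_TISSUE_BOUNDS: dict[str, tuple[float, float]] = {
    "sat": (-189.9, -29.6),
    "vat": (-189.9, -29.6),
    "imat": (-189.9, -29.6),
    "eat": (-189.9, -29.6),
    "pat": (-189.9, -29.6),
    "adipose": (-189.9, -29.6),
    "muscle": (-29.4, 149.9),
    "bone": (200.0, 1500.0),
    "air_pockets": (-1023.9, -800.1),
    "other": (1.0, 149.9),
}


class PhantomSpecError(ValueError):
    """Raised when a phantom specification cannot be realised."""


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Specification of a synthetic CT phantom.

    ``target_fractions`` maps tissue keys (sat, vat, imat, eat, pat,
    adipose, muscle, bone, air_pockets, other) to fractions of body voxels;
    fractions must be non-negative and sum to at most 1 (the remainder
    becomes unclassified soft tissue). ``region_layout`` is
    "nested_cylinders" (torso-like: subcutaneous shell around muscle around
    an abdominal core, ordered by radius) or "voxel_list" (body voxels given
    explicitly for hand-built fixtures).
    """

    shape: tuple[int, int, int] = (32, 32, 16)
    spacing: tuple[float, float, float] = (2.0, 2.0, 5.0)
    target_fractions: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"sat": 0.18, "vat": 0.12, "imat": 0.03,
                                 "eat": 0.01, "pat": 0.01, "muscle": 0.30,
                                 "bone": 0.10, "air_pockets": 0.05}
    )
    region_layout: str = "nested_cylinders"
    body_voxels: Sequence[tuple[int, int, int]] | None = None
    hu_noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise PhantomSpecError(f"shape must be 3 positive ints, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise PhantomSpecError(f"spacing must be positive, got {self.spacing}")
        unknown = set(self.target_fractions) - set(_TISSUE_RECIPES)
        if unknown:
            raise PhantomSpecError(f"unknown tissue keys: {sorted(unknown)}")
        fracs = list(self.target_fractions.values())
        if any(f < 0 for f in fracs):
            raise PhantomSpecError("target fractions must be >= 0")
        if sum(fracs) > 1 + 1e-9:
            raise PhantomSpecError(f"target fractions sum to {sum(fracs):.4f} > 1")
        if self.hu_noise_sd < 0:
            raise PhantomSpecError("hu_noise_sd must be >= 0")
        if self.region_layout not in {"nested_cylinders", "voxel_list"}:
            raise PhantomSpecError(f"unknown region_layout {self.region_layout!r}")
        if self.region_layout == "voxel_list" and not self.body_voxels:
            raise PhantomSpecError("voxel_list layout requires body_voxels")


def _body_order_nested_cylinders(shape: tuple[int, int, int]) -> np.ndarray:
    """Flat indices of body voxels, outermost (largest radius) first.

    The body is a cylinder along the z-axis of radius 0.45*min(nx, ny);
    ordering by radius descending makes contiguous tissue chunks form
    nested shells (subcutaneous outside, core inside).
    """
    nx, ny, nz = shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    r2 = (x - cx) ** 2 + (y - cy) ** 2
    radius = 0.45 * min(nx, ny)
    inside = (r2 <= radius**2).ravel()
    # stable ordering: radius descending, then lexicographic
    order2d = np.argsort(-r2, axis=None, kind="stable")
    order2d = order2d[inside[order2d]]
    # expand each in-body column to its nz voxels (C-order flat indices)
    return (order2d[:, None] * nz + np.arange(nz)[None, :]).ravel().astype(np.int64)


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[CTVolume, RegionLabelVolume, dict[str, int]]:
    """Build a (CT, region-label, ground-truth) triple from a spec.

    Ground truth maps each requested tissue key to its realised voxel
    count, plus ``body`` (all body voxels) and the derived ``bfr``/``smr``
    the quantification stage must reproduce exactly.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.shape)

    if spec.region_layout == "voxel_list":
        body = np.asarray(
            [np.ravel_multi_index(tuple(v), shape) for v in spec.body_voxels],
            dtype=np.int64,
        )
        if len(np.unique(body)) != len(body):
            raise PhantomSpecError("body_voxels contains duplicates")
    else:
        body = _body_order_nested_cylinders(shape)
    n_body = len(body)
    if n_body == 0:
        raise PhantomSpecError("phantom has no body voxels")

    keys = list(spec.target_fractions)
    counts = {k: int(round(spec.target_fractions[k] * n_body)) for k in keys}
    if sum(counts.values()) > n_body:
        raise PhantomSpecError(
            f"rounded tissue counts {counts} exceed {n_body} body voxels"
        )

    hu = np.full(shape, -1024.0, dtype=np.float32).ravel()
    reg = np.zeros(shape, dtype=np.int32).ravel()

    pos = 0
    assigned: dict[str, np.ndarray] = {}
    for key in keys:
        n = counts[key]
        voxels = body[pos : pos + n]
        pos += n
        assigned[key] = voxels
        (lo, hi), region = _TISSUE_RECIPES[key]
        vals = rng.uniform(lo, hi, size=n)
        if spec.hu_noise_sd > 0:
            vals = vals + rng.normal(0.0, spec.hu_noise_sd, size=n)
            blo, bhi = _TISSUE_BOUNDS[key]
            vals = np.clip(vals, blo, bhi)
        hu[voxels] = vals
        reg[voxels] = REGION_CODES[region]
    # remainder: unclassified soft tissue in the abdominal core
    rest = body[pos:]
    if len(rest):
        (lo, hi), region = _TISSUE_RECIPES["other"]
        vals = rng.uniform(lo, hi, size=len(rest))
        if spec.hu_noise_sd > 0:
            vals = np.clip(
                vals + rng.normal(0.0, spec.hu_noise_sd, size=len(rest)),
                *_TISSUE_BOUNDS["other"],
            )
        hu[rest] = vals
        reg[rest] = REGION_CODES[region]

    truth = dict(counts)
    truth["body"] = n_body
    n_air = counts.get("air_pockets", 0)
    denom = n_body - n_air
    adipose = sum(counts.get(k, 0) for k in _ADIPOSE_KEYS)
    truth["bfr"] = 100.0 * adipose / denom if denom else float("nan")
    truth["smr"] = 100.0 * counts.get("muscle", 0) / denom if denom else float("nan")

    ct = CTVolume(values=hu.reshape(shape), spacing=spec.spacing)
    regions = RegionLabelVolume(labels=reg.reshape(shape))
    return ct, regions, truth


# --- cohort simulation -----------------------------------------------------

#: BMI sampling ranges per group index (healthy, overweight, obese).
BMI_GROUP_RANGES = ((18.5, 25.0), (25.0, 30.0), (30.0, 40.0))
_GROUP_LABELS = ("healthy", "overweight", "obese")


@dataclasses.dataclass(frozen=True)
class MethodErrorModel:
    """Additive error of one modality's reading of a latent true ratio.

    reading = latent + bias_intercept + bias_bmi_slope * group_index + noise,
    with group_index 0/1/2 for healthy/overweight/obese and noise Gaussian
    with sd ``noise_sd`` (percentage points).
    """

    bias_intercept: float = 0.0
    bias_bmi_slope: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclasses.dataclass(frozen=True)
class GroupGaussian:
    """Per-BMI-group Gaussian (mean, sd) for a latent true ratio, in %."""

    means: tuple[float, float, float]
    sds: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.sds):
            raise ValueError("sds must be >= 0")


#: Default latent distributions: CT-derived group means +/- sd for BFR and
#: SMR in healthy / overweight / obese groups.
DEFAULT_TRUE_BFR = GroupGaussian(means=(32.43, 40.36, 49.79), sds=(11.25, 7.04, 7.65))
DEFAULT_TRUE_SMR = GroupGaussian(means=(27.84, 26.57, 23.65), sds=(4.90, 4.19, 5.17))

#: Default per-column error models. The CT-based BCA reading is the latent
#: value itself; DXA/BIA BFR biases grow with BMI group (fitted to the
#: observed per-group mean differences: BCA-DXA of 3.16/5.34/8.43 and
#: BCA-BIA of 3.58/5.02/9.96 percentage points); the BIA SMR reading sits
#: a flat ~6.3 points above the CT value (group differences non-monotone).
DEFAULT_ERROR_MODELS: dict[str, MethodErrorModel] = {
    "bfr_bca": MethodErrorModel(),
    "bfr_dxa": MethodErrorModel(bias_intercept=-3.16, bias_bmi_slope=-2.63, noise_sd=0.8),
    "bfr_bia": MethodErrorModel(bias_intercept=-3.58, bias_bmi_slope=-3.19, noise_sd=1.12),
    "smr_bca": MethodErrorModel(),
    "smr_bia": MethodErrorModel(bias_intercept=6.34, bias_bmi_slope=0.0, noise_sd=0.85),
}


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Specification of a simulated method-comparison cohort.

    ``bmi_group_weights`` are relative sizes of the healthy/overweight/obese
    groups (the emulated design is 22/35/17); with ``stratified_exact`` the
    realised group sizes are exactly proportional, otherwise multinomial.
    """

    n_subjects: int = 74
    bmi_group_weights: tuple[float, float, float] = (22.0, 35.0, 17.0)
    sex_ratio: float = 0.514  # fraction male
    true_bfr: GroupGaussian = DEFAULT_TRUE_BFR
    true_smr: GroupGaussian = DEFAULT_TRUE_SMR
    error_models: Mapping[str, MethodErrorModel] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_ERROR_MODELS)
    )
    stratified_exact: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if sum(self.bmi_group_weights) <= 0 or any(w < 0 for w in self.bmi_group_weights):
            raise ValueError("bmi_group_weights must be nonnegative with positive sum")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")


def _allocate_groups(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    w = np.asarray(spec.bmi_group_weights, dtype=float)
    p = w / w.sum()
    n = spec.n_subjects
    if spec.stratified_exact:
        # largest-remainder apportionment to exactly n
        raw = p * n
        base = np.floor(raw).astype(int)
        short = n - base.sum()
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
        groups = np.repeat(np.arange(3), base)
    else:
        groups = rng.choice(3, size=n, p=p)
    return groups


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a paired BCA/DXA/BIA measurement table.

    Fully reproducible from ``spec.seed``; readings are clipped to
    [0, 100] after bias and noise so they remain valid percentages.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    groups = _allocate_groups(spec, rng)

    lo = np.array([r[0] for r in BMI_GROUP_RANGES])
    hi = np.array([r[1] for r in BMI_GROUP_RANGES])
    bmi = rng.uniform(lo[groups], hi[groups])
    sex = np.where(rng.random(n) < spec.sex_ratio, "male", "female")
    age = np.clip(rng.normal(64.0, 11.5, size=n), 30.0, 95.0)
    height = np.clip(rng.normal(171.0, 10.0, size=n), 140.0, 205.0)
    weight = bmi * (height / 100.0) ** 2

    latent_bfr = rng.normal(
        np.asarray(spec.true_bfr.means)[groups], np.asarray(spec.true_bfr.sds)[groups]
    )
    latent_smr = rng.normal(
        np.asarray(spec.true_smr.means)[groups], np.asarray(spec.true_smr.sds)[groups]
    )
    latent_bfr = np.clip(latent_bfr, 0.0, 100.0)
    latent_smr = np.clip(latent_smr, 0.0, 100.0)

    table = pd.DataFrame(
        {
            "subject_id": [f"S{i+1:04d}" for i in range(n)],
            "sex": sex,
            "age": np.round(age, 1),
            "height": np.round(height, 1),
            "weight": np.round(weight, 2),
            "bmi": np.round(bmi, 2),
        }
    )
    # recompute BMI from the rounded height/weight so the table is
    # self-consistent to within the validation tolerance
    table["bmi"] = np.round(table["weight"] / (table["height"] / 100.0) ** 2, 2)

    for column, model in spec.error_models.items():
        latent = latent_bfr if column.startswith("bfr") else latent_smr
        reading = (
            latent
            + model.bias_intercept
            + model.bias_bmi_slope * groups
            + (rng.normal(0.0, model.noise_sd, size=n) if model.noise_sd > 0 else 0.0)
        )
        table[column] = np.clip(reading, 0.0, 100.0)
    table["bmi_group"] = np.asarray(_GROUP_LABELS, dtype=object)[groups]
    return table
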
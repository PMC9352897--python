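"""Pairwise method-agreement statistics.

For two modalities measuring the same percentage biomarker this module
computes:

* Pearson's product-moment r with the two-sided non-correlation p-value;
* Lin's concordance correlation coefficient

      rho_c = 2*s_xy / (s_x^2 + s_y^2 + (x_bar - y_bar)^2)

  with n-denominator (biased) moments as in Lin's original definition, and
  a 95% confidence interval from the Fisher z-transform with Lin's
  asymptotic standard error;
* Bland-Altman statistics: mean difference, limits of agreement
  mean +/- 1.96*sd (sample sd, n-1), t-based confidence intervals for the
  mean (SE = sd/sqrt(n)) and for each limit (SE = sd*sqrt(3/n));
* Shapiro-Wilk normality screening.

``compare_methods`` applies these to a measurement table for one pair of
modalities, overall and per stratum (BMI group or sex), dropping
incomplete pairs per comparison. Differences are always first-listed
method minus second-listed method.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedSample",
    "AgreementResult",
    "BlandAltmanResult",
    "DegenerateSampleError",
    "pearson_with_p",
    "lin_ccc",
    "bland_altman",
    "shapiro_wilk",
    "compare_methods",
]

logger = logging.getLogger(__name__)


class DegenerateSampleError(ValueError):
    """Raised for samples too small or too degenerate to analyse."""


@dataclasses.dataclass(frozen=True)
class PairedSample:
    """Two equal-length vectors of paired measurements, no missing values."""

    x: np.ndarray
    y: np.ndarray
    labels: tuple[str, str] = ("method_x", "method_y")

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
            raise DegenerateSampleError("x and y must be equal-length 1-D vectors")
        if len(x) < 3:
            raise DegenerateSampleError(f"need at least 3 pairs, got {len(x)}")
        if np.isnan(x).any() or np.isnan(y).any():
            raise DegenerateSampleError("missing values must be dropped upstream")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return len(self.x)


@dataclasses.dataclass(frozen=True)
class AgreementResult:
    r: float
    p: float
    ccc: float
    ccc_ci: tuple[float, float]
    n: int

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "p": self.p,
            "ccc": self.ccc,
            "ccc_ci": list(self.ccc_ci),
            "n": self.n,
        }


@dataclasses.dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci_mean: tuple[float, float]
    ci_loa_low: tuple[float, float]
    ci_loa_high: tuple[float, float]
    means: np.ndarray
    diffs: np.ndarray
    n: int

    def to_dict(self) -> dict:
        return {
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "ci_mean": list(self.ci_mean),
            "ci_loa_low": list(self.ci_loa_low),
            "ci_loa_high": list(self.ci_loa_high),
            "n": self.n,
        }


def _check_non_constant(sample: PairedSample) -> None:
    if np.ptp(sample.x) == 0 or np.ptp(sample.y) == 0:
        raise DegenerateSampleError("constant vector: correlation undefined")


def pearson_with_p(sample: PairedSample) -> tuple[float, float]:
    """Pearson product-moment r with the two-sided non-correlation p-value."""
    _check_non_constant(sample)
    res = stats.pearsonr(sample.x, sample.y)
    return float(res.statistic), float(res.pvalue)


def lin_ccc(sample: PairedSample, ci_level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Lin's concordance correlation coefficient with a Fisher-z CI.

    Uses n-denominator moments, so at small n the result differs from a
    version built on sample (n-1) variances; the value always satisfies
    |rho_c| <= |r|, with equality iff means and variances agree.
    """
    _check_non_constant(sample)
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must be in (0, 1)")
    x, y, n = sample.x, sample.y, sample.n
    mx, my = x.mean(), y.mean()
    sx2 = np.var(x)  # n-denominator
    sy2 = np.var(y)
    sxy = np.mean((x - mx) * (y - my))
    ccc = 2.0 * sxy / (sx2 + sy2 + (mx - my) ** 2)

    r = sxy / math.sqrt(sx2 * sy2)
    u = (mx - my) / (sx2 * sy2) ** 0.25  # location-shift relative to scale
    # Lin's asymptotic variance of the z-transformed ccc
    if abs(ccc) >= 1.0 or abs(r) < 1e-12:
        ci = (ccc, ccc)
    else:
        one_m_ccc2 = 1.0 - ccc**2
        var_z = (
            (1.0 - r**2) * ccc**2 / (one_m_ccc2 * r**2)
            + 2.0 * ccc**3 * (1.0 - ccc) * u**2 / (r * one_m_ccc2**2)
            - ccc**4 * u**4 / (2.0 * r**2 * one_m_ccc2**2)
        ) / (n - 2)
        se_z = math.sqrt(max(var_z, 0.0))
        z = math.atanh(ccc)
        zq = stats.norm.ppf(0.5 + ci_level / 2.0)
        ci = (math.tanh(z - zq * se_z), math.tanh(z + zq * se_z))
    return float(ccc), (float(ci[0]), float(ci[1]))


def bland_altman(sample: PairedSample, ci_level: float = 0.95) -> BlandAltmanResult:
    """Bland-Altman statistics for differences d = x - y (labels order)."""
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must be in (0, 1)")
    x, y, n = sample.x, sample.y, sample.n
    d = x - y
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low = mean_diff - 1.96 * sd
    loa_high = mean_diff + 1.96 * sd
    tq = stats.t.ppf(0.5 + ci_level / 2.0, df=n - 1)
    se_mean = sd / math.sqrt(n)
    se_loa = sd * math.sqrt(3.0 / n)
    return BlandAltmanResult(
        mean_diff=mean_diff,
        sd_diff=sd,
        loa_low=float(loa_low),
        loa_high=float(loa_high),
        ci_mean=(mean_diff - tq * se_mean, mean_diff + tq * se_mean),
        ci_loa_low=(loa_low - tq * se_loa, loa_low + tq * se_loa),
        ci_loa_high=(loa_high - tq * se_loa, loa_high + tq * se_loa),
        means=(x + y) / 2.0,
        diffs=d,
        n=n,
    )


def shapiro_wilk(values: Iterable[float]) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value for 3 <= n <= 5000."""
    v = np.asarray(list(values), dtype=float)
    if v.ndim != 1 or not 3 <= len(v) <= 5000:
        raise DegenerateSampleError(
            f"Shapiro-Wilk requires 3 <= n <= 5000, got n={v.size}"
        )
    if np.ptp(v) == 0:
        raise DegenerateSampleError("constant sample: W undefined")
    res = stats.shapiro(v)
    return float(res.statistic), float(res.pvalue)


def _strata(table: pd.DataFrame, stratify: str) -> list[tuple[str, pd.DataFrame]]:
    out: list[tuple[str, pd.DataFrame]] = [("overall", table)]
    if stratify == "none":
        return out
    if stratify == "bmi":
        from .report import assign_bmi_group

        groups = table["bmi"].map(assign_bmi_group)
        order = ["underweight", "healthy", "overweight", "obese"]
    elif stratify == "sex":
        groups = table["sex"]
        order = ["male", "female"]
    else:
        raise ValueError(f"stratify must be none|bmi|sex, got {stratify!r}")
    for name in order:
        sub = table[groups == name]
        if len(sub):
            out.append((name, sub))
    return out


def compare_methods(
    table: pd.DataFrame,
    metric: str,
    pair: Sequence[str],
    stratify: str = "none",
    ci_level: float = 0.95,
) -> list[tuple[str, AgreementResult, BlandAltmanResult]]:
    """Agreement analysis of one modality pair, overall and per stratum.

    ``metric`` is "bfr" or "smr"; ``pair`` names two methods (e.g.
    ("bca", "dxa")) resolved to columns ``{metric}_{method}``. Pairs with a
    missing value in either column are dropped per stratum
    (pairwise-complete deletion); strata with fewer than 3 complete pairs
    are skipped with a warning. Differences are pair[0] minus pair[1].
    """
    if metric not in {"bfr", "smr"}:
        raise ValueError(f"metric must be bfr|smr, got {metric!r}")
    a, b = pair
    col_x, col_y = f"{metric}_{a}", f"{metric}_{b}"
    for col in (col_x, col_y):
        if col not in table.columns:
            raise KeyError(f"column {col!r} not in measurement table")
    results = []
    for name, sub in _strata(table, stratify):
        complete = sub[[col_x, col_y]].dropna()
        if len(complete) < 3:
            logger.warning(
                "stratum %r skipped: only %d complete %s/%s pairs",
                name, len(complete), col_x, col_y,
            )
            continue
        sample = PairedSample(
            x=complete[col_x].to_numpy(),
            y=complete[col_y].to_numpy(),
            labels=(a, b),
        )
        try:
            r, p = pearson_with_p(sample)
            ccc, ci = lin_ccc(sample, ci_level=ci_level)
        except DegenerateSampleError as exc:
            logger.warning("stratum %r skipped: %s", name, exc)
            continue
        agreement = AgreementResult(r=r, p=p, ccc=ccc, ccc_ci=ci, n=sample.n)
        ba = bland_altman(sample, ci_level=ci_level)
        results.append((name, agreement, ba))
    return results
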
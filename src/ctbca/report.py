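"""Cohort description, BMI stratification and study-report assembly.

BMI groups use the WHO half-open cut points: underweight < 18.5, healthy
[18.5, 25), overweight [25, 30), obese >= 30 kg/m^2.
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Mapping

import numpy as np
import pandas as pd

from .agreement import DegenerateSampleError, compare_methods, shapiro_wilk
from .io_core import RATIO_COLUMNS, ValidationError

__all__ = [
    "BMI_CUT_POINTS",
    "BMI_GROUP_LABELS",
    "assign_bmi_group",
    "summarize_cohort",
    "run_study",
    "study_report_to_json",
]

BMI_CUT_POINTS = (18.5, 25.0, 30.0)
BMI_GROUP_LABELS = ("underweight", "healthy", "overweight", "obese")

_SUMMARY_VARIABLES = ("age", "weight", "height", "bmi") + RATIO_COLUMNS

#: Modality pairs analysed per metric; BCA is always listed first so the
#: Bland-Altman difference direction is CT minus reference.
DEFAULT_COMPARISONS = {
    "bfr": (("bca", "dxa"), ("bca", "bia"), ("dxa", "bia")),
    "smr": (("bca", "bia"),),
}


def assign_bmi_group(bmi: float, cut_points: tuple[float, float, float] = BMI_CUT_POINTS) -> str:
    """Map a BMI (kg/m^2) to its group label using half-open intervals."""
    if not math.isfinite(bmi) or bmi <= 0:
        raise ValidationError(f"BMI must be positive and finite, got {bmi}")
    if not (cut_points[0] < cut_points[1] < cut_points[2]):
        raise ValueError("cut points must be strictly increasing")
    if bmi < cut_points[0]:
        return "underweight"
    if bmi < cut_points[1]:
        return "healthy"
    if bmi < cut_points[2]:
        return "overweight"
    return "obese"


def summarize_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Per-BMI-group mean, sample sd (n-1) and n for every study variable.

    Rows are (group, variable); missing values are excluded per variable.
    Sex is summarised as counts. A single observation has sd reported as
    missing, not zero.
    """
    if table is None or len(table) == 0:
        raise ValidationError("cannot summarise an empty table")
    groups = table["bmi"].map(assign_bmi_group)
    rows = []
    labels = [g for g in BMI_GROUP_LABELS if (groups == g).any()]
    for label in labels + ["all"]:
        sub = table if label == "all" else table[groups == label]
        n_group = len(sub)
        rows.append({"group": label, "variable": "n", "mean": n_group, "sd": np.nan, "n": n_group})
        for sex in ("male", "female"):
            cnt = int((sub["sex"] == sex).sum())
            rows.append({"group": label, "variable": f"{sex}_n", "mean": cnt, "sd": np.nan, "n": n_group})
        for var in _SUMMARY_VARIABLES:
            if var not in sub.columns:
                continue
            vals = pd.to_numeric(sub[var], errors="coerce").dropna()
            rows.append(
                {
                    "group": label,
                    "variable": var,
                    "mean": float(vals.mean()) if len(vals) else np.nan,
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                    "n": int(len(vals)),
                }
            )
    return pd.DataFrame(rows)


@dataclasses.dataclass(frozen=True)
class StudyReport:
    """Full study output: cohort summary, agreement results, normality screen."""

    summary: pd.DataFrame
    comparisons: dict  # (metric, pair, stratify) -> list of per-stratum results
    normality: dict  # (column, group) -> {"W": ..., "p": ..., "n": ...}
    config: dict


def run_study(
    table: pd.DataFrame,
    config: Mapping | None = None,
) -> StudyReport:
    """Run the complete analysis on a measurement table.

    Deterministic given the table: Table-1-style summary, every default
    modality comparison (overall, per BMI group and per sex), and a
    Shapiro-Wilk normality screen per modality column within each BMI
    group. The config echo records cut points and CI level for provenance.
    """
    config = dict(config or {})
    ci_level = float(config.get("ci_level", 0.95))
    summary = summarize_cohort(table)

    comparisons: dict = {}
    for metric, pairs in DEFAULT_COMPARISONS.items():
        for pair in pairs:
            cols = {f"{metric}_{m}" for m in pair}
            if not cols <= set(table.columns):
                continue
            if table[list(cols)].dropna().shape[0] < 3:
                continue
            for stratify in ("bmi", "sex"):
                results = compare_methods(
                    table, metric, pair, stratify=stratify, ci_level=ci_level
                )
                comparisons[(metric, pair, stratify)] = results

    normality: dict = {}
    groups = table["bmi"].map(assign_bmi_group)
    for col in RATIO_COLUMNS:
        if col not in table.columns:
            continue
        for label in BMI_GROUP_LABELS:
            vals = pd.to_numeric(table.loc[groups == label, col], errors="coerce").dropna()
            if len(vals) < 3:
                continue
            try:
                w, p = shapiro_wilk(vals.to_numpy())
            except DegenerateSampleError:
                continue
            normality[(col, label)] = {"W": w, "p": p, "n": int(len(vals))}

    echo = {
        "ci_level": ci_level,
        "bmi_cut_points": list(BMI_CUT_POINTS),
        "hu_windows": config.get("windows", {"adipose": [-190, -30], "muscle": [-29, 150], "air": [-1024, -800]}),
    }
    return StudyReport(summary=summary, comparisons=comparisons, normality=normality, config=echo)


def study_report_to_json(report: StudyReport, indent: int = 2) -> str:
    """Serialise a StudyReport to deterministic JSON."""
    payload = {
        "config": report.config,
        "summary": report.summary.replace({np.nan: None}).to_dict(orient="records"),
        "comparisons": {
            f"{metric}:{a}-vs-{b}:{stratify}": [
                {
                    "stratum": name,
                    "agreement": agr.to_dict(),
                    "bland_altman": ba.to_dict(),
                }
                for name, agr, ba in results
            ]
            for (metric, (a, b), stratify), results in report.comparisons.items()
        },
        "normality": {
            f"{col}:{group}": stats_ for (col, group), stats_ in report.normality.items()
        },
    }
    return json.dumps(payload, indent=indent, sort_keys=True, allow_nan=True)
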
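"""Behavioral phenotyping after chronic social defeat stress.

Defeated mice are split into stress-susceptible and stress-resilient groups
from their social interaction (SI) ratio: the time spent in the interaction
zone with a social target present, divided by the time spent there with the
target absent, x100. Because SI ratios are right-skewed, outlier removal and
the classification border are computed on natural-log-transformed ratios;
the border — the control group's log-mean minus one log-SD — is
back-transformed to the percent scale for reporting.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateTableError,
    InsufficientDataError,
    UndefinedRatioError,
)
from .types import BehavioralRecord, PhenotypeCall

__all__ = [
    "compute_si_ratio",
    "remove_si_outliers",
    "classify_defeated",
    "susceptibility_percentage",
    "strain_phenotype_chi2",
    "modified_zscore_outliers",
    "weight_trajectory",
    "phenotype_cohort",
]


def compute_si_ratio(record: BehavioralRecord) -> float:
    """SI ratio on the percent scale: 100 x target time / no-target time.

    Raises
    ------
    UndefinedRatioError
        If the no-target time is zero (the mouse is excluded with reason).
    """
    if record.t_iz_no_target == 0:
        raise UndefinedRatioError(
            f"mouse {record.mouse_id}: no-target interaction time is zero, SI ratio undefined"
        )
    return 100.0 * record.t_iz_target / record.t_iz_no_target


def remove_si_outliers(ratios: Sequence[float]) -> np.ndarray:
    """Flag SI ratios whose log lies more than 3 IQRs from the log-median.

    Returns a boolean mask (True = outlier). A zero IQR (e.g. all values
    identical) flags nothing.
    """
    r = np.asarray(ratios, dtype=float)
    if r.size < 4:
        raise InsufficientDataError(f"need >= 4 ratios to define quartiles, got {r.size}")
    if (r <= 0).any():
        raise ValueError("SI ratios must be positive for log transformation")
    logr = np.log(r)
    med = np.median(logr)
    q1, q3 = np.percentile(logr, [25, 75])
    iqr = q3 - q1
    if iqr == 0:
        return np.zeros(r.size, dtype=bool)
    return np.abs(logr - med) > 3.0 * iqr


def classify_defeated(
    control_ratios: Sequence[float], defeated_ratios: Sequence[float]
) -> tuple[list[str], float]:
    """Label defeated mice susceptible/resilient against a control-derived border.

    The border is exp(mean(log controls) - SD(log controls)), reported on the
    percent scale. Defeated mice strictly below the border are susceptible;
    mice at or above it (resembling controls) are resilient.

    Returns ``(labels, border)``.
    """
    c = np.asarray(control_ratios, dtype=float)
    d = np.asarray(defeated_ratios, dtype=float)
    if c.size < 2:
        raise InsufficientDataError(f"need >= 2 control ratios, got {c.size}")
    if (c <= 0).any() or (d <= 0).any():
        raise ValueError("SI ratios must be positive")
    logc = np.log(c)
    border = float(np.exp(logc.mean() - logc.std(ddof=1)))
    labels = ["susceptible" if x < border else "resilient" for x in d]
    return labels, border


def susceptibility_percentage(n_susceptible: int, n_resilient: int) -> int:
    """Percent of defeated mice classified susceptible, rounded to integer."""
    total = n_susceptible + n_resilient
    if total == 0:
        raise InsufficientDataError("both phenotype counts are zero")
    if n_susceptible < 0 or n_resilient < 0:
        raise ValueError("counts must be non-negative")
    return int(round(100.0 * n_susceptible / total))


def strain_phenotype_chi2(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 strain x phenotype table.

    Returns ``(statistic, p_value)``.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise DegenerateTableError("negative cell counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DegenerateTableError("a row or column margin is zero")
    if t.sum() == 0:
        raise DegenerateTableError("empty table")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), float(p)


def modified_zscore_outliers(values: Sequence[float], threshold: float = 3.5) -> np.ndarray:
    """Flag values with modified Z-score |0.6745 (x - median) / MAD| > threshold.

    A zero MAD makes the score undefined; the function then flags nothing and
    warns, rather than erroring out on degenerate (e.g. constant) input.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise InsufficientDataError(f"need >= 3 values, got {v.size}")
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad == 0:
        warnings.warn("MAD is zero; modified Z-score undefined, no outliers flagged")
        return np.zeros(v.size, dtype=bool)
    z = 0.6745 * (v - med) / mad
    return np.abs(z) > threshold


def weight_trajectory(record: BehavioralRecord) -> np.ndarray:
    """Percent change from baseline body weight for each subsequent day.

    Day 1 is the baseline; the returned series has one entry per later day:
    100 x (w_day - w_day1) / w_day1.
    """
    if record.weights is None or len(record.weights) < 2:
        raise InsufficientDataError(
            f"mouse {record.mouse_id}: need >= 2 weight records with a baseline"
        )
    w = np.asarray(record.weights, dtype=float)
    if w[0] <= 0:
        raise InsufficientDataError(f"mouse {record.mouse_id}: baseline weight must be positive")
    return 100.0 * (w[1:] - w[0]) / w[0]


def phenotype_cohort(records: Iterable[BehavioralRecord]) -> pd.DataFrame:
    """Run the full classification on one strain's cohort of records.

    Computes SI ratios, excludes undefined ratios, flags log-IQR outliers
    jointly across control and defeated mice, derives the control border, and
    labels every mouse. Returns a table with columns
    ``mouse_id, strain, group, si_ratio, outlier, label, border``.
    """
    recs = list(records)
    strains = {r.strain for r in recs}
    if len(strains) != 1:
        raise ValueError(f"phenotype_cohort expects a single strain, got {sorted(strains)}")

    calls: list[PhenotypeCall] = []
    ratios, idx_ok = [], []
    for i, r in enumerate(recs):
        try:
            ratios.append(compute_si_ratio(r))
            idx_ok.append(i)
        except UndefinedRatioError:
            calls.append(PhenotypeCall(r.mouse_id, float("nan"), False, "excluded"))

    mask = remove_si_outliers(ratios)
    kept = [(recs[i], ratio) for (i, ratio), out in zip(zip(idx_ok, ratios), mask) if not out]
    for (i, ratio), out in zip(zip(idx_ok, ratios), mask):
        if out:
            calls.append(PhenotypeCall(recs[i].mouse_id, ratio, True, "excluded"))

    controls = [(r, x) for r, x in kept if r.group == "control"]
    defeated = [(r, x) for r, x in kept if r.group == "defeated"]
    labels, border = classify_defeated([x for _, x in controls], [x for _, x in defeated])
    for r, x in controls:
        calls.append(PhenotypeCall(r.mouse_id, x, False, "control"))
    for (r, x), lab in zip(defeated, labels):
        calls.append(PhenotypeCall(r.mouse_id, x, False, lab))

    order = {r.mouse_id: i for i, r in enumerate(recs)}
    calls.sort(key=lambda c: order[c.mouse_id])
    strain = next(iter(strains))
    return pd.DataFrame(
        {
            "mouse_id": [c.mouse_id for c in calls],
            "strain": strain,
            "group": [recs[order[c.mouse_id]].group for c in calls],
            "si_ratio": [c.si_ratio for c in calls],
            "outlier": [c.outlier for c in calls],
            "label": [c.label for c in calls],
            "border": border,
        }
    )
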
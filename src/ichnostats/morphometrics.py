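"""Perimeter-based morphometric ratios and allometry.

Ratios are dimensionless comparisons of footprint perimeter measurements:
hallucial divergence (digit 1-2 spacing over foot length), digit-width
ratios, heel/forefoot and width/length shape ratios, plus an ordinary
least-squares allometry fit of forefoot width on foot length with the
95% confidence band of the mean response.  Stature estimation applies
externally supplied regression coefficients to foot length; no
coefficients ship with the package.

Measurement conventions expected (not enforced): foot length from the
rear of the heel to the tip of the longest toe along the foot axis;
widths perpendicular to that axis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .regions import HEEL_REGIONS, REGION_INDEX, TOE_REGIONS

logger = logging.getLogger(__name__)


@dataclass
class StatureModel:
    """Linear stature-from-foot-length model: stature_cm = slope * length_mm + intercept."""

    slope: float  # cm per mm of foot length
    intercept: float  # cm
    note: str = ""


def divergence_ratio(d1_d2_distance: float | None, foot_length: float) -> float | None:
    """Hallucial divergence: distance between digits 1 and 2 over foot length."""
    if d1_d2_distance is None or (isinstance(d1_d2_distance, float) and math.isnan(d1_d2_distance)):
        logger.info("d1-d2 distance missing; divergence ratio absent")
        return None
    if foot_length <= 0:
        raise ValueError("foot_length must be positive")
    if d1_d2_distance < 0:
        raise ValueError("d1_d2_distance must be >= 0")
    return d1_d2_distance / foot_length


def digit_width_ratio(w_num: float, w_den: float) -> float:
    """Ratio of two digit impression widths (e.g. hallux/second digit)."""
    if w_den <= 0 or w_num <= 0:
        raise ValueError("digit widths must be positive")
    return w_num / w_den


def shape_ratios(
    foot_length: float, forefoot_width: float, heel_width: float
) -> tuple[float, float]:
    """(heel/forefoot width ratio, forefoot width/foot length ratio)."""
    if min(foot_length, forefoot_width, heel_width) <= 0:
        raise ValueError("lengths and widths must be positive")
    return heel_width / forefoot_width, forefoot_width / foot_length


def length_match_deviation(candidate_mm: float, target_mm: float) -> float:
    """Percent deviation of a comparative sample's foot length from a target.

    Used for the matching criterion that comparative feet be within 10%
    of the target track length.
    """
    if target_mm <= 0:
        raise ValueError("target length must be positive")
    return abs(candidate_mm - target_mm) / target_mm * 100.0


def allometry_fit(x, y, alpha: float = 0.05) -> dict:
    """OLS fit of y on x with the confidence band of the mean response.

    Returns slope, intercept, and arrays (x, fitted, ci_low, ci_high) of
    the mean-response band at the observed x, at level 1 - alpha.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 points for the allometry fit")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope is undefined")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    pred = fit.get_prediction(X).summary_frame(alpha=alpha)
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "r_squared": float(fit.rsquared),
        "x": x,
        "fitted": pred["mean"].to_numpy(),
        "ci_low": pred["mean_ci_lower"].to_numpy(),
        "ci_high": pred["mean_ci_upper"].to_numpy(),
    }


def estimate_stature(foot_length: float, model: StatureModel | None) -> float:
    """Stature (cm) from foot length (mm) via user-supplied coefficients."""
    if model is None:
        raise ValueError(
            "no stature model supplied; provide StatureModel(slope, intercept) "
            "coefficients from a published foot length-stature regression"
        )
    return model.slope * foot_length + model.intercept


def toe_depth_ratio(
    raw_depths: np.ndarray, convention: str = "log_ratio"
) -> dict | None:
    """Proportional toe-depth statistic of one footprint.

    Compares the mean depth of the five toe regions against the mean of
    the two heel regions under a named convention:

    - ``log_ratio``: ln(mean toe depth / mean heel depth)
    - ``normalized_difference``: (toe - heel) / (toe + heel)

    Both are 0 when toes and heel are equally deep and negative when the
    toes are shallower.  Returns None (logged) when the heel depth is
    zero.
    """
    raw = np.asarray(raw_depths, dtype=float)
    toe = raw[[REGION_INDEX[r] for r in TOE_REGIONS]].mean()
    heel = raw[[REGION_INDEX[r] for r in HEEL_REGIONS]].mean()
    if heel == 0 or (convention == "normalized_difference" and toe + heel == 0):
        logger.info("zero heel depth; toe-depth ratio absent")
        return None
    if convention == "log_ratio":
        if toe == 0:
            logger.info("zero toe depth; log toe-depth ratio absent")
            return None
        value = math.log(toe / heel)
    elif convention == "normalized_difference":
        value = (toe - heel) / (toe + heel)
    else:
        raise ValueError(f"unknown toe-depth convention {convention!r}")
    return {"value": float(value), "convention": convention}


def perimeter_ratio_table(perimeter: pd.DataFrame) -> pd.DataFrame:
    """Per-footprint ratio table from a perimeter-measurement table.

    Expects columns footprint_id, subject_id, group, foot_length_mm,
    forefoot_width_mm, heel_width_mm and optionally d1_d2_distance_mm,
    digit1_width_mm, digit2_width_mm.  Missing optional fields yield
    absent (NaN) ratios.
    """
    rows = []
    for _, r in perimeter.iterrows():
        heel_ff, ff_len = shape_ratios(
            r["foot_length_mm"], r["forefoot_width_mm"], r["heel_width_mm"]
        )
        rec = {
            "footprint_id": r["footprint_id"],
            "subject_id": r.get("subject_id"),
            "group": r.get("group"),
            "heel_forefoot_ratio": heel_ff,
            "width_length_ratio": ff_len,
        }
        d12 = r.get("d1_d2_distance_mm", np.nan)
        rec["divergence_ratio"] = (
            divergence_ratio(float(d12), r["foot_length_mm"])
            if pd.notna(d12)
            else np.nan
        )
        w1, w2 = r.get("digit1_width_mm", np.nan), r.get("digit2_width_mm", np.nan)
        rec["digit_width_ratio"] = (
            digit_width_ratio(float(w1), float(w2))
            if pd.notna(w1) and pd.notna(w2)
            else np.nan
        )
        rows.append(rec)
    return pd.DataFrame(rows)
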
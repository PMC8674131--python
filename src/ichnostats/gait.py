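"""Step and stride geometry from ordered footfall sequences.

Step length is measured along the travel axis (sagittal-plane convention)
between consecutive opposite-side contacts; stride length between
consecutive same-side contacts.  Step width is the lateral separation of
consecutive contacts, *signed*: positive when the landing foot stays on
its anatomical side of the line of travel, negative when it crosses the
midline (cross-stepping).  The line of travel is estimated per trackway
as the OLS line through all contacts (configurable to the raw x-axis).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def _travel_frame(contacts: pd.DataFrame, midline: str) -> tuple[np.ndarray, np.ndarray]:
    """(u, v) coordinates: u along the travel axis, v lateral (+v = left)."""
    x = contacts["x_mm"].to_numpy(dtype=float)
    y = contacts["y_mm"].to_numpy(dtype=float)
    if midline == "x_axis" or np.ptp(x) == 0:
        return x, y
    if midline != "ols":
        raise ValueError(f"unknown midline convention {midline!r}")
    slope, intercept = np.polyfit(x, y, 1)
    direction = np.array([1.0, slope]) / np.hypot(1.0, slope)
    normal = np.array([-direction[1], direction[0]])  # +v is left of travel
    pts = np.column_stack([x, y - intercept])
    return pts @ direction, pts @ normal


def step_metrics(contacts: pd.DataFrame, midline: str = "ols") -> pd.DataFrame:
    """Per-step records from a footfall table.

    ``contacts`` columns: idx, side (L|R), x_mm, y_mm, ordered by idx with
    +x the nominal direction of travel.  Returns one row per step with
    step_length_mm (along-travel gap to the previous contact),
    step_width_mm (signed lateral separation) and the landing side.
    Consecutive same-side contacts are skipped with a warning.
    """
    if len(contacts) < 2:
        raise ValueError("need >= 2 contacts for step metrics")
    contacts = contacts.sort_values("idx").reset_index(drop=True)
    if not contacts["idx"].is_unique:
        raise ValueError("contact indices must be strictly increasing")
    u, v = _travel_frame(contacts, midline)
    sides = contacts["side"].to_numpy()
    rows = []
    for k in range(1, len(contacts)):
        if sides[k] == sides[k - 1]:
            logger.warning(
                "contacts %d and %d are both %s; step skipped",
                int(contacts["idx"][k - 1]),
                int(contacts["idx"][k]),
                sides[k],
            )
            continue
        width = abs(v[k] - v[k - 1])
        # positive iff the landing foot is on its anatomical side of the midline
        on_own_side = (sides[k] == "L" and v[k] > 0) or (sides[k] == "R" and v[k] < 0)
        sign = 1.0 if (on_own_side or v[k] == 0) else -1.0
        rows.append(
            {
                "idx": int(contacts["idx"][k]),
                "side": sides[k],
                "step_length_mm": float(u[k] - u[k - 1]),
                "step_width_mm": float(sign * width),
            }
        )
    return pd.DataFrame(rows)


def stride_lengths(contacts: pd.DataFrame, midline: str = "ols") -> pd.DataFrame:
    """Per-stride along-travel gaps between consecutive same-side contacts."""
    contacts = contacts.sort_values("idx").reset_index(drop=True)
    u, _ = _travel_frame(contacts, midline)
    rows = []
    last_seen: dict[str, tuple[int, float]] = {}
    for k in range(len(contacts)):
        side = contacts["side"][k]
        if side in last_seen:
            _, u_prev = last_seen[side]
            rows.append(
                {
                    "idx": int(contacts["idx"][k]),
                    "side": side,
                    "stride_length_mm": float(u[k] - u_prev),
                }
            )
        last_seen[side] = (k, u[k])
    return pd.DataFrame(rows)


def relative_step_width(steps: pd.DataFrame) -> float:
    """Ratio of mean |step width| to mean step length.

    High values characterise wide-stance bipeds (bears, chimpanzees);
    habitual human bipedalism yields low values.
    """
    if len(steps) == 0:
        raise ValueError("no steps to summarise")
    mean_len = steps["step_length_mm"].mean()
    if mean_len <= 0:
        raise ValueError("mean step length must be positive")
    return float(steps["step_width_mm"].abs().mean() / mean_len)


def detect_cross_steps(steps: pd.DataFrame) -> tuple[list[int], float]:
    """Steps whose signed width is negative (midline crossed before touchdown).

    Returns the step indices and the crossed fraction.
    """
    if len(steps) == 0:
        return [], 0.0
    crossed = steps[steps["step_width_mm"] < 0]
    return crossed["idx"].astype(int).tolist(), float(len(crossed) / len(steps))


def summarize_trackway(contacts: pd.DataFrame, midline: str = "ols") -> dict:
    """Headline gait numbers for one trackway."""
    steps = step_metrics(contacts, midline=midline)
    strides = stride_lengths(contacts, midline=midline)
    cross_idx, cross_frac = detect_cross_steps(steps)
    return {
        "n_steps": int(len(steps)),
        "mean_step_length_mm": float(steps["step_length_mm"].mean()),
        "mean_abs_step_width_mm": float(steps["step_width_mm"].abs().mean()),
        "mean_signed_step_width_mm": float(steps["step_width_mm"].mean()),
        "mean_stride_length_mm": float(strides["stride_length_mm"].mean())
        if len(strides)
        else float("nan"),
        "relative_step_width": relative_step_width(steps),
        "cross_step_indices": cross_idx,
        "cross_step_fraction": cross_frac,
    }
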
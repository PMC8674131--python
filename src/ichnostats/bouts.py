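"""Behavioural bout statistics for bipedalism event logs.

An event log records contiguous episodes of bipedal behaviour (postural
standing vs locomotor stepping), each with an interval, a step count and
whether the animal used external support.  Assisted bouts are excluded
from headline statistics by default, so the numbers describe *unsupported*
bipedalism.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("start_s", "end_s", "kind", "n_steps", "assisted")


def _validate(events: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in events.columns:
            raise ValueError(f"event log missing column {col!r}")
    if len(events) == 0:
        return events
    if (events["end_s"] <= events["start_s"]).any():
        bad = events.index[events["end_s"] <= events["start_s"]].tolist()
        raise ValueError(f"events with non-positive duration at rows {bad}")
    ordered = events.sort_values("start_s").reset_index()
    overlap = ordered["start_s"].iloc[1:].to_numpy() < ordered["end_s"].iloc[:-1].to_numpy()
    if overlap.any():
        offenders = ordered["index"].iloc[1:][overlap].tolist()
        raise ValueError(f"overlapping events at rows {offenders}")
    return events


def summarize_bouts(
    events: pd.DataFrame, total_time: float, include_assisted: bool = False
) -> dict:
    """Headline statistics of a bipedalism event log.

    Returns the percentage of observation time spent in (unsupported)
    bipedal behaviour, the postural/locomotor split of that time (summing
    to 100 when any bipedal time was observed), the maximum step count of
    an unassisted locomotor bout, and the unassisted bout count.
    """
    events = _validate(events)
    if total_time <= 0:
        raise ValueError("total_time must be positive")
    durations = events["end_s"] - events["start_s"]
    if durations.sum() > total_time + 1e-9:
        raise ValueError("event durations exceed the observation window")
    sel = events if include_assisted else events.loc[~events["assisted"].astype(bool)]
    sel_dur = sel["end_s"] - sel["start_s"]
    bipedal_time = float(sel_dur.sum())
    out = {
        "bipedal_fraction_pct": bipedal_time / total_time * 100.0,
        "n_unassisted_bouts": int((~events["assisted"]).sum()),
        "max_consecutive_steps": int(
            sel.loc[sel["kind"] == "locomotor", "n_steps"].max()
        )
        if (sel["kind"] == "locomotor").any()
        else 0,
    }
    if bipedal_time > 0:
        postural = float(sel_dur[sel["kind"] == "postural"].sum())
        out["postural_share_pct"] = postural / bipedal_time * 100.0
        out["locomotor_share_pct"] = 100.0 - out["postural_share_pct"]
    else:
        logger.warning("no bipedal time observed; postural/locomotor shares undefined")
        out["postural_share_pct"] = None
        out["locomotor_share_pct"] = None
    return out


def hours_from_hms(h: int, m: int, s: float, ndigits: int | None = None) -> float:
    """Decimal hours from an h/m/s observation total (optionally rounded)."""
    if not 0 <= m < 60 or not 0 <= s < 60:
        raise ValueError("minutes and seconds must be in [0, 60)")
    hours = h + m / 60.0 + s / 3600.0
    return round(hours, ndigits) if ndigits is not None else hours


def event_probability(events: pd.DataFrame, total_time: float, predicate) -> float:
    """Time fraction (%) of events satisfying *predicate*.

    The convention is explicitly time-based: the summed duration of
    matching events over the total observation time, as a percentage.
    """
    events = _validate(events)
    if total_time <= 0:
        raise ValueError("total_time must be positive")
    if len(events) == 0:
        return 0.0
    match = events[events.apply(predicate, axis=1)]
    return float((match["end_s"] - match["start_s"]).sum() / total_time * 100.0)
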
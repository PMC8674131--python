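"""Readers and writers for the pipeline's plain-text formats.

All tables are UTF-8 comma-separated CSV with a header row and '.' decimal
separator; grids are ESRI ASCII; models and summaries are JSON.  Every
writer's output round-trips through the matching reader.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .regions import REGIONS, validate_regions
from .shape import CovarianceModel, DistanceSample

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"  # fixed formatting so identical runs are byte-identical

DEPTH_COLUMNS = ["footprint_id", "subject_id", "group", "region", "depth_mm"]


def read_depth_table(path) -> pd.DataFrame:
    """Long-format depth table; validates regions and completeness.

    Required columns: footprint_id, subject_id, group, region, depth_mm.
    Unknown region labels are rejected with their row numbers; a
    footprint missing any of the 14 regions is rejected by name; extra
    columns are ignored with a warning.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in DEPTH_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"depth table missing columns: {missing_cols}")
    extra = [c for c in df.columns if c not in DEPTH_COLUMNS]
    if extra:
        logger.warning("ignoring extra columns in depth table: %s", extra)
        df = df[DEPTH_COLUMNS]
    bad = ~df["region"].isin(REGIONS)
    if bad.any():
        rows = (df.index[bad] + 2).tolist()  # +2: header + 0-based
        labels = sorted(df.loc[bad, "region"].unique())
        raise ValueError(f"unknown region labels {labels} at file rows {rows[:10]}")
    counts = df.groupby("footprint_id")["region"].nunique()
    incomplete = counts.index[counts != len(REGIONS)].tolist()
    if incomplete:
        raise ValueError(f"footprints missing regions: {incomplete[:10]}")
    return df


def write_depth_table(path, depths: pd.DataFrame) -> None:
    depths[DEPTH_COLUMNS].to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_landmarks(path) -> dict[str, dict[str, tuple[float, float]]]:
    """landmarks.csv (footprint_id, region, x_mm, y_mm) -> nested dict."""
    df = pd.read_csv(path)
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for fid, g in df.groupby("footprint_id"):
        lm = {r["region"]: (float(r["x_mm"]), float(r["y_mm"])) for _, r in g.iterrows()}
        validate_regions(lm.keys())
        out[fid] = lm
    return out


def write_landmarks(path, landmarks: dict[str, dict[str, tuple[float, float]]]) -> None:
    rows = [
        {"footprint_id": fid, "region": r, "x_mm": x, "y_mm": y}
        for fid, lm in landmarks.items()
        for r, (x, y) in lm.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_footfalls(path) -> dict[str, pd.DataFrame]:
    """footfalls.csv (trackway_id, idx, side, x_mm, y_mm) -> per-trackway tables."""
    df = pd.read_csv(path)
    for col in ("trackway_id", "idx", "side", "x_mm", "y_mm"):
        if col not in df.columns:
            raise ValueError(f"footfalls table missing column {col!r}")
    df = df.astype({"idx": int, "x_mm": float, "y_mm": float})
    return {tid: g.drop(columns="trackway_id").reset_index(drop=True) for tid, g in df.groupby("trackway_id")}


def write_footfalls(path, trackways: dict[str, pd.DataFrame]) -> None:
    frames = []
    for tid, t in trackways.items():
        t = t.copy()
        t.insert(0, "trackway_id", tid)
        frames.append(t)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if len(df) and df["assisted"].dtype != bool:
        df["assisted"] = df["assisted"].astype(bool)
    return df


def write_events(path, events: pd.DataFrame) -> None:
    events.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_model(path, model: CovarianceModel) -> None:
    payload = {
        "regions": list(REGIONS),
        "mean_profile": model.mean_profile.tolist(),
        "cov": model.cov.tolist(),
        "n_subjects": model.n_subjects,
        "ridge": model.ridge,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_model(path) -> CovarianceModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("regions") != list(REGIONS):
        raise ValueError("model file region order does not match this package")
    return CovarianceModel(
        mean_profile=np.array(payload["mean_profile"]),
        cov=np.array(payload["cov"]),
        n_subjects=int(payload["n_subjects"]),
        ridge=float(payload["ridge"]),
    )


def write_distances(path, samples: list[DistanceSample]) -> None:
    rows = [
        {"label": s.label, "iteration": i, "distance": float(d)}
        for s in samples
        for i, d in enumerate(s.distances)
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_distances(path) -> list[DistanceSample]:
    df = pd.read_csv(path)
    out = []
    for label, g in df.groupby("label", sort=False):
        d = g.sort_values("iteration")["distance"].to_numpy()
        out.append(DistanceSample(label=label, distances=d, iterations=len(d)))
    return out


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
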
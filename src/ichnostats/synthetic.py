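"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators emulate the structure of the comparative data the pipeline
consumes: per-subject 14-region depth profiles for two morphs (a
"reference" human-like morph and an "outgroup" chimpanzee-like morph),
tilted noisy substrate surfaces with footprint depressions of known depth,
trackways parameterised by step length / signed step width, and
behavioural event logs of bipedal bouts.

All randomness flows through named streams keyed by a single master seed
(`_rng.stream_rng`), so a fixed seed gives byte-identical outputs and
adding a generator never perturbs another's draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import stream_rng
from .regions import N_REGIONS, REGIONS, validate_regions
from .surface import PlaneParams, SurfaceGrid

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Specs


@dataclass
class MorphSpec:
    """Depth-profile population model for one morph.

    A subject's mean regional depth is drawn from
    Normal(region_mean, between_subject_sd); each of that subject's tracks
    then draws Normal(subject_mean, within_subject_sd).  Negative draws
    are truncated to zero (depths are magnitudes).
    """

    name: str
    region_means: dict[str, float]
    between_subject_sd: dict[str, float] | float = 0.0
    within_subject_sd: dict[str, float] | float = 0.0
    n_subjects: int = 0
    n_tracks_per_subject: int = 1

    def __post_init__(self):
        validate_regions(self.region_means.keys())
        if isinstance(self.between_subject_sd, (int, float)):
            self.between_subject_sd = {r: float(self.between_subject_sd) for r in REGIONS}
        if isinstance(self.within_subject_sd, (int, float)):
            self.within_subject_sd = {r: float(self.within_subject_sd) for r in REGIONS}
        validate_regions(self.between_subject_sd.keys())
        validate_regions(self.within_subject_sd.keys())
        for r in REGIONS:
            if self.region_means[r] < 0:
                raise ValueError(f"region mean for {r} is negative")
            if self.between_subject_sd[r] < 0 or self.within_subject_sd[r] < 0:
                raise ValueError(f"sd for {r} is negative")
        if self.n_subjects < 0 or self.n_tracks_per_subject < 0:
            raise ValueError("subject/track counts must be >= 0")


@dataclass
class GaitSpec:
    """Trackway model: step lengths and signed step widths in mm.

    A negative ``step_width_mean`` produces a cross-stepping trackway
    (each foot lands across the midline).
    """

    step_length_mean: float = 300.0
    step_length_sd: float = 0.0
    step_width_mean: float = 100.0
    step_width_sd: float = 0.0
    n_steps: int = 10

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.step_length_sd < 0 or self.step_width_sd < 0:
            raise ValueError("sds must be >= 0")


@dataclass
class SurfaceSpec:
    """Tilted noisy substrate with Gaussian footprint depressions.

    ``plane`` gives the substrate elevation a*x + b*y + c; each well is a
    plan-view Gaussian depression of the stated peak depth whose standard
    deviation is ``radius / 2`` (so the bump is negligible beyond three
    radii, which is where the substrate mask begins).
    """

    nx: int = 100
    ny: int = 100
    spacing: float = 2.0  # mm per cell
    plane: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd: float = 0.0  # mm
    wells: list[tuple[str, float, float, float, float]] = field(default_factory=list)
    # each well: (region, centre_x_mm, centre_y_mm, peak_depth_mm, radius_mm)

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for region, cx, cy, depth, radius in self.wells:
            if radius <= 0:
                raise ValueError(f"well {region}: radius must be positive")
            if depth < 0:
                raise ValueError(f"well {region}: depth must be >= 0")
            if not (0 <= cx <= (self.nx - 1) * self.spacing) or not (
                0 <= cy <= (self.ny - 1) * self.spacing
            ):
                raise ValueError(f"well {region} centre lies outside the grid")


@dataclass
class BoutSpec:
    """Bipedal-bout event-log model.

    ``steps_distribution`` maps step counts for locomotor bouts to
    probabilities (postural bouts always have zero steps).
    """

    total_time: float = 183318.0  # s; 50 h 55 min 18 s of observation
    # 1.62 bouts/h x 4 s mean x 50% unassisted => 0.09% of time unsupported
    bout_rate: float = 1.62  # bouts per hour
    duration_mean: float = 4.0  # s
    locomotor_fraction: float = 0.41
    steps_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.45, 2: 0.35, 3: 0.15, 4: 0.05}
    )
    assisted_fraction: float = 0.5

    def __post_init__(self):
        if self.total_time <= 0:
            raise ValueError("total_time must be positive")
        for name in ("locomotor_fraction", "assisted_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        probs = np.array(list(self.steps_distribution.values()), dtype=float)
        if probs.size == 0 or abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            raise ValueError("steps_distribution probabilities must be >= 0 and sum to 1")


# ---------------------------------------------------------------------------
# Default morphs

#: Default depth means (mm) for an arched, human-like footprint: deep heel
#: and forefoot, shallow midfoot (longitudinal arch), hallux deepest toe.
HUMAN_LIKE_MEANS: dict[str, float] = {
    "heel_medial": 8.0,
    "heel_lateral": 7.5,
    "midfoot_medial": 1.0,
    "midfoot_lateral": 2.5,
    "mt1": 7.0,
    "mt2": 6.5,
    "mt3": 5.5,
    "mt4": 4.5,
    "mt5": 4.0,
    "toe1": 6.5,
    "toe2": 4.0,
    "toe3": 3.5,
    "toe4": 3.0,
    "toe5": 2.5,
}

#: Default depth means (mm) for a flat, chimpanzee-like footprint: midfoot
#: contact (no arch), deep divergent hallux, shallow lateral toes.
CHIMP_LIKE_MEANS: dict[str, float] = {
    "heel_medial": 4.5,
    "heel_lateral": 4.5,
    "midfoot_medial": 4.5,
    "midfoot_lateral": 5.0,
    "mt1": 6.0,
    "mt2": 4.5,
    "mt3": 4.0,
    "mt4": 3.5,
    "mt5": 3.0,
    "toe1": 8.0,
    "toe2": 3.0,
    "toe3": 2.5,
    "toe4": 2.0,
    "toe5": 1.5,
}


def default_reference_morph(n_subjects: int = 40, n_tracks: int = 6) -> MorphSpec:
    return MorphSpec(
        name="reference",
        region_means=dict(HUMAN_LIKE_MEANS),
        between_subject_sd=0.6,
        within_subject_sd=0.5,
        n_subjects=n_subjects,
        n_tracks_per_subject=n_tracks,
    )


def default_outgroup_morph(n_subjects: int = 2, n_tracks: int = 20) -> MorphSpec:
    return MorphSpec(
        name="outgroup",
        region_means=dict(CHIMP_LIKE_MEANS),
        between_subject_sd=0.6,
        within_subject_sd=0.5,
        n_subjects=n_subjects,
        n_tracks_per_subject=n_tracks,
    )


# ---------------------------------------------------------------------------
# Generators


def generate_depth_dataset(morphs: list[MorphSpec], seed: int) -> pd.DataFrame:
    """Long-format depth table for a list of morph populations.

    Columns: footprint_id, subject_id, group, region, depth_mm.  One row
    per footprint per region; deterministic for a fixed seed.
    """
    rng = stream_rng(seed, "depths")
    rows: list[dict] = []
    for morph in morphs:
        means = np.array([morph.region_means[r] for r in REGIONS])
        between = np.array([morph.between_subject_sd[r] for r in REGIONS])
        within = np.array([morph.within_subject_sd[r] for r in REGIONS])
        for s in range(morph.n_subjects):
            subject_id = f"{morph.name}_s{s:03d}"
            subj_mean = np.maximum(rng.normal(means, between), 0.0)
            for t in range(morph.n_tracks_per_subject):
                track = np.maximum(rng.normal(subj_mean, within), 0.0)
                footprint_id = f"{subject_id}_t{t:03d}"
                for r, d in zip(REGIONS, track):
                    rows.append(
                        {
                            "footprint_id": footprint_id,
                            "subject_id": subject_id,
                            "group": morph.name,
                            "region": r,
                            "depth_mm": float(d),
                        }
                    )
    return pd.DataFrame(
        rows, columns=["footprint_id", "subject_id", "group", "region", "depth_mm"]
    )


def generate_surface(
    spec: SurfaceSpec, seed: int
) -> tuple[SurfaceGrid, dict]:
    """Render a substrate surface with footprint depressions.

    Returns the grid (with substrate mask set to cells beyond three radii
    of every well) and a ground-truth sidecar with the plane, the per-well
    peak depths and the landmark coordinates.
    """
    rng = stream_rng(seed, "surface")
    a, b, c = spec.plane
    x = np.arange(spec.nx) * spec.spacing
    y = np.arange(spec.ny) * spec.spacing
    xx, yy = np.meshgrid(x, y)
    elev = a * xx + b * yy + c
    if spec.noise_sd > 0:
        elev = elev + rng.normal(0.0, spec.noise_sd, size=elev.shape)
    mask = np.ones(elev.shape, dtype=bool)
    truth_wells = {}
    for region, cx, cy, depth, radius in spec.wells:
        sigma = radius / 2.0
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        elev = elev - depth * np.exp(-r2 / (2.0 * sigma**2))
        inside = r2 <= (3.0 * radius) ** 2
        mask &= ~inside
        truth_wells[region] = {"x_mm": cx, "y_mm": cy, "depth_mm": depth, "radius_mm": radius}
    # Flag overlapping wells (allowed, but peak depths then interact).
    for i in range(len(spec.wells)):
        for j in range(i + 1, len(spec.wells)):
            _, xi, yi, _, ri = spec.wells[i]
            _, xj, yj, _, rj = spec.wells[j]
            if np.hypot(xi - xj, yi - yj) < (ri + rj):
                logger.warning(
                    "wells %s and %s overlap; summed depths at their centres",
                    spec.wells[i][0],
                    spec.wells[j][0],
                )
    grid = SurfaceGrid(elevations=elev, spacing=spec.spacing, substrate_mask=mask)
    truth = {
        "plane": {"a": a, "b": b, "c": c},
        "noise_sd": spec.noise_sd,
        "wells": truth_wells,
    }
    return grid, truth


def generate_trackway(spec: GaitSpec, seed: int) -> pd.DataFrame:
    """Footfall table for one trackway: idx, side, x_mm, y_mm.

    Contacts alternate L/R advancing along +x by drawn step lengths.  Each
    contact's lateral position is s_i * o_i where s_i is +1 for a left
    foot and -1 for a right foot and o_i ~ Normal(width_mean/2,
    width_sd/2): consecutive offsets then subtend the configured signed
    step width on average, and exactly when the sd is zero.  Negative
    step-length draws are resampled (and logged).
    """
    rng = stream_rng(seed, "trackway")
    n_contacts = spec.n_steps + 1
    sides = ["L" if i % 2 == 0 else "R" for i in range(n_contacts)]
    xs = [0.0]
    for _ in range(spec.n_steps):
        d = rng.normal(spec.step_length_mean, spec.step_length_sd)
        n_resample = 0
        while d <= 0:
            d = rng.normal(spec.step_length_mean, spec.step_length_sd)
            n_resample += 1
            if n_resample > 1000:
                raise ValueError("step length distribution draws are almost all negative")
        if n_resample:
            logger.debug("resampled %d negative step-length draws", n_resample)
        xs.append(xs[-1] + d)
    offsets = rng.normal(spec.step_width_mean / 2.0, spec.step_width_sd / 2.0, size=n_contacts)
    ys = [o if s == "L" else -o for s, o in zip(sides, offsets)]
    return pd.DataFrame(
        {
            "idx": np.arange(n_contacts),
            "side": sides,
            "x_mm": np.asarray(xs, dtype=float),
            "y_mm": np.asarray(ys, dtype=float),
        }
    )


def generate_event_log(spec: BoutSpec, seed: int) -> pd.DataFrame:
    """Event log of bipedal bouts: start_s, end_s, kind, n_steps, assisted.

    The bout count is Poisson(bout_rate * hours); durations are
    exponential with the configured mean; bouts are placed without
    overlap by distributing the free time as random gaps.  Raises if the
    drawn bouts cannot fit inside the observation window.
    """
    rng = stream_rng(seed, "events")
    hours = spec.total_time / 3600.0
    n = int(rng.poisson(spec.bout_rate * hours)) if spec.bout_rate > 0 else 0
    if n == 0:
        return pd.DataFrame(
            columns=["start_s", "end_s", "kind", "n_steps", "assisted"]
        ).astype({"start_s": float, "end_s": float, "kind": str, "n_steps": int, "assisted": bool})
    durations = rng.exponential(spec.duration_mean, size=n)
    total_busy = durations.sum()
    if total_busy > spec.total_time:
        raise ValueError(
            f"drawn bouts occupy {total_busy:.1f} s, exceeding the "
            f"{spec.total_time:.1f} s observation window"
        )
    free = spec.total_time - total_busy
    cuts = np.sort(rng.uniform(0.0, free, size=n))
    starts = cuts + np.concatenate([[0.0], np.cumsum(durations[:-1])])
    kinds = np.where(rng.random(n) < spec.locomotor_fraction, "locomotor", "postural")
    step_vals = np.array(list(spec.steps_distribution.keys()))
    step_probs = np.array(list(spec.steps_distribution.values()), dtype=float)
    steps = np.where(
        kinds == "locomotor", rng.choice(step_vals, size=n, p=step_probs), 0
    )
    assisted = rng.random(n) < spec.assisted_fraction
    return pd.DataFrame(
        {
            "start_s": starts,
            "end_s": starts + durations,
            "kind": kinds,
            "n_steps": steps.astype(int),
            "assisted": assisted,
        }
    )


def generate_perimeters(
    group: str,
    n: int,
    seed: int,
    foot_length_mean: float = 250.0,
    foot_length_sd: float = 15.0,
    width_length_ratio: float = 0.36,
    heel_forefoot_ratio: float = 0.85,
    divergence: float = 0.08,
    noise_cv: float = 0.04,
) -> pd.DataFrame:
    """Synthetic perimeter-measurement table for one group.

    Foot lengths are normal; forefoot width, heel width and the digit 1-2
    distance scale with length through the given ratios, each perturbed
    by multiplicative noise with coefficient of variation ``noise_cv``.
    """
    rng = stream_rng(seed, f"perimeters:{group}")
    lengths = np.maximum(rng.normal(foot_length_mean, foot_length_sd, size=n), 1.0)
    jitter = lambda base: base * rng.normal(1.0, noise_cv, size=n)
    forefoot = jitter(lengths * width_length_ratio)
    heel = jitter(forefoot * heel_forefoot_ratio)
    d12 = jitter(lengths * divergence)
    return pd.DataFrame(
        {
            "footprint_id": [f"{group}_p{i:03d}" for i in range(n)],
            "subject_id": [f"{group}_s{i:03d}" for i in range(n)],
            "group": group,
            "foot_length_mm": lengths,
            "forefoot_width_mm": forefoot,
            "heel_width_mm": heel,
            "d1_d2_distance_mm": d12,
        }
    )


def landmarks_for_wells(spec: SurfaceSpec) -> dict[str, tuple[float, float]]:
    """Landmark table (region -> centre) for a generated surface's wells."""
    return {region: (cx, cy) for region, cx, cy, _, _ in spec.wells}
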
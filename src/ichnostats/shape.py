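"""Footprint-shape statistics: normalisation, between-subject covariance,
Mahalanobis distances and subject-level resampling classification.

The analysis chain mirrors a comparative-ichnology protocol for testing
whether candidate tracks fall inside the topographic variation of a
reference population:

1.  Each footprint's 14 regional depths are min-max normalised to [0, 1]
    within the footprint, so topology is compared independently of how
    deeply the substrate recorded the track.
2.  Within-subject means of the normalised profiles are averaged into a
    reference mean profile, and a between-subject covariance matrix is
    computed over the subject means.
3.  A null distribution is built by resampling: repeatedly average two
    footprints of a random reference subject and measure the Mahalanobis
    distance (under the between-subject covariance) to the mean of all
    *other* subjects.  Out-group and candidate (fossil) tracks are
    measured against the overall reference mean with the same covariance.
4.  A candidate is "within" the reference distribution when its distance
    does not exceed a chosen quantile (default 0.95) of the resampled
    reference distances.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regions import N_REGIONS, REGIONS

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Containers


@dataclass
class CovarianceModel:
    """Reference-population mean profile and between-subject covariance."""

    mean_profile: np.ndarray  # (14,)
    cov: np.ndarray  # (14, 14), ridge already added
    n_subjects: int
    ridge: float = 0.0

    def __post_init__(self):
        self.mean_profile = np.asarray(self.mean_profile, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.mean_profile.shape != (N_REGIONS,):
            raise ValueError(f"mean_profile must have {N_REGIONS} entries")
        if self.cov.shape != (N_REGIONS, N_REGIONS):
            raise ValueError(f"cov must be {N_REGIONS}x{N_REGIONS}")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("covariance matrix must be symmetric")


@dataclass
class DistanceSample:
    """A labelled sample of Mahalanobis distances."""

    label: str
    distances: np.ndarray
    iterations: int
    seed: int | None = None

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float)
        if (self.distances < 0).any():
            raise ValueError("distances must be non-negative")


# ---------------------------------------------------------------------------
# Normalisation and profile tables


def normalize_depths(raw) -> tuple[np.ndarray, bool]:
    """Min-max normalise one footprint's 14 raw depths to [0, 1].

    Returns ``(normalized, degenerate)``.  A zero-range footprint (all
    depths equal) is flagged degenerate and mapped to all zeros; by
    default degenerate footprints are excluded downstream.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.shape != (N_REGIONS,):
        raise ValueError(f"expected {N_REGIONS} depths, got shape {raw.shape}")
    if not np.all(np.isfinite(raw)):
        raise ValueError("depths must be finite")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        logger.warning("zero-range footprint; flagged degenerate")
        return np.zeros(N_REGIONS), True
    return (raw - lo) / (hi - lo), False


def profile_table(depths: pd.DataFrame, drop_degenerate: bool = True) -> pd.DataFrame:
    """Wide table of normalised profiles from a long depth table.

    Input columns: footprint_id, subject_id, group, region, depth_mm.
    Output: one row per footprint, indexed by footprint_id, with columns
    subject_id, group, degenerate, and the 14 regions (normalised).
    """
    wide = depths.pivot_table(
        index="footprint_id", columns="region", values="depth_mm", aggfunc="first"
    )
    missing = [r for r in REGIONS if r not in wide.columns]
    if missing:
        raise ValueError(f"depth table lacks regions: {missing}")
    if wide[list(REGIONS)].isna().any().any():
        bad = wide.index[wide[list(REGIONS)].isna().any(axis=1)].tolist()
        raise ValueError(f"footprints with missing regions: {bad}")
    wide = wide[list(REGIONS)]
    meta = depths.drop_duplicates("footprint_id").set_index("footprint_id")[
        ["subject_id", "group"]
    ]
    norm = np.empty_like(wide.values)
    degenerate = np.zeros(len(wide), dtype=bool)
    for k, (_, row) in enumerate(wide.iterrows()):
        norm[k], degenerate[k] = normalize_depths(row.values)
    out = pd.DataFrame(norm, index=wide.index, columns=list(REGIONS))
    out.insert(0, "subject_id", meta.loc[out.index, "subject_id"])
    out.insert(1, "group", meta.loc[out.index, "group"])
    out["degenerate"] = degenerate
    if drop_degenerate and degenerate.any():
        logger.warning("dropping %d degenerate footprints", int(degenerate.sum()))
        out = out[~out["degenerate"]]
    return out


def subject_mean_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Within-subject means of the 14 normalised depths.

    One row per subject_id, columns = the 14 regions.
    """
    return profiles.groupby("subject_id")[list(REGIONS)].mean()


# ---------------------------------------------------------------------------
# Covariance and distance


def build_covariance(subject_means: pd.DataFrame, ridge: float = 1e-8) -> CovarianceModel:
    """Between-subject covariance (unbiased, n-1) plus ridge*I.

    ``subject_means`` is the output of :func:`subject_mean_profiles`;
    the model mean is the grand mean of the subject means.
    """
    x = subject_means[list(REGIONS)].to_numpy(dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError(f"need >= 2 subjects to estimate covariance; got {n}")
    mean = x.mean(axis=0)
    cov = np.cov(x, rowvar=False, ddof=1) + ridge * np.eye(N_REGIONS)
    return CovarianceModel(mean_profile=mean, cov=cov, n_subjects=n, ridge=ridge)


def mahalanobis(
    x,
    model: CovarianceModel,
    mean: np.ndarray | None = None,
    allow_pinv: bool = True,
) -> float:
    """Mahalanobis distance sqrt((x-mu)' Sigma^-1 (x-mu)).

    ``mean`` overrides the model mean (used for leave-subject-out nulls).
    A singular covariance falls back to the Moore-Penrose pseudo-inverse
    (logged) unless ``allow_pinv`` is False.
    """
    x = np.asarray(x, dtype=float)
    mu = model.mean_profile if mean is None else np.asarray(mean, dtype=float)
    d = x - mu
    try:
        sol = np.linalg.solve(model.cov, d)
    except np.linalg.LinAlgError:
        if not allow_pinv:
            raise
        logger.warning("singular covariance; using pseudo-inverse")
        sol = np.linalg.pinv(model.cov) @ d
    val = float(d @ sol)
    return float(np.sqrt(max(val, 0.0)))


# ---------------------------------------------------------------------------
# Resampling


def _eligible_subjects(profiles: pd.DataFrame) -> list[str]:
    counts = profiles.groupby("subject_id").size()
    return sorted(counts.index[counts >= 2])


def resample_reference(
    profiles: pd.DataFrame,
    model: CovarianceModel,
    iterations: int = 1000,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> DistanceSample:
    """Null distribution of two-track averages within the reference sample.

    Each iteration samples a subject (uniform over subjects with at least
    two footprints), averages two of their footprints drawn without
    replacement, and measures the Mahalanobis distance to the mean
    profile of all *other* subjects, under the full between-subject
    covariance.
    """
    eligible = _eligible_subjects(profiles)
    if not eligible:
        raise ValueError("no subject has >= 2 footprints; cannot resample")
    rng = np.random.default_rng(seed) if rng is None else rng
    subj_means = subject_mean_profiles(profiles)
    all_ids = subj_means.index.to_numpy()
    means = subj_means.to_numpy(dtype=float)
    by_subject = {
        s: g[list(REGIONS)].to_numpy(dtype=float)
        for s, g in profiles.groupby("subject_id")
    }
    dists = np.empty(iterations)
    for it in range(iterations):
        s = eligible[rng.integers(len(eligible))]
        tracks = by_subject[s]
        pick = rng.choice(len(tracks), size=2, replace=False)
        avg = tracks[pick].mean(axis=0)
        loo_mean = means[all_ids != s].mean(axis=0)
        dists[it] = mahalanobis(avg, model, mean=loo_mean)
    return DistanceSample(label="reference", distances=dists, iterations=iterations, seed=seed)


def resample_outgroup(
    profiles: pd.DataFrame,
    model: CovarianceModel,
    iterations: int = 1000,
    seed: int = 0,
    label: str = "outgroup",
    rng: np.random.Generator | None = None,
) -> DistanceSample:
    """Distance distribution of out-group two-track averages.

    As :func:`resample_reference`, but subjects come from the out-group
    table and distances are measured to the overall reference mean (no
    leave-out), still under the reference covariance.
    """
    eligible = _eligible_subjects(profiles)
    if not eligible:
        raise ValueError("no out-group subject has >= 2 footprints")
    rng = np.random.default_rng(seed) if rng is None else rng
    by_subject = {
        s: g[list(REGIONS)].to_numpy(dtype=float)
        for s, g in profiles.groupby("subject_id")
    }
    dists = np.empty(iterations)
    for it in range(iterations):
        s = eligible[rng.integers(len(eligible))]
        tracks = by_subject[s]
        pick = rng.choice(len(tracks), size=2, replace=False)
        avg = tracks[pick].mean(axis=0)
        dists[it] = mahalanobis(avg, model)
    return DistanceSample(label=label, distances=dists, iterations=iterations, seed=seed)


def fossil_combination_distances(
    profiles: pd.DataFrame, model: CovarianceModel, label: str = "fossil"
) -> DistanceSample:
    """Distances of all unordered two-track averages of one candidate site.

    With n tracks this yields C(n, 2) distances (10 for n = 5, a single
    averaged pair for n = 2), each measured to the overall reference
    mean under the reference covariance.
    """
    tracks = profiles[list(REGIONS)].to_numpy(dtype=float)
    n = len(tracks)
    if n < 2:
        raise ValueError(f"need >= 2 tracks for two-track combinations; got {n}")
    dists = [
        mahalanobis(tracks[[i, j]].mean(axis=0), model)
        for i, j in itertools.combinations(range(n), 2)
    ]
    return DistanceSample(label=label, distances=np.array(dists), iterations=len(dists))


def classify_within(
    candidate: DistanceSample,
    reference: DistanceSample,
    quantile: float = 0.95,
) -> pd.DataFrame:
    """Verdict per candidate distance against the reference null.

    A distance is "within" when it does not exceed the stated quantile of
    the reference distances (boundary inclusive).  The empirical
    percentile of each candidate distance is also reported.
    """
    ref = reference.distances
    if ref.size == 0:
        raise ValueError("reference distance sample is empty")
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    threshold = float(np.quantile(ref, quantile))
    rows = []
    for k, d in enumerate(candidate.distances):
        rows.append(
            {
                "label": candidate.label,
                "combination": k,
                "distance": float(d),
                "percentile": float(np.mean(ref <= d)),
                "verdict": "within" if d <= threshold else "outside",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Depth-scale comparison


def depth_scale_test(group_a, group_b) -> float:
    """Exact two-sided Wilcoxon signed-rank p for paired region means.

    ``group_a`` and ``group_b`` are the 14 per-region mean raw depths of
    two samples, paired by region.  The null distribution of the
    signed-rank statistic is enumerated over all 2^m sign assignments of
    the non-zero differences (m <= 14, so full enumeration is cheap).
    Zero differences are discarded; if every difference is zero, p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.shape != (N_REGIONS,) or b.shape != (N_REGIONS,):
        raise ValueError(f"both groups must provide {N_REGIONS} paired region means")
    d = a - b
    d = d[d != 0]
    m = d.size
    if m == 0:
        return 1.0
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))  # midranks for tied magnitudes
    w_plus = ranks[d > 0].sum()
    # Enumerate W+ over all sign assignments.
    stats = np.zeros(1 << m)
    for bit in range(m):
        half = 1 << bit
        stats[half : 2 * half] = stats[:half] + ranks[bit]
        # builds all subset sums iteratively
    total = stats.size
    mean_w = ranks.sum() / 2.0
    # Two-sided: as or more extreme in |W+ - E[W+]|.
    p = float(np.mean(np.abs(stats - mean_w) >= np.abs(w_plus - mean_w) - 1e-12))
    return min(p, 1.0)
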
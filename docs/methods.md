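# Methods

This note documents the statistical model, the conventions and defaults,
what the synthetic-data generator does and does not emulate, and the
numerical choices, in the package's own terms.

## Regional depth extraction (`surface`)

A footprint arrives as a regular elevation grid (mm, positive up; 0-based
cells, lower-left origin) with a boolean mask marking undisturbed substrate.
The reference surface is the least-squares plane through the masked cells;
a mask with fewer than three cells or rank-deficient (collinear) geometry is
rejected by name. Depth at each of the 14 regions is the drop from the plane
to the *minimum* elevation inside a square window centred on the region's
landmark, clamped at zero.

- **Windowed minimum, default 10 mm.** A point sample is fragile to landmark
  jitter; the deepest point in a small window is robust and matches how an
  analyst probes a region. The window size is a config knob (`window_mm`).
- **Depressions only.** Raised features (e.g. a ridge of displaced
  sediment) report zero depth with a warning; the 14-region protocol
  measures depressions.
- Adding any plane a·x + b·y + c to a whole grid changes no depth by more
  than 1e−6 mm: the re-fit absorbs it (verified as a test invariant).

## Shape statistics (`shape`)

Raw 14-vectors are min–max normalised within each footprint. A zero-range
footprint (all regions equally deep) cannot be normalised; it is flagged
degenerate, mapped to zeros, and excluded from covariance estimation and
resampling by default.

The reference model is the grand mean μ of within-subject mean profiles and
the unbiased (n−1) between-subject covariance Σ of those profiles, plus a
ridge (default 1e−8) on the diagonal: with only tens of subjects in 14
dimensions the sample covariance can be numerically singular. If Σ is still
singular, Mahalanobis evaluation falls back to the Moore–Penrose
pseudo-inverse and logs the fact.

Resampling conventions:

- **Reference null** (default 1,000 iterations): subject uniform over
  subjects with ≥ 2 footprints (subjects with a single track cannot
  contribute a two-track average and are ineligible); two footprints drawn
  without replacement; the comparison mean is the mean profile of all
  *other* subjects (leave-subject-out), which offsets the in-sample
  advantage a subject would otherwise have against a mean it helped define.
- **Out-group and candidate sites**: compared against the overall reference
  mean, no leave-out, always under the full reference covariance — the
  out-group and candidates are treated as if they were additional subjects
  of the reference population.
- **Candidate sites**: all C(n,2) unordered two-track averages; a two-track
  site contributes its single averaged pair.
- **Verdict**: "within" iff distance ≤ the 0.95 quantile (config knob) of
  the reference null, boundary inclusive; the empirical percentile is
  reported alongside. The cut-off is an operational choice — the underlying
  comparison is the position of the candidate in the null distribution.

The depth-scale check is an exact two-sided Wilcoxon signed-rank test over
the 14 paired region means of two groups, with the null distribution
enumerated over all 2^m sign assignments of the non-zero differences
(midranks for tied magnitudes; zeros dropped; p = 1 when all differences
vanish). Pairing by region mean is one defensible convention for comparing
the overall depth scales of two samples; it is recorded as such.

A caveat established while validating the self-consistency of the
resampling scheme: with an *estimated* covariance, in-sample subjects sit
systematically closer to the reference mean than fresh draws from the same
population, by O(p/n) in 14 dimensions. The leave-subject-out mean removes
most but not all of this; distribution-level indistinguishability between
the reference null and a clone out-group emerges only for populations of
several hundred subjects (the property test uses 800). At study-like sizes
(tens of subjects) the effect is real but small relative to the separation
between morphs.

## Morphometrics (`morphometrics`)

All ratios are dimensionless and invariant under global rescaling:
hallucial divergence (digit 1–2 distance / foot length), digit-width ratio,
heel/forefoot ratio, forefoot-width/foot-length ratio, and the percent
foot-length matching deviation used to select comparative samples (≤ 10 %).
The allometry fit is ordinary least squares via statsmodels, with the 95 %
confidence band of the mean response from the t distribution.

- **Stature** requires user-supplied slope/intercept coefficients (cm per
  mm, cm). Shipping built-in coefficients would misattribute provenance;
  the hook applies whatever published regression the user chooses.
- **Toe-depth ratio** is surfaced under two named conventions —
  `log_ratio` ln(mean toe depth / mean heel depth), default, and
  `normalized_difference` (toe − heel)/(toe + heel) — because the defining
  formula in the literature admits more than one reading. Output records
  the convention used; both are 0 for equal depths and negative for
  shallow toes.
- Measurement conventions for the inputs (foot length along the foot axis,
  widths perpendicular) are documented but not enforced; the module
  consumes already-measured values.

## Gait (`gait`)

Contacts are abstract points (idx, side, x, y) with +x the nominal travel
direction; side alternation is *not* assumed, since cross-stepping data may
deviate. Step length is the along-travel gap between consecutive
opposite-side contacts (sagittal-plane convention, not Euclidean distance);
stride length the same between same-side contacts; consecutive same-side
contacts skip a step with a warning but still close a stride.

Signed step width: magnitude = lateral separation of consecutive contacts;
sign positive when the landing foot is on its anatomical side of the line
of travel, negative when it crossed the midline. The line of travel is the
OLS line through all contacts of the trackway (config `midline`, alternative
`x_axis`); the choice matters only for curved or drifting trackways.
Cross-steps are steps with negative signed width; the relative step width
is mean |width| / mean step length — high for wide-stance bipeds, low for
habitual human-like bipedalism.

## Bouts (`bouts`)

Bout summaries use a time-fraction convention throughout: percentage of
observation time in (by default, unsupported) bipedal behaviour, the
postural/locomotor partition of that time (summing to 100 whenever bipedal
time is positive), the maximum step count over unassisted locomotor bouts,
and `event_probability`, the time fraction of an arbitrary event subset,
labelled explicitly as such. Assisted bouts are excluded from headline
numbers because supported bipedalism answers a different behavioural
question. Overlapping events are rejected with the offending rows.

## Synthetic data (`synthetic`)

All generators draw from named streams keyed by one master seed (CRC of the
stream name into a `SeedSequence`), so outputs are byte-reproducible and
adding a generator never shifts another's draws.

- **Depth profiles**: subject mean ~ N(region mean, between-subject sd),
  track ~ N(subject mean, within-subject sd), truncated at 0 (depths are
  magnitudes). The two default morphs encode an arched human-like profile
  (deep heel and forefoot, shallow midfoot) and a flat chimpanzee-like
  profile (midfoot contact, deep divergent hallux, shallow lateral toes),
  with between/within-subject sd 0.6/0.5 mm. No published raw values exist
  for these populations, so the means are free parameters chosen once for
  realism; their normalised mean profiles are separated by Mahalanobis ≈ 40
  under a typical simulated reference covariance, comfortably beyond the
  ≥ 4 separation the classification-recovery study requires. Default
  population sizes, 40 reference subjects × 6 tracks and 2 out-group
  subjects × 20 tracks, mirror the scale of comparative footprint samples
  (hundreds of reference tracks from tens of subjects; tens of out-group
  tracks from very few individuals).
- **Surfaces**: elevation = plane + Gaussian noise − Gaussian wells
  (plan-view sd = radius/2, so a well's influence is negligible beyond the
  3-radius exclusion that defines the substrate mask). Peak well depth is
  the ground truth; the bump shape is a smooth stand-in — downstream
  contracts depend only on the peak. Overlapping wells are allowed but
  logged, since their depths then interact.
- **Trackways**: contacts alternate L/R; x advances by step lengths
  ~ N(mean, sd) with negative draws resampled; the lateral position of
  contact i is sᵢ·oᵢ (sᵢ = +1 left, −1 right), oᵢ ~ N(width mean/2,
  width sd/2), so the measured signed step width has the configured mean,
  exactly so when sd = 0 — including negative (cross-stepping) widths.
- **Event logs**: bout count ~ Poisson(rate × hours), exponential
  durations, placed without overlap by distributing free time as random
  gaps. Defaults (1.62 bouts/h, 4 s mean duration, 41 % locomotor, 50 %
  assisted, 50 h 55 min 18 s window) make unsupported bipedalism ≈ 0.09 %
  of observation time in expectation, matching the behavioural conditions
  the pipeline is designed to summarise.

What the generator does **not** emulate: substrate rheology and shear,
spatial correlation of real surface noise, non-Gaussian and asymmetric
depth distributions, intra-subject drift (fatigue, speed), partial or
overprinted tracks, and erosion between recording epochs. Passing tests
therefore demonstrate correctness of the statistical machinery under a
known generative model, not robustness to every taphonomic complication of
real tracks.

## Problem sizes and numerics

Tests and the acceptance script use desk-scale sizes chosen as the package's
own defaults: classification recovery with 20 replicates × 1,000 resampling
iterations; surface recovery on 160×160 grids (2 mm spacing) with 56 wells;
the self-consistency rank test with 800-subject populations × 300
iterations. Tolerances: plane and noiseless depth recovery 1e−6 mm;
brute-force oracle agreement 1e−8; min-max affine invariance 1e−9 (inputs
with range > 1e−3 mm — below that, floating-point cancellation dominates any
measurement). Ridge 1e−8 keeps Σ invertible without perturbing distances
at the scales above. CSV floats are written at 10 significant digits so
identical runs produce byte-identical bundles.
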
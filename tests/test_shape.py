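"""Shape statistics against independent brute-force oracles and invariants."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu, wilcoxon

from ichnostats import shape
from ichnostats import synthetic as syn
from ichnostats.regions import N_REGIONS, REGIONS


def _profiles_from_dataset(df, group):
    return shape.profile_table(df[df["group"] == group])


def _pad14(values):
    """First len(values) regions get the values; the rest interpolate."""
    out = np.linspace(min(values), max(values), N_REGIONS)
    out[: len(values)] = values
    return out


class TestNormalize:
    def test_min_max_formula(self):
        raw = _pad14([2.0, 5.0, 8.0])
        norm, degenerate = shape.normalize_depths(raw)
        assert not degenerate
        assert norm[0] == pytest.approx(0.0)
        assert norm[1] == pytest.approx(0.5)
        assert norm[2] == pytest.approx(1.0)

    def test_zero_range_flagged_degenerate(self):
        norm, degenerate = shape.normalize_depths(np.full(N_REGIONS, 3.0))
        assert degenerate
        assert np.all(norm == 0.0)

    @settings(deadline=None, max_examples=60)
    @given(
        raw=st.lists(
            st.floats(min_value=0, max_value=100, allow_nan=False, allow_subnormal=False),
            min_size=N_REGIONS, max_size=N_REGIONS,
        ).filter(lambda v: max(v) - min(v) > 1e-3),
        scale=st.floats(min_value=0.01, max_value=50),
        shift=st.floats(min_value=-5, max_value=50),
    )
    def test_affine_invariance_and_range(self, raw, scale, shift):
        # Min-max output attains 0 and 1, preserves order, and is
        # invariant under positive affine transforms of the raw depths.
        raw = np.asarray(raw)
        norm, deg = shape.normalize_depths(raw)
        assert not deg
        assert norm.min() == 0.0 and norm.max() == pytest.approx(1.0)
        assert ((raw[:, None] < raw[None, :]) == (norm[:, None] < norm[None, :])).all()
        norm2, _ = shape.normalize_depths(raw * scale + shift)
        assert np.allclose(norm, norm2, atol=1e-9)


class TestSubjectMeans:
    def test_single_footprint_identity(self, small_dataset):
        profiles = _profiles_from_dataset(small_dataset, "reference")
        one = profiles.iloc[[0]]
        means = shape.subject_mean_profiles(one)
        assert np.allclose(means.iloc[0].values, one[list(REGIONS)].iloc[0].values)

    def test_mean_of_opposite_profiles(self):
        df = pd.DataFrame(
            {
                "subject_id": ["s"] * 2,
                "group": ["g"] * 2,
                **{r: [0.0, 1.0] for r in REGIONS},
            },
            index=["f1", "f2"],
        )
        means = shape.subject_mean_profiles(df)
        assert np.allclose(means.loc["s"].values, 0.5)


class TestCovariance:
    def test_identical_subjects_zero_covariance(self):
        means = pd.DataFrame([np.full(N_REGIONS, 0.4)] * 5, columns=list(REGIONS))
        model = shape.build_covariance(means, ridge=1e-8)
        assert np.allclose(model.cov, 1e-8 * np.eye(N_REGIONS))

    def test_two_subject_hand_computation(self):
        # One informative region with subject means 0.2 and 0.4:
        # var = ((0.2-0.3)^2 + (0.4-0.3)^2) / (2-1) = 0.02.
        a = np.full(N_REGIONS, 0.5)
        b = np.full(N_REGIONS, 0.5)
        a[0], b[0] = 0.2, 0.4
        means = pd.DataFrame([a, b], columns=list(REGIONS))
        model = shape.build_covariance(means, ridge=0.0)
        assert model.cov[0, 0] == pytest.approx(0.02, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            n = rng.integers(3, 12)
            x = rng.random((n, N_REGIONS))
            means = pd.DataFrame(x, columns=list(REGIONS))
            model = shape.build_covariance(means, ridge=0.0)
            xbar = x.mean(axis=0)
            brute = sum(np.outer(xi - xbar, xi - xbar) for xi in x) / (n - 1)
            assert np.allclose(model.cov, brute, atol=1e-12)

    def test_single_subject_rejected(self):
        means = pd.DataFrame([np.zeros(N_REGIONS)], columns=list(REGIONS))
        with pytest.raises(ValueError, match=">= 2 subjects"):
            shape.build_covariance(means)


class TestMahalanobis:
    def _model(self, cov, mean=None):
        return shape.CovarianceModel(
            mean_profile=np.zeros(N_REGIONS) if mean is None else mean,
            cov=cov, n_subjects=10,
        )

    def test_distance_to_own_mean_is_zero(self, rng):
        mu = rng.random(N_REGIONS)
        model = self._model(np.eye(N_REGIONS), mean=mu)
        assert shape.mahalanobis(mu, model) == 0.0

    def test_identity_covariance_reduces_to_euclidean(self, rng):
        x = rng.random(N_REGIONS)
        model = self._model(np.eye(N_REGIONS))
        assert shape.mahalanobis(x, model) == pytest.approx(np.linalg.norm(x))

    def test_diagonal_closed_form(self):
        # Embedded 2-D case x=(1,0), mu=0, Sigma=diag(4,1): distance 1/2.
        cov = np.eye(N_REGIONS)
        cov[0, 0] = 4.0
        x = np.zeros(N_REGIONS)
        x[0] = 1.0
        assert shape.mahalanobis(x, self._model(cov)) == pytest.approx(0.5)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            a = rng.random((N_REGIONS + 5, N_REGIONS))
            cov = np.cov(a, rowvar=False) + 0.1 * np.eye(N_REGIONS)
            x, mu = rng.random(N_REGIONS), rng.random(N_REGIONS)
            model = self._model(cov, mean=mu)
            d = x - mu
            brute = np.sqrt(d @ np.linalg.inv(cov) @ d)
            assert shape.mahalanobis(x, model) == pytest.approx(brute, abs=1e-8)

    def test_invariance_under_linear_maps(self, rng):
        # Applying any invertible linear map to the data and transforming
        # the covariance accordingly leaves the distance unchanged.
        for _ in range(20):
            cov_half = rng.random((N_REGIONS, N_REGIONS))
            cov = cov_half @ cov_half.T + 0.5 * np.eye(N_REGIONS)
            x, mu = rng.random(N_REGIONS), rng.random(N_REGIONS)
            d0 = shape.mahalanobis(x, self._model(cov, mean=mu))
            A = rng.random((N_REGIONS, N_REGIONS)) + 2 * np.eye(N_REGIONS)
            d1 = shape.mahalanobis(A @ x, self._model(A @ cov @ A.T, mean=A @ mu))
            assert d1 == pytest.approx(d0, abs=1e-8)


@pytest.fixture
def reference_model(small_dataset):
    profiles = _profiles_from_dataset(small_dataset, "reference")
    model = shape.build_covariance(shape.subject_mean_profiles(profiles))
    return profiles, model


class TestResampling:
    def test_zero_iterations_empty(self, reference_model):
        profiles, model = reference_model
        s = shape.resample_reference(profiles, model, iterations=0, seed=0)
        assert len(s.distances) == 0

    def test_same_seed_identical(self, reference_model):
        profiles, model = reference_model
        s1 = shape.resample_reference(profiles, model, iterations=50, seed=9)
        s2 = shape.resample_reference(profiles, model, iterations=50, seed=9)
        assert np.array_equal(s1.distances, s2.distances)

    def test_degenerate_population_all_zero(self):
        rows = []
        for s in range(4):
            for t in range(3):
                rows.append({"subject_id": f"s{s}", "group": "g",
                             **{r: v for r, v in zip(REGIONS, np.linspace(0, 1, N_REGIONS))}})
        profiles = pd.DataFrame(rows, index=[f"f{i}" for i in range(len(rows))])
        means = shape.subject_mean_profiles(profiles)
        model = shape.build_covariance(means, ridge=1e-6)
        s = shape.resample_reference(profiles, model, iterations=30, seed=0)
        assert np.allclose(s.distances, 0.0, atol=1e-9)

    def test_no_eligible_subject_rejected(self):
        profiles = pd.DataFrame(
            [{"subject_id": "s1", "group": "g", **{r: 0.5 for r in REGIONS}}], index=["f1"]
        )
        model = shape.CovarianceModel(
            mean_profile=np.zeros(N_REGIONS), cov=np.eye(N_REGIONS), n_subjects=2
        )
        with pytest.raises(ValueError, match=">= 2 footprints"):
            shape.resample_reference(profiles, model, iterations=5, seed=0)

    def test_positive_spread_with_variation(self, reference_model):
        profiles, model = reference_model
        s = shape.resample_reference(profiles, model, iterations=200, seed=3)
        assert (s.distances >= 0).all()
        assert s.distances.std() > 0

    def test_single_outgroup_pair_constant(self, reference_model):
        _, model = reference_model
        profiles = pd.DataFrame(
            [
                {"subject_id": "c1", "group": "o", **{r: v for r, v in
                 zip(REGIONS, np.linspace(0.1, 1, N_REGIONS))}},
                {"subject_id": "c1", "group": "o", **{r: v for r, v in
                 zip(REGIONS, np.linspace(0, 0.9, N_REGIONS))}},
            ],
            index=["f1", "f2"],
        )
        s = shape.resample_outgroup(profiles, model, iterations=25, seed=1)
        assert len(s.distances) == 25
        assert np.allclose(s.distances, s.distances[0])

    def test_outgroup_with_reference_parameters_indistinguishable(self):
        # When the "out-group" is drawn from the reference population its
        # distance distribution should be statistically indistinguishable
        # from the leave-subject-out reference null: a rank test at
        # alpha 0.01 rejects in at most 2 of 20 seeds.  The population
        # must be large: an estimated 14-dim covariance places in-sample
        # points systematically closer than fresh ones by O(p/n), which a
        # rank test this size can detect for populations of a few hundred
        # subjects or fewer.
        rejections = 0
        for seed in range(20):
            ref_morph = syn.default_reference_morph(n_subjects=800, n_tracks=4)
            clone = syn.default_reference_morph(n_subjects=800, n_tracks=4)
            clone.name = "outgroup"
            df = syn.generate_depth_dataset([ref_morph, clone], seed=1000 + seed)
            ref = _profiles_from_dataset(df, "reference")
            out = _profiles_from_dataset(df, "outgroup")
            model = shape.build_covariance(shape.subject_mean_profiles(ref))
            s_ref = shape.resample_reference(ref, model, iterations=300, seed=seed)
            s_out = shape.resample_outgroup(out, model, iterations=300, seed=seed + 500)
            p = mannwhitneyu(s_ref.distances, s_out.distances).pvalue
            rejections += p <= 0.01
        assert rejections <= 2


class TestDistanceNonDegeneracy:
    def test_distances_nonnegative_and_spread_positive(self, reference_model):
        profiles, model = reference_model
        s = shape.resample_reference(profiles, model, iterations=100, seed=1)
        assert (s.distances >= 0).all() and np.ptp(s.distances) > 0


class TestFossilCombinations:
    def test_counts(self, reference_model):
        profiles, model = reference_model
        five = profiles.iloc[:5]
        assert len(shape.fossil_combination_distances(five, model).distances) == 10
        two = profiles.iloc[:2]
        assert len(shape.fossil_combination_distances(two, model).distances) == 1

    def test_tracks_at_model_mean_give_zero(self, reference_model):
        _, model = reference_model
        profiles = pd.DataFrame(
            [
                {"subject_id": "f", "group": "fossil",
                 **dict(zip(REGIONS, model.mean_profile))},
            ] * 2,
            index=["t1", "t2"],
        )
        s = shape.fossil_combination_distances(profiles, model)
        assert s.distances[0] == pytest.approx(0.0, abs=1e-9)

    def test_single_track_rejected(self, reference_model):
        profiles, model = reference_model
        with pytest.raises(ValueError, match=">= 2 tracks"):
            shape.fossil_combination_distances(profiles.iloc[:1], model)


class TestClassify:
    def _sample(self, values, label="x"):
        return shape.DistanceSample(label=label, distances=np.asarray(values, float),
                                    iterations=len(values))

    def test_minimum_is_within_with_low_percentile(self):
        ref = self._sample(np.linspace(1, 10, 100), "reference")
        cand = self._sample([1.0])
        row = shape.classify_within(cand, ref).iloc[0]
        assert row["verdict"] == "within"
        assert row["percentile"] <= 1 / 100

    def test_above_maximum_is_outside(self):
        ref = self._sample(np.linspace(1, 10, 100), "reference")
        row = shape.classify_within(self._sample([11.0]), ref).iloc[0]
        assert row["verdict"] == "outside"

    def test_boundary_inclusive_at_quantile_one(self):
        ref = self._sample(np.linspace(1, 10, 100), "reference")
        row = shape.classify_within(self._sample([10.0]), ref, quantile=1.0).iloc[0]
        assert row["verdict"] == "within"


class TestDepthScaleTest:
    def test_identical_groups_p_one(self):
        a = np.linspace(1, 5, N_REGIONS)
        assert shape.depth_scale_test(a, a) == 1.0

    def test_all_positive_differences(self):
        # 14 one-sided differences: only the two extreme sign assignments
        # are as extreme, so p = 2 / 2^14.
        a = np.linspace(2, 6, N_REGIONS)
        b = a - np.linspace(0.1, 1.0, N_REGIONS)
        assert shape.depth_scale_test(a, b) == pytest.approx(2 / 2**14, abs=1e-12)

    def test_matches_scipy_exact_oracle(self, rng):
        for _ in range(100):
            a = rng.random(N_REGIONS) * 5
            b = a + rng.normal(0, 1, N_REGIONS)  # continuous: no ties/zeros
            p_mine = shape.depth_scale_test(a, b)
            p_scipy = wilcoxon(a, b, method="exact").pvalue
            assert p_mine == pytest.approx(p_scipy, abs=1e-8)


class TestClassificationRecovery:
    def test_two_morph_classification(self):
        # Synthetic analogue of the fossil comparison: candidate sites
        # drawn from the reference morph must classify within the
        # resampled human-like distribution and out-group-morph sites
        # outside it, in >= 90% of seeded replicates.
        ref_ok = out_ok = 0
        n_rep = 20
        for seed in range(n_rep):
            df = syn.generate_depth_dataset(
                [syn.default_reference_morph(40, 6), syn.default_outgroup_morph(2, 20)],
                seed=seed,
            )
            ref = _profiles_from_dataset(df, "reference")
            model = shape.build_covariance(shape.subject_mean_profiles(ref))
            null = shape.resample_reference(ref, model, iterations=1000, seed=seed)

            site_ref = syn.MorphSpec(
                name="cand_ref", region_means=dict(syn.HUMAN_LIKE_MEANS),
                between_subject_sd=0.0, within_subject_sd=0.5,
                n_subjects=1, n_tracks_per_subject=2,
            )
            site_out = syn.MorphSpec(
                name="cand_out", region_means=dict(syn.CHIMP_LIKE_MEANS),
                between_subject_sd=0.0, within_subject_sd=0.5,
                n_subjects=1, n_tracks_per_subject=2,
            )
            cand = syn.generate_depth_dataset([site_ref, site_out], seed=10_000 + seed)
            v_ref = shape.classify_within(
                shape.fossil_combination_distances(
                    _profiles_from_dataset(cand, "cand_ref"), model
                ),
                null,
            )
            v_out = shape.classify_within(
                shape.fossil_combination_distances(
                    _profiles_from_dataset(cand, "cand_out"), model
                ),
                null,
            )
            ref_ok += (v_ref["verdict"] == "within").all()
            out_ok += (v_out["verdict"] == "outside").all()
        assert ref_ok >= 0.9 * n_rep
        assert out_ok >= 0.9 * n_rep
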
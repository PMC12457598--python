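"""Consensus reference rating: initial mean, exclusions, profiles,
weighting, leave-one-out."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from boneage_calib import (
    Cohort,
    ConsensusError,
    RaterProfile,
    apply_exclusions,
    build_consensus,
    consensus_pipeline,
    fit_rater_profiles,
    initial_consensus,
    leave_one_out_consensus,
)
from boneage_calib.consensus import REASON_DEVIATION, REASON_MISSING
from boneage_calib.simulate import default_gbad_like_config, generate_cohort


def cohort_from_ratings(ratings, sex="female", **extra):
    """Build a minimal cohort from an (n_images x n_raters) list of lists."""
    ratings = np.asarray(ratings, dtype=float)
    n, k = ratings.shape
    frame = pd.DataFrame({"image_id": [f"i{j}" for j in range(n)]})
    frame["sex"] = sex
    frame["ca_months"] = 100.0
    raters = [f"r{j + 1}" for j in range(k)]
    for j, r in enumerate(raters):
        frame[r] = ratings[:, j]
    frame["ai_ba_months"] = extra.get("ai", 100.0)
    frame["disorder"] = False
    return Cohort(frame, raters)


class TestInitialConsensus:
    @pytest.mark.parametrize(
        "ratings,expected",
        [
            ([[100, 100, 100]], 100.0),
            ([[90, 100, 110]], 100.0),
            ([[96, 102, np.nan]], 99.0),
        ],
    )
    def test_mean_over_available_ratings(self, ratings, expected):
        cohort = cohort_from_ratings(ratings)
        assert initial_consensus(cohort).iloc[0] == pytest.approx(expected)

    def test_image_with_no_rating_is_an_error(self):
        cohort = cohort_from_ratings([[np.nan, np.nan, np.nan], [1, 2, 3]])
        with pytest.raises(ConsensusError, match="i0"):
            initial_consensus(cohort)


class TestExclusions:
    @pytest.mark.parametrize(
        "ratings,excluded",
        [
            ([100, 100, 131], False),  # max deviation 20.67 <= 30
            ([100, 100, 145], False),  # deviation exactly 30: strict rule keeps it
            ([100, 100, 146], True),  # deviation 30.67 > 30
        ],
    )
    def test_strict_30_month_deviation_rule(self, ratings, excluded):
        cohort = cohort_from_ratings([ratings])
        initial = initial_consensus(cohort)
        filtered, dropped = apply_exclusions(cohort, initial)
        assert (filtered.n_images == 0) == excluded
        if excluded:
            assert dropped == [("i0", REASON_DEVIATION)]

    def test_missing_rating_excluded_with_reason(self):
        cohort = cohort_from_ratings([[100, np.nan, 100], [90, 95, 100]])
        filtered, dropped = apply_exclusions(cohort, initial_consensus(cohort))
        assert dropped == [("i0", REASON_MISSING)]
        assert list(filtered.frame["image_id"]) == ["i1"]

    def test_missing_rating_kept_when_disabled(self):
        cohort = cohort_from_ratings([[100, np.nan, 100]])
        filtered, dropped = apply_exclusions(
            cohort, initial_consensus(cohort), drop_missing=False
        )
        assert filtered.n_images == 1 and dropped == []

    def test_nonpositive_threshold_rejected(self):
        cohort = cohort_from_ratings([[1, 2, 3]])
        with pytest.raises(ConsensusError):
            apply_exclusions(cohort, initial_consensus(cohort), deviation_threshold=0)


class TestRaterProfiles:
    def test_constant_offset_becomes_smd_bias(self):
        base = np.array([[100.0, 100, 100], [60, 60, 60], [140, 140, 140]])
        base[:, 1] += 6.0
        cohort = cohort_from_ratings(base)
        profiles = fit_rater_profiles(cohort, initial_consensus(cohort))
        assert profiles[1].smd_bias == pytest.approx(6.0 - 2.0)  # vs panel mean +2
        # bias-corrected rater 2 agrees perfectly with its own offset removed
        assert profiles[1].mad == pytest.approx(0.0, abs=1e-12)

    def test_weights_are_inverse_mad_normalized(self):
        """Weights are exactly (1/MAD) normalized across the panel."""
        rng = np.random.default_rng(0)
        ratings = 100 + rng.normal(0, 10, (40, 1)) + rng.normal(0, [2, 5, 9], (40, 3))
        cohort = cohort_from_ratings(ratings)
        fitted = fit_rater_profiles(cohort, initial_consensus(cohort))
        mads = np.array([p.mad for p in fitted])
        weights = np.array([p.weight for p in fitted])
        np.testing.assert_allclose(weights, (1 / mads) / np.sum(1 / mads), rtol=1e-12)
        assert weights.argmax() == mads.argmin()

    def test_engineered_mad_ratio_gives_exact_weights(self):
        """MADs in ratio 6:3:3 must yield weights (0.2, 0.4, 0.4)."""
        n = 20
        base = 100 + np.arange(float(n))
        z = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)  # balanced signs
        # deviations s_j * z_i with s = (6, -3, -3): row sums 0, so the
        # initial mean is exactly `base` and MAD_j = |s_j|
        ratings = np.column_stack([base + 6 * z, base - 3 * z, base - 3 * z])
        fitted = fit_rater_profiles(
            cohort_from_ratings(ratings), initial_consensus(cohort_from_ratings(ratings))
        )
        np.testing.assert_allclose([p.mad for p in fitted], [6.0, 3.0, 3.0], rtol=1e-12)
        np.testing.assert_allclose(
            [p.weight for p in fitted], [0.2, 0.4, 0.4], rtol=1e-12
        )

    def test_zero_mad_rater_gets_floored_weight_with_warning(self):
        base = 100 + np.arange(10.0)
        d = np.where(np.arange(10) % 2 == 0, 3.0, -3.0)
        # rater 1 sits exactly at the panel midpoint (plus a constant), so
        # its bias-corrected MAD against the initial mean is exactly 0
        ratings = np.column_stack([base + 2.0, base + d, base - d])
        cohort = cohort_from_ratings(ratings)
        initial = initial_consensus(cohort)
        with pytest.warns(RuntimeWarning, match="flooring"):
            profiles = fit_rater_profiles(cohort, initial)
        weights = np.array([p.weight for p in profiles])
        assert weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert profiles[0].mad == 0.0
        assert weights[0] > 0.99 and weights[1] == pytest.approx(weights[2])


class TestBuildConsensus:
    def test_identical_unbiased_raters_pass_through(self):
        ratings = np.column_stack([[100.0, 60, 140]] * 3)
        cohort = cohort_from_ratings(ratings)
        result = consensus_pipeline(cohort)
        np.testing.assert_allclose(result.consensus.to_numpy(), [100, 60, 140])

    def test_bias_corrected_ratings_agree(self):
        # two raters with +2/-2 biases around a common latent rating of 100
        ratings = np.array([[102.0, 98.0], [62.0, 58.0], [142.0, 138.0]])
        cohort = cohort_from_ratings(ratings)
        result = consensus_pipeline(cohort)
        np.testing.assert_allclose(result.consensus.to_numpy(), [100, 60, 140])

    def test_matches_spreadsheet_style_oracle(self):
        """3x3 toy table equals a fully hand-unrolled weighted average."""
        ratings = np.array([[100.0, 104, 90], [60, 66, 57], [140, 147, 130]])
        cohort = cohort_from_ratings(ratings)
        result = consensus_pipeline(cohort)

        init = [np.mean(row) for row in ratings]
        smd = [np.mean([ratings[i][j] - init[i] for i in range(3)]) for j in range(3)]
        mad = [
            np.mean([abs(ratings[i][j] - smd[j] - init[i]) for i in range(3)])
            for j in range(3)
        ]
        inv = [1.0 / m for m in mad]
        weights = [v / sum(inv) for v in inv]
        expected = [
            sum(weights[j] * (ratings[i][j] - smd[j]) for j in range(3))
            for i in range(3)
        ]
        np.testing.assert_allclose(result.consensus.to_numpy(), expected, atol=1e-12)

    def test_rater_mismatch_rejected(self, tiny_cohort):
        profiles = (RaterProfile("r1", 0, 1, 0.5), RaterProfile("zz", 0, 1, 0.5))
        with pytest.raises(ConsensusError, match="zz"):
            build_consensus(tiny_cohort, profiles)


class TestConsensusInvariants:
    def test_weights_sum_to_one(self, gbad_cohort):
        cohort, _ = gbad_cohort
        result = consensus_pipeline(cohort)
        assert result.weights.sum() == pytest.approx(1.0, abs=1e-9)
        inv_mad = 1.0 / np.array([p.mad for p in result.profiles])
        np.testing.assert_allclose(result.weights, inv_mad / inv_mad.sum(), atol=1e-9)

    @given(offset=st.floats(-50, 50))
    def test_constant_rater_offset_absorbed_up_to_panel_mean(self, offset):
        """Adding a constant to one rater's column leaves every weight and
        MAD unchanged, and shifts the consensus by exactly offset/k — the
        bias correction is anchored to the initial panel mean, which
        retains the panel's mean shift by construction."""
        rng = np.random.default_rng(7)
        ratings = 100 + rng.normal(0, 10, size=(30, 4)) + rng.normal(0, 3, size=(30, 1))
        cohort = cohort_from_ratings(ratings)
        baseline = consensus_pipeline(cohort, deviation_threshold=1e9)
        shifted_ratings = ratings.copy()
        shifted_ratings[:, 2] += offset
        shifted = consensus_pipeline(
            cohort_from_ratings(shifted_ratings), deviation_threshold=1e9
        )
        np.testing.assert_allclose(
            [p.weight for p in baseline.profiles],
            [p.weight for p in shifted.profiles],
            atol=1e-9,
        )
        np.testing.assert_allclose(
            [p.mad for p in baseline.profiles],
            [p.mad for p in shifted.profiles],
            atol=1e-9,
        )
        np.testing.assert_allclose(
            shifted.consensus.to_numpy() - baseline.consensus.to_numpy(),
            offset / 4.0,
            atol=1e-9,
        )

    def test_permutation_invariant_in_rater_order(self):
        rng = np.random.default_rng(3)
        ratings = 100 + rng.normal(0, 8, size=(25, 5))
        cohort = cohort_from_ratings(ratings)
        permuted = cohort_from_ratings(ratings[:, [3, 0, 4, 1, 2]])
        np.testing.assert_allclose(
            consensus_pipeline(cohort).consensus.to_numpy(),
            consensus_pipeline(permuted).consensus.to_numpy(),
            atol=1e-12,
        )

    def test_equal_mads_reduce_to_unweighted_mean(self):
        # two +/-d pairs with different sign patterns: row sums are zero, so
        # every rater has MAD exactly 5 and the weights are all 1/4
        base = 100 + np.arange(20.0)
        d1 = np.where(np.arange(20) % 2 == 0, 1.0, -1.0) * 5
        d2 = np.where(np.arange(20) % 4 < 2, 1.0, -1.0) * 5
        ratings = np.column_stack([base + d1, base - d1, base + d2, base - d2])
        cohort = cohort_from_ratings(ratings)
        result = consensus_pipeline(cohort)
        np.testing.assert_allclose([p.mad for p in result.profiles], 5.0, rtol=1e-12)
        corrected = ratings - np.array([p.smd_bias for p in result.profiles])
        np.testing.assert_allclose(
            result.consensus.to_numpy(), corrected.mean(axis=1), atol=1e-9
        )


class TestLeaveOneOut:
    def test_redundant_rater_leaves_consensus_unchanged(self):
        rng = np.random.default_rng(5)
        base = 100 + rng.normal(0, 10, size=24)
        ratings = np.column_stack([base, base, base, base])
        cohort = cohort_from_ratings(ratings)
        full = consensus_pipeline(cohort)
        loo = leave_one_out_consensus(cohort, "r4")
        np.testing.assert_allclose(
            full.consensus.to_numpy(), loo.consensus.to_numpy(), atol=1e-9
        )

    def test_equals_pipeline_on_rater_deleted_cohort(self, gbad_cohort):
        """Oracle equivalence: masking a rater must match physically
        deleting the rater column and re-running the standard pipeline."""
        cohort, _ = gbad_cohort
        for rater in cohort.rater_ids[:3]:
            loo = leave_one_out_consensus(cohort, rater)
            oracle = consensus_pipeline(cohort.drop_rater(rater))
            pd.testing.assert_series_equal(loo.consensus, oracle.consensus,
                                           check_exact=True)
            assert [p.weight for p in loo.profiles] == [
                p.weight for p in oracle.profiles
            ]

    def test_unknown_rater_and_small_panel_rejected(self, tiny_cohort):
        with pytest.raises(ConsensusError, match="unknown"):
            leave_one_out_consensus(tiny_cohort, "r9")
        with pytest.raises(ConsensusError, match="at least 3"):
            leave_one_out_consensus(tiny_cohort.drop_rater("r3"), "r1")

    def test_seven_rater_panel_yields_seven_distinct_tables(self, gbad_cohort):
        cohort, _ = gbad_cohort
        consensuses = [
            leave_one_out_consensus(cohort, r).consensus for r in cohort.rater_ids
        ]
        assert len(consensuses) == 7
        for a in range(7):
            for b in range(a + 1, 7):
                assert not consensuses[a].equals(consensuses[b])


def test_iterative_mode_converges_and_stays_close():
    cohort, _ = generate_cohort(default_gbad_like_config(seed=4))
    single = consensus_pipeline(cohort)
    iterated = consensus_pipeline(cohort, iterate=True)
    diff = np.abs(single.consensus.to_numpy() - iterated.consensus.to_numpy())
    assert diff.max() < 1.0  # refinement is a small perturbation, not a rewrite
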
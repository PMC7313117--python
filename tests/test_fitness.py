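"""Condition indices, growth, weighted correlations and randomization tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cpforage import (
    correlate_tendency,
    dbmi,
    feeding_frequency,
    randomization_test,
    residualize,
    scaled_mass_index,
    sma_slope,
    weighted_corr,
)


class TestScaledMassIndex:
    def test_equal_keels_returns_mass(self):
        mass = np.array([110.0, 120.0, 130.0])
        keel = np.array([39.0, 39.0, 39.0])
        assert np.allclose(scaled_mass_index(mass, keel), mass)

    def test_perfect_power_law_collapses_to_constant(self):
        keel = np.array([36.0, 38.0, 40.0, 42.0])
        mass = 0.08 * keel**2.0
        smi = scaled_mass_index(mass, keel)
        assert np.allclose(smi, smi[0], rtol=1e-9)

    def test_matches_bruteforce_sma_oracle(self):
        mass = np.array([101.0, 118.0, 124.0, 131.0, 112.0])
        keel = np.array([36.5, 38.2, 40.1, 41.3, 37.8])
        lx, ly = np.log(keel), np.log(mass)
        b_sma = np.sign(np.corrcoef(lx, ly)[0, 1]) * np.std(ly, ddof=1) / np.std(lx, ddof=1)
        expected = mass * (keel.mean() / keel) ** b_sma
        assert np.allclose(scaled_mass_index(mass, keel), expected, atol=1e-9)
        assert sma_slope(lx, ly) == pytest.approx(b_sma, rel=1e-12)

    def test_uncorrelated_slope_rejected(self):
        with pytest.raises(ValueError):
            sma_slope([1.0, 2.0, 1.0, 2.0], [3.0, 3.0, 5.0, 5.0])


class TestDbmi:
    def test_two_nestlings_doubling_in_a_week(self):
        brood = pd.DataFrame(
            {"bm_first": [30.0, 40.0], "bm_second": [60.0, 80.0], "i_days": [7, 7]}
        )
        assert dbmi(brood) == pytest.approx(1.0 / 7.0, rel=1e-12)

    def test_single_nestling_example(self):
        brood = pd.DataFrame({"bm_first": [40.0], "bm_second": [44.0], "i_days": [8]})
        assert dbmi(brood) == pytest.approx(0.0125, rel=1e-12)

    def test_dead_nestling_excluded_from_m(self):
        brood = pd.DataFrame(
            {
                "bm_first": [30.0, 40.0, 35.0],
                "bm_second": [60.0, 80.0, np.nan],
                "i_days": [7, 7, 7],
            }
        )
        # average over the 2 survivors only
        by_hand = 0.5 * ((60 - 30) / 30 / 7 + (80 - 40) / 40 / 7)
        assert dbmi(brood) == pytest.approx(by_hand, rel=1e-12)

    def test_scale_invariance(self):
        brood = pd.DataFrame(
            {"bm_first": [30.0, 42.0], "bm_second": [55.0, 70.0], "i_days": [8, 8]}
        )
        scaled = brood.copy()
        scaled[["bm_first", "bm_second"]] *= 3.7
        assert dbmi(brood) == pytest.approx(dbmi(scaled), rel=1e-12)

    def test_no_survivors_rejected(self):
        brood = pd.DataFrame({"bm_first": [30.0], "bm_second": [np.nan], "i_days": [7]})
        with pytest.raises(ValueError):
            dbmi(brood)


class TestResidualize:
    def test_orthogonal_centered_response_unchanged(self, rng):
        p = rng.standard_normal(50)
        y = rng.standard_normal(50)
        y -= np.column_stack([np.ones(50), p]) @ np.linalg.lstsq(
            np.column_stack([np.ones(50), p]), y, rcond=None
        )[0]
        assert np.allclose(residualize(y, p), y, atol=1e-10)

    def test_residuals_uncorrelated_with_predictors(self, rng):
        P = rng.standard_normal((60, 3))
        y = P @ np.array([1.0, -2.0, 0.5]) + rng.standard_normal(60)
        r = residualize(y, P)
        assert abs(r.mean()) < 1e-10
        for j in range(3):
            assert abs(np.corrcoef(r, P[:, j])[0, 1]) < 1e-10


class TestFeedingFrequency:
    def test_rate(self):
        assert feeding_frequency(12, 16.0) == pytest.approx(0.75)

    def test_scale_invariance(self):
        assert feeding_frequency(24, 32.0) == feeding_frequency(12, 16.0)

    def test_zero_hours_rejected(self):
        with pytest.raises(ValueError):
            feeding_frequency(3, 0.0)


class TestWeightedCorr:
    def test_equal_weights_match_pearson(self, rng):
        x, y = rng.standard_normal(20), rng.standard_normal(20)
        r_w = weighted_corr(x, y, np.full(20, 2.5))
        assert r_w == pytest.approx(stats.pearsonr(x, y)[0], abs=1e-12)

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(0.1, 10.0), min_size=4, max_size=10))
    def test_perfect_linear_relation_is_one(self, weights):
        x = np.arange(len(weights), dtype=float)
        y = 2.0 * x + 1.0
        assert weighted_corr(x, y, np.array(weights)) == pytest.approx(1.0, abs=1e-9)

    def test_four_point_formula_oracle(self):
        x = np.array([1.0, 2.0, 4.0, 5.0])
        y = np.array([1.5, 1.0, 3.0, 2.0])
        w = np.array([1.0, 2.0, 1.0, 0.5])
        xm = (w * x).sum() / w.sum()
        ym = (w * y).sum() / w.sum()
        expected = ((w * (x - xm) * (y - ym)).sum()
                    / math.sqrt((w * (x - xm) ** 2).sum() * (w * (y - ym) ** 2).sum()))
        assert weighted_corr(x, y, w) == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            weighted_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [1.0, 1.0, 1.0])


class TestRandomization:
    def test_exhaustive_equals_direct_enumeration(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(5)
        y = x + 0.3 * rng.standard_normal(5)
        w = rng.uniform(0.5, 2.0, 5)
        p = randomization_test(x, y, w)
        r_obs = abs(weighted_corr(x, y, w))
        count = sum(
            abs(weighted_corr(x, y[list(perm)], w)) >= r_obs - 1e-12
            for perm in itertools.permutations(range(5))
        )
        assert p == pytest.approx(count / math.factorial(5), rel=1e-12)

    def test_self_correlation_is_maximally_significant(self):
        x = np.array([0.2, 1.1, -0.7, 2.0, 0.5])
        p = randomization_test(x, x, np.ones(5))
        # only permutations reproducing |r| = 1 count; p = (#ties)/120
        assert 0 < p <= 4 / 120 + 1e-12

    def test_p_value_always_positive(self, rng):
        x, y = rng.standard_normal(12), rng.standard_normal(12)
        p = randomization_test(x, y, np.ones(12), n_perm=199, seed=1)
        assert 0 < p <= 1


class TestCorrelateTendency:
    def _adults(self, rng, coupling, n=25):
        tendency = rng.standard_normal(n)
        sd = rng.uniform(0.2, 0.5, n)
        return pd.DataFrame(
            {
                "individual_id": [f"I{i}" for i in range(n)],
                "sex": rng.integers(0, 2, n),
                "tendency": tendency + rng.standard_normal(n) * 0.2,
                "tendency_sd": sd,
                "residual_dbmi": coupling * tendency + rng.standard_normal(n) * 0.5,
                "device_load": rng.uniform(0.04, 0.055, n),
            }
        )

    def test_positive_coupling_recovered(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            out = correlate_tendency(self._adults(rng, 1.0), n_perm=99, seed=seed)
            row = out[out["target"] == "residual_dbmi"].iloc[0]
            hits += row["r_w"] > 0
        assert hits >= 27  # >= 90 % of replicates

    def test_null_coupling_gives_small_correlations(self):
        rs = []
        for seed in range(30):
            rng = np.random.default_rng(100 + seed)
            out = correlate_tendency(self._adults(rng, 0.0), n_perm=99, seed=seed)
            rs.append(out[out["target"] == "residual_dbmi"]["r_w"].iloc[0])
        assert abs(np.mean(rs)) < 0.15

    def test_equal_weights_reduce_to_unweighted(self, rng):
        adults = self._adults(rng, 1.0)
        adults["tendency_sd"] = 1.0
        out = correlate_tendency(adults, n_perm=99, seed=0)
        row = out[out["target"] == "residual_dbmi"].iloc[0]
        expected = stats.pearsonr(adults["tendency"], adults["residual_dbmi"])[0]
        assert row["r_w"] == pytest.approx(expected, abs=1e-12)

    def test_device_load_analysed_per_sex(self, rng):
        out = correlate_tendency(self._adults(rng, 0.5), n_perm=99, seed=0)
        assert {"device_load_sex0", "device_load_sex1"} <= set(out["target"])
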
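import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from kasphi.stats import (
    biomass_effect_test,
    bland_altman,
    concordance,
    holm,
    permutation_ancova,
    profile_bias_tests,
    snp_bias,
    variance_homogeneity,
)


class TestHolm:
    def test_hand_applied_step_down(self):
        # sorted {0.01, 0.03, 0.04}: 0.01*3=0.03; max(0.03, 0.03*2)=0.06;
        # max(0.06, 0.04*1)=0.06 -> mapped back to input order
        assert holm([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=12))
    def test_adjusted_at_least_raw_and_monotone(self, ps):
        adj = holm(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_nan_passthrough(self):
        adj = holm([0.02, np.nan, 0.5])
        assert np.isnan(adj[1]) and np.isfinite(adj[0])


class TestBlandAltman:
    def test_hand_computed_loa(self):
        res = bland_altman([0.1, -0.1, 0.0, 0.2])
        assert res.mean_bias == pytest.approx(0.05)
        assert res.sd == pytest.approx(0.12909944, abs=1e-7)
        assert res.loa_low == pytest.approx(0.05 - 1.96 * res.sd)
        assert res.loa_high == pytest.approx(0.05 + 1.96 * res.sd)

    def test_all_zero_differences(self):
        res = bland_altman([0.0, 0.0, 0.0])
        assert (res.mean_bias, res.loa_low, res.loa_high) == (0.0, 0.0, 0.0)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([0.1])

    def test_normal_coverage_approaches_95_percent(self):
        rng = np.random.default_rng(7)
        d = rng.normal(0.02, 0.1, size=20000)
        res = bland_altman(d)
        inside = np.mean((d >= res.loa_low) & (d <= res.loa_high))
        # 3 binomial SE at n = 20000 is ~0.0046
        assert inside == pytest.approx(0.95, abs=0.005)


class TestSnpBias:
    def test_zero_deviations_retained(self):
        res = snp_bias({"s1": [0.0] * 10}, B=200, seed=0)[0]
        assert res.median_bias == 0.0 and (res.ci_low, res.ci_high) == (0.0, 0.0)
        assert res.retained

    def test_large_constant_bias_not_retained(self):
        res = snp_bias({"s1": [0.2] * 10}, B=200, seed=0)[0]
        assert (res.ci_low, res.ci_high) == (pytest.approx(0.2), pytest.approx(0.2))
        assert not res.retained

    def test_small_noise_retained_with_high_probability(self):
        rng = np.random.default_rng(42)
        devs = {f"s{i}": rng.normal(0, 0.01, 30) for i in range(10)}
        results = snp_bias(devs, B=2000, seed=1)
        assert sum(r.retained for r in results) == 10

    def test_single_deviation_unevaluable(self):
        res = snp_bias({"s1": [0.1]}, B=100, seed=0)[0]
        assert not res.evaluable and not res.retained

    @given(st.lists(st.floats(-1, 1), min_size=2, max_size=40))
    def test_percentile_ci_contains_sample_median(self, devs):
        res = snp_bias({"s": devs}, B=500, seed=3)[0]
        assert res.ci_low - 1e-12 <= res.median_bias <= res.ci_high + 1e-12


class TestConcordance:
    def test_monotone_pairs_rho_one(self):
        out = concordance([1, 2, 3, 4], [10, 20, 30, 40], ["r"] * 4)
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_reversed_pairs_rho_minus_one(self):
        out = concordance([4, 3, 2, 1], [1, 2, 3, 4], ["r"] * 4)
        assert out.loc[0, "rho"] == pytest.approx(-1.0)

    def test_rank_preserving_noise_still_rho_one(self):
        obs = [0.0, 0.3, 0.45, 0.8, 0.95]
        exp = [0.0, 0.25, 0.5, 0.75, 1.0]
        out = concordance(obs, exp, ["r"] * 5)
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_constant_expected_undefined(self):
        out = concordance([1, 2, 3], [5, 5, 5], ["r"] * 3)
        assert np.isnan(out.loc[0, "rho"]) and "undefined" in out.loc[0, "note"]

    def test_exact_small_n_p_matches_enumeration(self):
        # perfect monotone n=5: p = 2/5! * (# of perms achieving |rho|=1) = 2/120
        out = concordance([1, 2, 3, 4, 5], [2, 4, 6, 8, 10], ["r"] * 5)
        assert out.loc[0, "p"] == pytest.approx(2 / 120)


class TestPermutationAncova:
    def _null_data(self, seed, n_per=30):
        rng = np.random.default_rng(seed)
        exp = np.tile(np.repeat([0, 0.25, 0.5, 0.75, 1.0], n_per // 5), 2)
        obs = exp + rng.normal(0, 0.1, size=2 * n_per)
        reg = np.repeat(["low", "high"], n_per)
        return obs, exp, reg

    def test_duplicated_data_gives_large_p(self):
        rng = np.random.default_rng(0)
        exp = np.repeat([0, 0.5, 1.0], 10)
        obs = exp + rng.normal(0, 0.05, 30)
        res = permutation_ancova(
            np.tile(obs, 2), np.tile(exp, 2), np.repeat(["a", "b"], 30),
            n_perm=999, seed=1,
        )
        assert res.p_regime > 0.3 and res.p_interaction > 0.3

    def test_strong_regime_offset_detected(self):
        obs, exp, reg = self._null_data(5)
        obs = obs + np.where(reg == "low", 0.5, 0.0)
        res = permutation_ancova(obs, exp, reg, n_perm=999, seed=2)
        assert res.p_regime < 0.01

    def test_interaction_detected_when_slopes_differ(self):
        obs, exp, reg = self._null_data(6)
        obs = obs + np.where(reg == "low", 0.8 * exp, 0.0)
        res = permutation_ancova(obs, exp, reg, n_perm=999, seed=3)
        assert res.p_interaction < 0.01

    def test_zero_permutations_is_error(self):
        obs, exp, reg = self._null_data(7)
        with pytest.raises(ValueError):
            permutation_ancova(obs, exp, reg, n_perm=0)

    def test_one_regime_is_error(self):
        with pytest.raises(ValueError):
            permutation_ancova([1, 2, 3], [1, 2, 3], ["a", "a", "a"])


def _dev_frame(devs_by_profile, regime="low"):
    rows = []
    for prof, devs in devs_by_profile.items():
        for d in devs:
            rows.append(dict(profile=prof, regime=regime, deviation=d))
    return pd.DataFrame(rows)


class TestProfileBias:
    def test_identical_distributions_large_kw_p(self):
        rng = np.random.default_rng(1)
        base = {p: rng.normal(0, 0.1, 27) for p in (0.0, 0.25, 0.5, 0.75, 1.0)}
        kw, _ = profile_bias_tests(_dev_frame(base))
        assert kw.loc[0, "p"] > 0.01

    def test_shifted_profile_flagged_after_holm(self):
        rng = np.random.default_rng(2)
        base = {p: rng.normal(0, 0.1, 27) for p in (0.0, 0.5, 1.0)}
        base[0.25] = rng.normal(0.2, 0.1, 27)
        kw, w = profile_bias_tests(_dev_frame(base))
        flagged = w[(w["profile"] == 0.25)].iloc[0]
        assert flagged["p_adj"] < 0.05
        assert flagged["median_deviation"] > 0.1
        assert kw.loc[0, "p"] < 0.001

    def test_all_zero_profile_reports_p_one(self):
        _, w = profile_bias_tests(_dev_frame({0.0: [0.0] * 10, 0.5: [0.1, -0.2, 0.3] * 4}))
        assert w[w["profile"] == 0.0].iloc[0]["p"] == 1.0


class TestVarianceHomogeneity:
    def test_equal_spread_not_significant(self):
        rng = np.random.default_rng(3)
        out = variance_homogeneity(
            _dev_frame({0.0: rng.normal(0, 0.1, 50), 1.0: rng.normal(0, 0.1, 50)})
        )
        assert out.loc[0, "p"] > 0.05

    def test_tenfold_spread_difference_detected(self):
        rng = np.random.default_rng(4)
        out = variance_homogeneity(
            _dev_frame({0.0: rng.normal(0, 0.02, 50), 0.5: rng.normal(0, 0.2, 50)})
        )
        assert out.loc[0, "p_adj"] < 0.01

    def test_five_profiles_yield_ten_pairs(self):
        rng = np.random.default_rng(5)
        out = variance_homogeneity(
            _dev_frame({p: rng.normal(0, 0.1, 10) for p in (0, 0.25, 0.5, 0.75, 1.0)})
        )
        assert len(out) == 10

    def test_degenerate_pair_untestable(self):
        out = variance_homogeneity(_dev_frame({0.0: [0.1, 0.1, 0.1], 1.0: [0.2, 0.2]}))
        assert np.isnan(out.loc[0, "p"]) and "untestable" in out.loc[0, "note"]


class TestBiomassEffect:
    def test_identical_pairs_p_one(self):
        unc = [0.1, 0.2, 0.15, 0.3]
        out = biomass_effect_test({0.25: (unc, unc)})
        assert out.loc[0, "p"] == 1.0 and out.loc[0, "median_paired_diff"] == 0.0

    def test_uniform_improvement_detected(self):
        rng = np.random.default_rng(6)
        unc = rng.uniform(0.2, 0.5, 20)
        out = biomass_effect_test({0.25: (unc, unc - 0.1)})
        assert out.loc[0, "p_adj"] < 0.01

    def test_single_pair_untestable(self):
        out = biomass_effect_test({0.75: ([0.3], [0.2])})
        assert np.isnan(out.loc[0, "p"]) and "single pair" in out.loc[0, "note"]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            biomass_effect_test({0.25: ([0.1, 0.2], [0.1])})
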
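"""Matched-pair replication: matching, paired tests, Fisher's method,
power calculations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pedigwas.errors import ConfigurationError
from pedigwas.replication import (
    MatchedPair,
    MatchedPairSet,
    fisher_combine,
    fold_summary,
    match_controls,
    min_detectable_effect,
    paired_log_t,
    power_at,
    triplicate_mean,
    wilcoxon_signed_rank,
)


def _pair_set(carrier_vals, control_vals):
    return MatchedPairSet(pairs=[
        MatchedPair(f"car{k}", f"ctl{k}", cv, tv, 1, 1950, 1950, 0)
        for k, (cv, tv) in enumerate(zip(carrier_vals, control_vals))
    ])


class TestTriplicateMean:
    @pytest.mark.parametrize("vals,expected", [
        ([10, 10, 10], 10.0),
        ([5, 10, 15], 10.0),
    ])
    def test_mean(self, vals, expected):
        mean, flagged = triplicate_mean(vals)
        assert mean == expected and not flagged

    def test_out_of_range_flagged_but_averaged(self):
        mean, flagged = triplicate_mean([1.0, 10.0, 10.0])  # below assay range
        assert flagged and mean == pytest.approx(7.0)

    def test_fewer_than_three_flagged(self):
        mean, flagged = triplicate_mean([10.0, 12.0])
        assert flagged and mean == 11.0

    def test_vector_of_sets_matches_elementwise_oracle(self):
        rng = np.random.default_rng(0)
        sets = rng.lognormal(3, 0.4, (34, 3))
        means = [triplicate_mean(s)[0] for s in sets]
        assert np.allclose(means, sets.mean(axis=1))


class TestMatchControls:
    def _meta(self, rows):
        return pd.DataFrame(rows).T.astype(int)

    def test_exact_match_forms_pair(self):
        meta = self._meta({"c": {"sex": 1, "birth_year": 1950, "sample_year": 2016},
                           "x": {"sex": 1, "birth_year": 1950, "sample_year": 2016}})
        out = match_controls(["c"], ["x"], meta)
        assert len(out) == 1 and out.pairs[0].control == "x"

    def test_sample_year_window_enforced(self):
        meta = self._meta({"c": {"sex": 1, "birth_year": 1950, "sample_year": 2016},
                           "x": {"sex": 1, "birth_year": 1950, "sample_year": 2018}})
        out = match_controls(["c"], ["x"], meta)
        assert len(out) == 0 and out.unmatched == ["c"]

    def test_sex_must_match(self):
        meta = self._meta({"c": {"sex": 1, "birth_year": 1950, "sample_year": 2016},
                           "x": {"sex": 2, "birth_year": 1950, "sample_year": 2016}})
        out = match_controls(["c"], ["x"], meta)
        assert out.unmatched == ["c"]

    def test_invariants_and_determinism_on_random_pool(self):
        rng = np.random.default_rng(1)
        carriers = [f"car{k:02d}" for k in range(34)]
        pool = [f"ctl{k:03d}" for k in range(500)]
        rows = {}
        for iid in carriers + pool:
            rows[iid] = {"sex": int(rng.integers(1, 3)),
                         "birth_year": int(rng.integers(1930, 1990)),
                         "sample_year": int(rng.integers(2014, 2018))}
        meta = self._meta(rows)
        out1 = match_controls(carriers, pool, meta)
        out2 = match_controls(carriers, pool, meta)
        assert out1.to_frame().equals(out2.to_frame())
        used = [p.control for p in out1.pairs]
        assert len(used) == len(set(used))  # no control reused
        for p in out1.pairs:
            assert meta.loc[p.carrier, "sex"] == meta.loc[p.control, "sex"]
            assert p.sample_year_diff <= 1
        assert len(out1.pairs) + len(out1.unmatched) == len(carriers)

    def test_minimal_birth_year_distance_chosen(self):
        meta = self._meta({
            "c": {"sex": 1, "birth_year": 1950, "sample_year": 2016},
            "far": {"sex": 1, "birth_year": 1970, "sample_year": 2016},
            "near": {"sex": 1, "birth_year": 1952, "sample_year": 2016},
        })
        out = match_controls(["c"], ["far", "near"], meta)
        assert out.pairs[0].control == "near"

    def test_overlapping_pools_rejected(self):
        meta = self._meta({"a": {"sex": 1, "birth_year": 1950, "sample_year": 2016}})
        with pytest.raises(ValueError):
            match_controls(["a"], ["a"], meta)


def exact_wilcoxon_by_enumeration(d):
    """Full 2^n sign enumeration oracle for the two-sided exact p."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws)
    lower = (ws <= w_obs + 1e-9).mean()
    upper = (ws >= w_obs - 1e-9).mean()
    return min(1.0, 2 * min(lower, upper))


class TestWilcoxon:
    def test_all_positive_n5(self):
        assert wilcoxon_signed_rank(np.arange(1.0, 6.0)) == pytest.approx(0.0625)

    @pytest.mark.parametrize("n", range(3, 13))
    def test_exact_path_equals_full_enumeration(self, n):
        rng = np.random.default_rng(n)
        d = np.round(rng.normal(0.3, 1.0, n), 1)  # rounding induces ties
        d = np.where(d == 0, 0.1, d)
        assert wilcoxon_signed_rank(d) == pytest.approx(
            exact_wilcoxon_by_enumeration(d), abs=1e-12)

    def test_agrees_with_scipy_exact_when_no_ties(self):
        rng = np.random.default_rng(99)
        d = rng.normal(0.5, 1.0, 15)
        assert wilcoxon_signed_rank(d) == pytest.approx(
            stats.wilcoxon(d, method="exact").pvalue, abs=1e-12)

    def test_normal_approximation_floor_at_n34(self):
        """34 concordant pairs with distinct differences: the
        approximate two-sided p with continuity correction is ~3.8e-7,
        the achievable minimum."""
        p = wilcoxon_signed_rank(np.arange(1.0, 35.0), exact_limit=25)
        assert p == pytest.approx(3.8e-7, rel=0.05)

    def test_approximation_close_to_exact_at_n20(self):
        rng = np.random.default_rng(2)
        rel_errs = []
        for _ in range(100):
            d = rng.normal(0.4, 1.0, 20)
            exact = wilcoxon_signed_rank(d, exact_limit=25)
            approx = wilcoxon_signed_rank(d, exact_limit=0)
            rel_errs.append(abs(approx - exact) / exact)
        assert np.median(rel_errs) < 0.10

    def test_zero_differences_dropped(self):
        d = np.array([0.0, 0.0, 1.0, 2.0, -0.5])
        assert wilcoxon_signed_rank(d) == pytest.approx(
            wilcoxon_signed_rank(np.array([1.0, 2.0, -0.5])))

    def test_all_zero_returns_one(self):
        assert wilcoxon_signed_rank(np.zeros(5)) == 1.0


class TestPairedLogT:
    def test_identical_pairs_give_p_one(self):
        ps = _pair_set([10, 12, 9], [10, 12, 9])
        assert paired_log_t(ps) == 1.0

    def test_constant_nonzero_shift_flagged_below_resolution(self):
        ps = _pair_set([20, 40, 10], [10, 20, 5])  # log-diff constant
        assert paired_log_t(ps) == pytest.approx(0.0, abs=1e-300)

    def test_matches_closed_form_t(self):
        rng = np.random.default_rng(3)
        cv = rng.lognormal(3, 0.4, 30)
        tv = rng.lognormal(2.5, 0.4, 30)
        ps = _pair_set(cv, tv)
        d = np.log(cv) - np.log(tv)
        t = d.mean() / (d.std(ddof=1) / np.sqrt(30))
        expected = 2 * stats.t.sf(abs(t), df=29)
        assert paired_log_t(ps) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            paired_log_t(_pair_set([10, -1], [5, 5]))


class TestFoldSummary:
    def test_uniform_doubling(self):
        rep = fold_summary(_pair_set([20] * 4, [10] * 4))
        assert rep.ratio_of_medians == 2.0
        assert rep.median_of_ratios == 2.0

    def test_conventions_differ_in_general(self):
        rep = fold_summary(_pair_set([10, 30, 8], [5, 10, 8]))
        assert rep.ratio_of_medians == pytest.approx(10 / 8)
        assert rep.median_of_ratios == pytest.approx(2.0)

    def test_equal_groups_give_unity(self):
        rep = fold_summary(_pair_set([7, 9, 11], [7, 9, 11]))
        assert rep.ratio_of_medians == 1.0
        assert rep.median_of_ratios == 1.0


class TestFisherCombine:
    def test_two_ones_stay_one(self):
        assert fisher_combine([1.0, 1.0]).combined_p == pytest.approx(1.0)

    def test_single_p_identity(self):
        for p in (0.3, 1e-5, 0.9):
            assert fisher_combine([p]).combined_p == pytest.approx(p, rel=1e-12)

    def test_statistic_and_df(self):
        res = fisher_combine([0.1, 0.2, 0.3])
        assert res.statistic == pytest.approx(-2 * sum(np.log([0.1, 0.2, 0.3])))
        assert res.df == 6

    def test_matches_scipy(self):
        ps = [0.03, 0.4, 0.007]
        expected = stats.combine_pvalues(ps, method="fisher").pvalue
        assert fisher_combine(ps).combined_p == pytest.approx(expected, rel=1e-12)

    def test_monotone_and_exchangeable(self):
        base = fisher_combine([0.01, 0.2]).combined_p
        assert fisher_combine([0.2, 0.01]).combined_p == pytest.approx(base)
        assert fisher_combine([0.005, 0.2]).combined_p < base

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine([0.0, 0.5])
        with pytest.raises(ValueError):
            fisher_combine([1.5])


class TestPower:
    def test_half_power_drops_power_quantile(self):
        n, maf, alpha = 10_000, 0.01, 0.05
        mde = min_detectable_effect(n, maf, alpha, power=0.5)
        v = n * 2 * maf * (1 - maf)
        assert mde == pytest.approx(stats.norm.ppf(0.975) / np.sqrt(v), rel=1e-12)

    def test_round_trip_inverse(self):
        for n, maf, alpha, power in [(273_160, 0.0009, 0.05, 0.8),
                                     (5000, 0.01, 0.01, 0.9)]:
            eff = min_detectable_effect(n, maf, alpha, power)
            assert power_at(n, maf, eff, alpha) == pytest.approx(power, abs=1e-10)

    def test_null_effect_gives_half_alpha(self):
        assert power_at(1000, 0.1, 0.0, 0.05) == pytest.approx(0.025)

    def test_monotone_in_effect_n_and_maf(self):
        effects = np.linspace(0, 2, 20)
        pw = [power_at(2000, 0.05, e, 0.05) for e in effects]
        assert all(a <= b for a, b in zip(pw, pw[1:]))
        assert power_at(4000, 0.05, 0.3) > power_at(2000, 0.05, 0.3)
        assert power_at(2000, 0.10, 0.3) > power_at(2000, 0.05, 0.3)
        assert pw[-1] > 0.999

    def test_simulation_matches_analytic_power(self):
        """Empirical rejection rate of the per-variant test matches the
        analytic approximation within binomial error."""
        rng = np.random.default_rng(4)
        n, maf, effect, alpha = 5000, 0.01, 0.3, 0.05
        reps = 2000
        G = rng.binomial(2, maf, size=(reps, n)).astype(float)
        Y = effect * G + rng.standard_normal((reps, n))
        Gc = G - G.mean(axis=1, keepdims=True)
        Yc = Y - Y.mean(axis=1, keepdims=True)
        sxx = (Gc**2).sum(axis=1)
        beta = (Gc * Yc).sum(axis=1) / sxx
        resid = Yc - beta[:, None] * Gc
        s2 = (resid**2).sum(axis=1) / (n - 2)
        z = beta / np.sqrt(s2 / sxx)
        emp = (2 * stats.norm.sf(np.abs(z)) < alpha).mean()
        analytic = power_at(n, maf, effect, alpha)
        se = np.sqrt(analytic * (1 - analytic) / reps)
        assert abs(emp - analytic) < 3 * se

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ConfigurationError):
            min_detectable_effect(1000, 0.1, alpha=0.05, power=0.01)
        with pytest.raises(ConfigurationError):
            power_at(0, 0.1, 0.3)


class TestSyntheticReplicationSucceeds:
    def test_planted_effect_yields_small_wilcoxon_p(self):
        """34 matched pairs at a 1.47 SD latent effect: the Wilcoxon p
        is small in the typical replication (qualitative success)."""
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(200):
            carrier_latent = 1.47 + rng.standard_normal(34)
            control_latent = rng.standard_normal(34)
            cv = np.exp(0.5 * carrier_latent + np.log(13.3))
            tv = np.exp(0.5 * control_latent + np.log(13.3))
            ps.append(wilcoxon_signed_rank(cv - tv, exact_limit=25))
        assert np.median(ps) < 1e-3
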
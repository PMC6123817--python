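"""Synthetic pedigree/genotype/phenotype generator properties."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pedigwas.errors import ConfigurationError
from pedigwas.pedigree import Pedigree, Individual, kinship_matrix
from pedigwas.simulate import (
    ANNOTATION_CLASSES,
    ANNOTATION_PROPORTIONS,
    SimConfig,
    assign_typing_status,
    gene_drop,
    simulate_pedigree,
    simulate_trait,
    simulate_variant_panel,
)
from pedigwas.pedigree import relationship_degree


class TestSimConfig:
    @pytest.mark.parametrize("kw", [
        {"n_founders": 1},
        {"n_generations": 0},
        {"mean_offspring": 0.0},
        {"rare_maf": 0.0},
        {"rare_maf": 0.6},
        {"chip_typed_fraction": 1.2},
        {"n_common_variants": 5, "ld_block_size": 10},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            SimConfig(**kw)


class TestSimulatePedigree:
    def test_two_founders_one_generation(self):
        cfg = SimConfig(n_founders=2, n_generations=1, mean_offspring=2.0, seed=0)
        # force one male + one female by trying seeds until pairing happens
        for seed in range(20):
            ped = simulate_pedigree(SimConfig(n_founders=2, n_generations=1,
                                              mean_offspring=2.0, seed=seed))
            kids = [i for i in ped.topological_order if ped.parents(i)]
            if kids:
                break
        assert kids, "no seed produced children from a single founder pair"
        parents = {ped.parents(k) for k in kids}
        assert len(parents) == 1  # all children share the same two parents

    def test_structure_invariants(self, small_cohort):
        _, ped = small_cohort
        for iid in ped.topological_order:
            par = ped.parents(iid)
            if par is None:
                continue
            assert par[0] in ped and par[1] in ped
            child_year = ped.member(iid).birth_year
            for p in par:
                assert ped.member(p).birth_year < child_year

    def test_determinism(self):
        cfg = SimConfig(n_founders=50, seed=7)
        p1 = simulate_pedigree(cfg).to_dataframe()
        p2 = simulate_pedigree(cfg).to_dataframe()
        pd.testing.assert_frame_equal(p1, p2)

    def test_mean_offspring_matches_poisson_target(self):
        """Observed mean offspring per mating within 3 SE of the target
        over 20 seeds (Monte-Carlo check of the sampling law)."""
        target = 2.5
        counts = []
        for seed in range(20):
            cfg = SimConfig(n_founders=200, n_generations=3,
                            mean_offspring=target, seed=seed)
            ped = simulate_pedigree(cfg)
            per_couple = {}
            for iid in ped.topological_order:
                par = ped.parents(iid)
                if par:
                    per_couple[par] = per_couple.get(par, 0) + 1
            counts.extend(per_couple.values())
        counts = np.asarray(counts, dtype=float)
        # offspring counts are truncated-at-max Poisson conditioned > 0
        # (childless couples leave no trace); compare to that law
        lam, cap = target, SimConfig().max_offspring
        k = np.arange(1, cap + 1)
        pmf = stats.poisson.pmf(k, lam)
        pmf[-1] += stats.poisson.sf(cap, lam)
        pmf /= pmf.sum()
        expected_mean = (k * pmf).sum()
        se = counts.std() / np.sqrt(len(counts))
        assert abs(counts.mean() - expected_mean) < 3 * se

    def test_no_consanguineous_matings(self, small_cohort):
        _, ped = small_cohort
        kin = kinship_matrix(ped)
        couples = {ped.parents(i) for i in ped.topological_order if ped.parents(i)}
        for f, m in couples:
            assert kin.value(f, m) == 0.0


class TestGeneDrop:
    def test_zero_maf_gives_all_zero(self, small_cohort):
        _, ped = small_cohort
        g = gene_drop(ped, 0.0, seed=1)["drop0"]
        assert (g == 0).all()

    def test_homozygous_parents_force_child(self):
        ped = Pedigree([
            Individual("f", None, None, 1, 1900),
            Individual("m", None, None, 2, 1900),
            Individual("c", "f", "m", 1, 1930),
        ])
        for seed in range(10):
            g = gene_drop(ped, 0.5, seed=seed)["drop0"]
            if g.loc["f"] == 2 and g.loc["m"] == 2:
                assert g.loc["c"] == 2

    def test_founder_frequency_within_binomial_interval(self):
        """Founder allele frequency at tiny maf stays inside the
        99% binomial interval (sampling-bound oracle)."""
        maf = 0.0009
        ped = Pedigree([Individual(f"f{i}", None, None, 1, 1900)
                        for i in range(10_000)])
        g = gene_drop(ped, maf, seed=3)["drop0"]
        count = int(g.sum())
        lo, hi = stats.binom.interval(0.99, 2 * 10_000, maf)
        assert lo <= count <= hi

    def test_mendelian_consistency_all_trios(self, small_cohort):
        _, ped = small_cohort
        drops = gene_drop(ped, 0.3, seed=9, n_drops=5)
        for col in drops.columns:
            g = drops[col]
            for iid in ped.topological_order:
                par = ped.parents(iid)
                if not par:
                    continue
                gf, gm, gc = g.loc[par[0]], g.loc[par[1]], g.loc[iid]
                assert gc >= (gf // 2) + (gm // 2)
                assert gc <= (1 if gf > 0 else 0) + (1 if gm > 0 else 0)

    def test_determinism(self, small_cohort):
        _, ped = small_cohort
        a = gene_drop(ped, 0.1, seed=4)
        b = gene_drop(ped, 0.1, seed=4)
        pd.testing.assert_frame_equal(a, b)


class TestSimulateTrait:
    def _latent(self, meas, cfg):
        """Invert the raw-scale link (valid when repeat noise is off)."""
        return np.log(meas["value"] / cfg.raw_median) / cfg.raw_scale

    def test_null_latent_is_standard_normal(self):
        cfg = SimConfig(n_founders=2500, n_generations=1, seed=5,
                        sex_effect=0.0, birth_year_effect=0.0,
                        polygenic_var=0.0, repeat_prob=0.0, repeat_noise_sd=0.0)
        ped = simulate_pedigree(cfg)
        g = pd.Series(0, index=pd.Index(ped.topological_order))
        meas = simulate_trait(ped, g, 0.0, cfg)
        latent = self._latent(meas, cfg)
        assert len(latent) >= 2500
        assert stats.kstest(latent, "norm").pvalue > 0.01

    def test_carrier_shift_recovers_effect(self, small_cohort):
        """Mean latent difference between carriers and non-carriers
        approaches the planted effect (direct group-means oracle)."""
        cfg0, ped = small_cohort
        cfg = SimConfig(n_founders=100, seed=42, repeat_prob=0.0,
                        repeat_noise_sd=0.0, sex_effect=0.0,
                        birth_year_effect=0.0)
        diffs = []
        for seed in range(60):
            g = gene_drop(ped, 0.05, seed=seed)["drop0"]
            if g.nunique() < 2:
                continue
            meas = simulate_trait(ped, g, 1.47, cfg, seed=seed)
            latent = self._latent(meas, cfg).to_numpy()
            gv = g.loc[meas["iid"]].to_numpy()
            carriers = latent[gv == 1]
            if carriers.size == 0:
                continue
            diffs.append(carriers.mean() - latent[gv == 0].mean())
        diffs = np.asarray(diffs)
        se = diffs.std() / np.sqrt(len(diffs))
        assert abs(diffs.mean() - 1.47) < 3 * se

    def test_positive_values_and_repeat_counts(self, small_cohort):
        cfg, ped = small_cohort
        g = gene_drop(ped, 0.1, seed=2)["drop0"]
        meas = simulate_trait(ped, g, 0.5, cfg)
        assert (meas["value"] > 0).all()
        per = meas.groupby("iid").size()
        assert set(per.unique()) <= {1, 2}
        assert abs(per.mean() - 1.4) < 0.1

    def test_determinism(self, small_cohort):
        cfg, ped = small_cohort
        g = gene_drop(ped, 0.1, seed=2)["drop0"]
        a = simulate_trait(ped, g, 0.5, cfg)
        b = simulate_trait(ped, g, 0.5, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_median_near_reference_scale(self, small_cohort):
        cfg, ped = small_cohort
        g = pd.Series(0, index=pd.Index(ped.topological_order))
        meas = simulate_trait(ped, g, 0.0, cfg)
        assert 9 < meas["value"].median() < 19  # ~13.3 IU/L up to covariates


class TestVariantPanel:
    def test_block_size_one_gives_independence(self):
        cfg = SimConfig(n_founders=1000, n_generations=1, seed=8,
                        n_common_variants=60, ld_block_size=1)
        ped = simulate_pedigree(cfg)
        panel, _ = simulate_variant_panel(cfg, ped)
        X = panel.to_numpy(dtype=float)
        r = np.corrcoef(X.T)
        off = r[np.triu_indices_from(r, 1)]
        assert np.nanmean(off**2) < 0.02

    def test_within_block_ld_exceeds_cross_block(self, small_cohort):
        cfg = SimConfig(n_founders=100, seed=42, n_common_variants=100,
                        ld_block_size=10, ld_copy_prob=0.9)
        _, ped = small_cohort
        panel, variants = simulate_variant_panel(cfg, ped)
        X = panel.to_numpy(dtype=float)
        r2 = np.corrcoef(X.T) ** 2
        blocks = variants["block"].to_numpy()
        same = blocks[:, None] == blocks[None, :]
        mask = ~np.eye(len(blocks), dtype=bool)
        within = np.nanmean(r2[same & mask])
        cross = np.nanmean(r2[~same])
        assert within > cross

    def test_adjacent_pairs_correlated(self, small_cohort):
        cfg = SimConfig(n_founders=100, seed=42, n_common_variants=100,
                        ld_block_size=10, ld_copy_prob=0.9)
        _, ped = small_cohort
        panel, variants = simulate_variant_panel(cfg, ped)
        X = panel.to_numpy(dtype=float)
        blocks = variants["block"].to_numpy()
        adj = []
        for j in range(X.shape[1] - 1):
            if blocks[j] == blocks[j + 1]:
                adj.append(np.corrcoef(X[:, j], X[:, j + 1])[0, 1] ** 2)
        assert np.mean(adj) > 0.3  # copy probability 0.9 implies strong adjacent LD

    def test_annotation_proportions_within_multinomial_bounds(self):
        cfg = SimConfig(n_founders=40, n_generations=1, seed=3,
                        n_common_variants=20_000, ld_block_size=1)
        ped = simulate_pedigree(cfg)
        _, variants = simulate_variant_panel(cfg, ped)
        counts = variants["annotation"].value_counts()
        m = len(variants)
        for cls, p in zip(ANNOTATION_CLASSES, ANNOTATION_PROPORTIONS):
            lo, hi = stats.binom.interval(0.99, m, p)
            assert lo <= counts.get(cls, 0) <= hi


class TestTypingStatus:
    def test_all_typed(self, small_cohort):
        _, ped = small_cohort
        typed, inferable = assign_typing_status(ped, 1.0, seed=1)
        assert typed.all() and inferable == []

    def test_none_typed(self, small_cohort):
        _, ped = small_cohort
        typed, inferable = assign_typing_status(ped, 0.0, seed=1)
        assert (~typed).all() and inferable == []

    def test_inferable_set_verified_by_degree_search(self, small_cohort):
        """Every reported individual has a typed relative of degree <= 2,
        and no excluded untyped individual does (brute-force check)."""
        _, ped = small_cohort
        typed, inferable = assign_typing_status(ped, 0.7, seed=1)
        typed_ids = [i for i in typed.index if typed.loc[i]]
        inferable_set = set(inferable)
        ids = ped.topological_order[:120]  # cap the O(n^2) brute force
        for iid in ids:
            if typed.loc[iid]:
                continue
            has_close = any(
                relationship_degree(ped, iid, t) in ("1st", "2nd")
                for t in typed_ids
            )
            assert has_close == (iid in inferable_set)
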
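"""Breeding-program simulator: pedigree, gene dropping, phenotypes,
selective genotyping."""

import numpy as np
import pandas as pd
import pytest

from gxeblup.params import GENETIC_TRAITS, default_true_params, rtype_index
from gxeblup.pedigree import Pedigree
from gxeblup.synthetic_data import (
    SimConfig,
    apply_selective_genotyping,
    default_missingness_plan,
    simulate_dataset,
    simulate_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
)


class TestPedigreeSimulation:
    def test_minimal_program(self):
        cfg = SimConfig(
            n_time_steps=1, n_sires_per_ts=2, n_dams_per_ts=2,
            offspring_per_dam=2, prop_to_C=0.0, n_founder_males=2,
            n_founder_females=2,
            missingness_plan={1: {"B": {6: 1.0}}},
        )
        ped = simulate_pedigree(cfg, rng_seed=0)
        assert ped.n == 8  # 4 founders + 4 offspring
        off = np.flatnonzero(ped.time_step == 1)
        assert len(off) == 4
        founders = set(ped.founders())
        assert set(ped.sire[off]) <= founders
        assert set(ped.dam[off]) <= founders

    def test_same_seed_identical(self):
        cfg = SimConfig(n_time_steps=3, n_dams_per_ts=4, offspring_per_dam=6, seed=9)
        p1 = simulate_pedigree(cfg, rng_seed=9)
        p2 = simulate_pedigree(cfg, rng_seed=9)
        assert p1.to_frame().equals(p2.to_frame())

    def test_family_split_uses_floor_rule(self):
        cfg = SimConfig(n_time_steps=2, n_sires_per_ts=2, n_dams_per_ts=4,
                        offspring_per_dam=10, prop_to_C=0.3)
        ped = simulate_pedigree(cfg, rng_seed=3)
        df = ped.to_frame()
        fam = df[df.time_step > 0].groupby(["sire", "dam", "time_step"])
        for _, members in fam:
            assert (members.environment == "C").sum() == 3  # floor(0.3 * 10)

    def test_sexes_balanced_within_family(self):
        cfg = SimConfig(n_time_steps=1, offspring_per_dam=8)
        ped = simulate_pedigree(cfg, rng_seed=4)
        df = ped.to_frame()
        for _, members in df[df.time_step == 1].groupby(["sire", "dam"]):
            assert (members.sex == "M").sum() == 4

    def test_impossible_split_raises(self):
        cfg = SimConfig(n_time_steps=1, offspring_per_dam=2, prop_to_C=0.3)
        # floor(0.3 * 2) = 0 members in C although C records are required
        cfg.missingness_plan = {1: {"B": {6: 1.0}, "C": {5: 1.0}}}
        with pytest.raises(ValueError, match="without members in C"):
            simulate_pedigree(cfg, rng_seed=0)


class TestGeneDropping:
    def test_fixed_parents_give_fixed_offspring(self):
        cfg = SimConfig(n_time_steps=2, n_dams_per_ts=4, offspring_per_dam=6,
                        n_snps=60, maf_range=(0.5, 0.5))
        ped = simulate_pedigree(cfg, rng_seed=5)
        geno = simulate_genotypes(ped, cfg, rng_seed=5)
        M = geno.dosages
        for i in np.flatnonzero(ped.sire >= 0):
            s, d = ped.sire[i], ped.dam[i]
            both2 = (M[s] == 2) & (M[d] == 2)
            both0 = (M[s] == 0) & (M[d] == 0)
            assert np.all(M[i][both2] == 2)
            assert np.all(M[i][both0] == 0)

    def test_founder_allele_frequency(self):
        ped = Pedigree(
            ids=np.arange(1, 10001), sire=np.full(10000, -1),
            dam=np.full(10000, -1), sex=["M"] * 10000,
            time_step=np.zeros(10000),
        )
        cfg = SimConfig(n_snps=4, maf_range=(0.5, 0.5))
        geno = simulate_genotypes(ped, cfg, rng_seed=6)
        freq = geno.dosages.mean(axis=0) / 2.0
        # binomial SE sqrt(p q / 2n) ~ 0.0035; 0.02 is > 5 SE
        assert np.abs(freq - 0.5).max() < 0.02

    def test_deterministic(self):
        cfg = SimConfig(n_time_steps=2, n_snps=30)
        ped = simulate_pedigree(cfg, rng_seed=7)
        g1 = simulate_genotypes(ped, cfg, rng_seed=7)
        g2 = simulate_genotypes(ped, cfg, rng_seed=7)
        assert np.array_equal(g1.dosages, g2.dosages)


class TestPhenotypes:
    def test_zero_variance_zero_fixed_gives_zero_phenotypes(self):
        cfg = SimConfig(n_time_steps=2, n_dams_per_ts=4, offspring_per_dam=6,
                        n_snps=20)
        tp = default_true_params()
        zero = default_true_params()
        zero.va0 = np.zeros_like(tp.va0)
        zero.vc0 = np.zeros_like(tp.vc0)
        zero.ve0 = np.zeros_like(tp.ve0)
        zero.mean_g = {k: 0.0 for k in tp.mean_g}
        zero.fixed_effect_sizes = {k: 0.0 for k in tp.fixed_effect_sizes}
        ped = simulate_pedigree(cfg, rng_seed=8)
        geno = simulate_genotypes(ped, cfg, rng_seed=8)
        ds = simulate_phenotypes(ped, geno, zero, cfg, rng_seed=8)
        assert np.allclose(ds.phenotypes["value_g"], 0.0)

    def test_structural_zero_violation_raises(self):
        cfg = SimConfig(n_time_steps=1, prop_to_C=0.0,
                        missingness_plan={1: {"B": {5: 1.0}}})
        tp = default_true_params()
        bad = default_true_params()
        # couple male and female BW5.B residuals
        bad.ve0 = tp.ve0.copy()
        bad.ve0[0, 1] = bad.ve0[1, 0] = 0.1
        ped = simulate_pedigree(cfg, rng_seed=9)
        geno = simulate_genotypes(ped, cfg, rng_seed=9)
        with pytest.raises(ValueError, match="structural-zero"):
            simulate_phenotypes(ped, geno, bad, cfg, rng_seed=9)

    def test_true_bv_correlation_matches_target(self):
        """Base-population BV correlation ~0.5 across environments (large
        founder cohort, Fisher-z style bound)."""
        cfg = SimConfig(
            n_time_steps=1, n_founder_males=2500, n_founder_females=2500,
            n_sires_per_ts=2, n_dams_per_ts=2, offspring_per_dam=2, n_snps=800,
            prop_to_C=0.0, missingness_plan={1: {"B": {5: 1.0}}},
        )
        tp = default_true_params(rg_bc=0.5)
        ped = simulate_pedigree(cfg, rng_seed=10)
        geno = simulate_genotypes(ped, cfg, rng_seed=10)
        ds = simulate_phenotypes(ped, geno, tp, cfg, rng_seed=10)
        u = ds.true_bv[ped.founders()]
        corr = np.corrcoef(u[:, 0], u[:, 2])[0, 1]
        assert abs(corr - 0.5) < 0.04

    def test_true_bv_covariance_converges(self):
        cfg = SimConfig(
            n_time_steps=1, n_founder_males=2500, n_founder_females=2500,
            n_sires_per_ts=2, n_dams_per_ts=2, offspring_per_dam=2, n_snps=800,
            prop_to_C=0.0, missingness_plan={1: {"B": {5: 1.0}}},
        )
        tp = default_true_params()
        ped = simulate_pedigree(cfg, rng_seed=11)
        geno = simulate_genotypes(ped, cfg, rng_seed=11)
        ds = simulate_phenotypes(ped, geno, tp, cfg, rng_seed=11)
        u = ds.true_bv[ped.founders()]
        S = np.cov(u, rowvar=False)
        n = len(u)
        for a in range(4):
            for b in range(4):
                se = np.sqrt(
                    (tp.va0[a, a] * tp.va0[b, b] + tp.va0[a, b] ** 2) / n
                )
                assert abs(S[a, b] - tp.va0[a, b]) < 3 * se + 1e-9

    def test_record_means_and_sds_match_parameters(self):
        cfg = SimConfig(seed=12, n_time_steps=12, n_dams_per_ts=12,
                        random_mating=True)
        tp = default_true_params()
        ds = simulate_dataset(cfg, tp, 12)
        ph = ds.phenotypes
        fixed_var = (
            tp.fixed_effect_sizes["hatch_ts"] ** 2
            + 2 * tp.fixed_effect_sizes["parent_ts"] ** 2
            + tp.fixed_effect_sizes["dam_age"] ** 2
        )
        for (sex, trait, env), cell in ph.groupby(["sex", "trait", "env"]):
            week = int(trait[2])
            if len(cell) < 300:
                continue
            sd_expect = tp.sex_sd[(sex, week, env)] * np.sqrt(1.0 + fixed_var)
            mean_expect = tp.mean_g[(sex, week, env)]
            n = len(cell)
            assert abs(cell["value_g"].mean() - mean_expect) < 4 * sd_expect / np.sqrt(n) + 0.15 * sd_expect
            assert abs(cell["value_g"].std() - sd_expect) < 0.2 * sd_expect


class TestSelectiveGenotyping:
    def test_full_and_zero_proportions(self, small_dataset):
        cfg, ds = small_dataset
        import dataclasses

        all_cfg = dataclasses.replace(cfg, prop_genotyped_B=1.0)
        flagged = apply_selective_genotyping(ds, all_cfg)
        assert flagged.genotyped[ds.environment == "B"].all()

        none_cfg = dataclasses.replace(cfg, prop_genotyped_B=0.0)
        flagged = apply_selective_genotyping(ds, none_cfg)
        ped = ds.pedigree
        parents = np.union1d(ped.sire[ped.sire >= 0], ped.dam[ped.dam >= 0])
        expected = np.zeros(ped.n, bool)
        expected[ds.environment == "C"] = True
        expected[parents] = True
        assert np.array_equal(flagged.genotyped, expected)

    def test_top_fraction_selected_exactly(self, small_dataset):
        cfg, ds = small_dataset
        ped = ds.pedigree
        ph = ds.phenotypes
        plan = cfg.plan()
        for ts in np.unique(ped.time_step[ped.time_step > 0]):
            cell = plan.get(int(ts), {}).get("B", {})
            week = 5 if cell.get(5, 0) >= 1 else 6
            sub = ph[(ph.env == "B") & (ph.hatch_ts == ts) & (ph.trait == f"BW{week}")]
            scores = dict(zip(sub["animal"], sub["value_g"]))
            for sex in ("M", "F"):
                grp = np.flatnonzero(
                    (ds.environment == "B") & (ped.time_step == ts) & (ped.sex == sex)
                )
                k = int(np.floor(cfg.prop_genotyped_B * len(grp)))
                vals = np.array([scores[int(ped.ids[i])] for i in grp])
                order = np.lexsort((ped.ids[grp], -vals))
                top = set(ped.ids[grp[order[:k]]])
                parents = set(ped.ids[np.union1d(ped.sire[ped.sire >= 0], ped.dam[ped.dam >= 0])])
                flagged = set(ped.ids[grp][ds.genotyped[grp]])
                assert top <= flagged
                assert flagged - top <= parents

    def test_genotyped_b_birds_are_heavier(self, small_dataset):
        _, ds = small_dataset
        ph = ds.phenotypes
        b5 = ph[(ph.env == "B") & (ph.trait == "BW5")]
        flags = dict(zip(ds.pedigree.ids, ds.genotyped))
        is_geno = b5["animal"].map(flags).to_numpy(bool)
        assert b5.loc[is_geno, "value_g"].mean() > b5.loc[~is_geno, "value_g"].mean()


class TestDatasetContract:
    def test_same_seed_identical_dataset(self):
        cfg = SimConfig(seed=13, n_time_steps=4, n_dams_per_ts=6, offspring_per_dam=6)
        tp = default_true_params()
        d1 = simulate_dataset(cfg, tp, 13)
        d2 = simulate_dataset(cfg, tp, 13)
        assert d1.phenotypes.equals(d2.phenotypes)
        assert np.array_equal(d1.genotypes.dosages, d2.genotypes.dosages)
        assert np.array_equal(d1.true_bv, d2.true_bv)
        assert np.array_equal(d1.genotyped, d2.genotyped)

    def test_parents_always_genotyped(self, small_dataset):
        _, ds = small_dataset
        ped = ds.pedigree
        parents = np.union1d(ped.sire[ped.sire >= 0], ped.dam[ped.dam >= 0])
        assert ds.genotyped[parents].all()

    def test_phenotyped_animals_in_pedigree(self, small_dataset):
        _, ds = small_dataset
        assert set(ds.phenotypes["animal"]) <= set(ds.pedigree.ids.tolist())

    def test_default_plan_mirrors_study_windows(self):
        plan = default_missingness_plan(16)
        assert plan[5]["B"] == {6: 1.0}           # early B: week 6 only
        assert plan[12]["B"][5] == 1.0            # late B: week 5 on everyone
        assert 0 < plan[12]["B"][6] < 1           # week 6 on a subset
        assert plan[8]["C"] == {5: 1.0, 6: 1.0}   # mid C: both weeks
        assert plan[14]["C"] == {5: 1.0}          # late C: week 5 only
        assert "C" not in plan[2]                 # C testing starts later
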
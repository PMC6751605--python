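"""Design construction, MME assembly and the PBLUP/ssGBLUP solvers."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from gxeblup.mixed_model import (
    ModelSpec,
    RecordType,
    assemble_mme,
    build_design,
    model1_spec,
    model2_spec,
    predict_ebv,
    solve_direct,
    solve_pcg,
)
from gxeblup.params import default_true_params
from gxeblup.pedigree import Pedigree
from gxeblup.relationships import build_A_inverse, make_h_inverse_parts


def _univariate_spec(use_maternal=False):
    return ModelSpec(
        traits=("BW5.B",),
        rtypes=(RecordType("M", 5, "B"),),
        rtype_trait_idx=(0,),
        residual_groups=((0,),),
        use_maternal=use_maternal,
        value_column="value_g",
    )


def _records(animals, values, **extra):
    base = dict(trait="BW5", env="B", sex="M", hatch_ts=1, sire_ts=0,
                dam_ts=0, dam_id=0, dam_age_wk=0)
    base.update(extra)
    return pd.DataFrame([{"animal": a, "value_g": v, **base}
                         for a, v in zip(animals, values)])


class TestDesign:
    def test_toy_table_dimensions_match_hand_count(self, small_standardized, small_dataset):
        _, ds = small_dataset
        spec = model2_spec()
        design = build_design(small_standardized, spec, ds.pedigree)
        assert design.n_records == len(small_standardized)
        # genetic block: 4 traits x every pedigree animal; maternal: 4 x dams
        assert design.n_equations() == (
            4 * ds.pedigree.n + 4 * design.n_dams + design.n_fixed
        )

    def test_sexes_share_genetic_trait_but_not_columns(self, small_standardized, small_dataset):
        from gxeblup.mixed_model import CompiledModel

        _, ds = small_dataset
        design = build_design(small_standardized, model2_spec(), ds.pedigree)
        c = CompiledModel(design)
        tr = np.array(design.spec.rtype_trait_idx)
        # a male and a female record of the same trait point at the same
        # genetic trait index but different animals' columns
        males = np.flatnonzero(design.rec_rtype == 0)
        females = np.flatnonzero(design.rec_rtype == 1)
        assert tr[0] == tr[1] == 0
        assert set(c.rec_gcol[males]).isdisjoint(c.rec_gcol[females])

    def test_week_pair_shares_residual_block(self, small_standardized, small_dataset):
        from gxeblup.mixed_model import CompiledModel

        _, ds = small_dataset
        design = build_design(small_standardized, model2_spec(), ds.pedigree)
        c = CompiledModel(design)
        # any animal with week-5 and week-6 records sits in a 2-type pattern
        pats = [p for p in c.patterns if len(p) == 2]
        assert pats
        for pat in pats:
            assert pat[0] // 2 != pat[1] // 2  # different traits (weeks)
            assert pat[0] % 2 == pat[1] % 2    # same sex

    def test_unknown_animal_raises(self, founder_pair):
        rec = _records([99], [5.0])
        with pytest.raises(KeyError):
            build_design(rec, _univariate_spec(), founder_pair)


class TestHendersonSystem:
    def test_single_record_closed_form(self):
        """One founder, one record: solution of the 3x3 Henderson system
        (mean, genetic, maternal) matches an independently built dense
        system."""
        ped = Pedigree(ids=[1, 2], sire=[-1, -1], dam=[-1, -1],
                       sex=["F", "M"], time_step=[0, 1])
        rec = _records([2], [10.0], dam_id=1)
        spec = ModelSpec(
            traits=("BW5.B",), rtypes=(RecordType("M", 5, "B"),),
            rtype_trait_idx=(0,), residual_groups=((0,),),
            use_maternal=True, value_column="value_g",
        )
        va, vc, ve = 1.0, 0.5, 2.0
        design = build_design(rec, spec, ped)
        system = assemble_mme(design, np.array([[va]]), np.array([[ve]]),
                              build_A_inverse(ped), vc0=np.array([[vc]]))
        sol = solve_direct(system)
        # layout: genetic (2 animals), maternal (dam 1), fixed mean
        # record row w = [a2, c1, mu]; hand-built normal equations:
        lhs = np.array(
            [
                [1 / ve + 1 / va, 1 / ve, 1 / ve],
                [1 / ve, 1 / ve + 1 / vc, 1 / ve],
                [1 / ve, 1 / ve, 1 / ve],
            ]
        )
        rhs = np.array([10 / ve, 10 / ve, 10 / ve])
        expect = np.linalg.solve(lhs, rhs)
        assert sol[1] == pytest.approx(expect[0])   # animal 2 genetic
        assert sol[2] == pytest.approx(expect[1])   # dam maternal
        assert sol[3] == pytest.approx(expect[2])   # mean
        assert sol[0] == pytest.approx(0.0)         # unphenotyped founder

    def test_blup_scale_invariance(self, small_standardized, small_dataset):
        _, ds = small_dataset
        tp = default_true_params()
        spec = model2_spec()
        design = build_design(small_standardized, spec, ds.pedigree)
        ainv = build_A_inverse(ds.pedigree)
        s1 = solve_direct(assemble_mme(design, tp.va0, tp.ve0, ainv, vc0=tp.vc0))
        c = 3.7
        s2 = solve_direct(
            assemble_mme(design, c * tp.va0, c * tp.ve0, ainv, vc0=c * tp.vc0)
        )
        assert np.allclose(s1, s2, atol=1e-8)

    def test_zero_records_gives_zero_ebv(self, founder_pair):
        tab = predict_ebv(
            _records([], []), _univariate_spec(), founder_pair,
            build_A_inverse(founder_pair), va0=[[1.0]], ve0=[[1.0]],
        )
        assert np.allclose(tab.values, 0.0)

    def test_estimability_constant_shift_in_one_level(self, small_standardized, small_dataset):
        """Adding a constant to all records of one hatch-TS level changes
        only fixed effects, not EBV."""
        _, ds = small_dataset
        tp = default_true_params()
        spec = model2_spec()
        ainv = build_A_inverse(ds.pedigree)
        base = predict_ebv(small_standardized, spec, ds.pedigree, ainv,
                           va0=tp.va0, ve0=tp.ve0, vc0=tp.vc0, method="direct")
        shifted = small_standardized.copy()
        lev = shifted["hatch_ts"].iloc[0]
        shifted.loc[shifted["hatch_ts"] == lev, "value_std"] += 5.0
        out = predict_ebv(shifted, spec, ds.pedigree, ainv,
                          va0=tp.va0, ve0=tp.ve0, vc0=tp.vc0, method="direct")
        assert np.allclose(base.values, out.values, atol=1e-7)


class TestSolvers:
    def test_direct_residual_contract(self, small_standardized, small_dataset):
        _, ds = small_dataset
        tp = default_true_params()
        design = build_design(small_standardized, model2_spec(), ds.pedigree)
        system = assemble_mme(design, tp.va0, tp.ve0,
                              build_A_inverse(ds.pedigree), vc0=tp.vc0)
        x = solve_direct(system)
        resid = np.linalg.norm(system.matvec(x) - system.rhs)
        assert resid / np.linalg.norm(system.rhs) < 1e-10

    def test_pcg_agrees_with_direct(self, small_standardized, small_dataset):
        _, ds = small_dataset
        tp = default_true_params()
        design = build_design(small_standardized, model2_spec(), ds.pedigree)
        system = assemble_mme(design, tp.va0, tp.ve0,
                              build_A_inverse(ds.pedigree), vc0=tp.vc0)
        xd = solve_direct(system)
        res = solve_pcg(system, tol=1e-10)
        assert np.linalg.norm(res.x - xd) / np.linalg.norm(xd) < 1e-6

    def test_pcg_zero_iterations_at_solution(self, small_standardized, small_dataset):
        _, ds = small_dataset
        tp = default_true_params()
        design = build_design(small_standardized, model2_spec(), ds.pedigree)
        system = assemble_mme(design, tp.va0, tp.ve0,
                              build_A_inverse(ds.pedigree), vc0=tp.vc0)
        x = solve_direct(system)
        res = solve_pcg(system, tol=1e-8, x0=x)
        assert res.n_iter == 0

    def test_pcg_tightening_tolerance_improves_solution(self, small_standardized, small_dataset):
        _, ds = small_dataset
        tp = default_true_params()
        design = build_design(small_standardized, model2_spec(), ds.pedigree)
        system = assemble_mme(design, tp.va0, tp.ve0,
                              build_A_inverse(ds.pedigree), vc0=tp.vc0)
        xd = solve_direct(system)
        errs = [
            np.linalg.norm(solve_pcg(system, tol=tol).x - xd)
            for tol in (1e-4, 1e-7, 1e-10)
        ]
        assert errs[0] >= errs[1] >= errs[2]


class TestSingleStep:
    def test_parent_average_for_uninformative_offspring(self):
        """An unphenotyped final-generation animal's EBV equals its parent
        average (10-animal toy, direct solve)."""
        ped = Pedigree(
            ids=np.arange(1, 11),
            sire=[-1, -1, -1, -1, 0, 0, 2, 2, 4, 6],
            dam=[-1, -1, -1, -1, 1, 1, 3, 3, 5, 7],
            sex=["M", "F", "M", "F", "M", "F", "M", "F", "M", "F"],
            time_step=[0, 0, 0, 0, 1, 1, 1, 1, 2, 2],
        )
        rng = np.random.default_rng(0)
        rec = _records(np.arange(1, 9), rng.normal(10, 2, 8))
        tab = predict_ebv(rec, _univariate_spec(), ped, build_A_inverse(ped),
                          va0=[[1.0]], ve0=[[2.0]], method="direct")
        # animals 9, 10 have no records and no descendants
        assert tab.values[8, 0] == pytest.approx(
            0.5 * (tab.values[4, 0] + tab.values[5, 0]), abs=1e-8
        )
        assert tab.values[9, 0] == pytest.approx(
            0.5 * (tab.values[6, 0] + tab.values[7, 0]), abs=1e-8
        )

    def test_h_kernel_with_gw_equal_a22_matches_pblup(self, small_standardized, small_dataset):
        _, ds = small_dataset
        tp = default_true_params()
        spec = model2_spec()
        ainv = build_A_inverse(ds.pedigree)
        geno = ds.genotypes.subset_animals(ds.pedigree.ids[ds.genotyped])
        parts = make_h_inverse_parts(ds.pedigree, geno, omega=0.01, a_inv=ainv)
        parts_eq = dataclasses.replace(parts, g_w=parts.a22, g_w_inv=parts.a22_inv)
        pblup = predict_ebv(small_standardized, spec, ds.pedigree, ainv,
                            va0=tp.va0, ve0=tp.ve0, vc0=tp.vc0,
                            method="pcg", tol=1e-10)
        ss = predict_ebv(small_standardized, spec, ds.pedigree, parts_eq,
                         va0=tp.va0, ve0=tp.ve0, vc0=tp.vc0,
                         method="pcg", tol=1e-10)
        scale = np.abs(pblup.values).max()
        assert np.abs(pblup.values - ss.values).max() / scale < 1e-6

    def test_ssgblup_dense_oracle(self, small_standardized, small_dataset):
        _, ds = small_dataset
        tp = default_true_params()
        design = build_design(small_standardized, model2_spec(), ds.pedigree)
        ainv = build_A_inverse(ds.pedigree)
        geno = ds.genotypes.subset_animals(ds.pedigree.ids[ds.genotyped])
        parts = make_h_inverse_parts(ds.pedigree, geno, omega=0.01, a_inv=ainv)
        system = assemble_mme(design, tp.va0, tp.ve0, parts, vc0=tp.vc0)
        xd = solve_direct(system)
        res = solve_pcg(system, tol=1e-10)
        assert np.linalg.norm(res.x - xd) / np.linalg.norm(xd) < 1e-6
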
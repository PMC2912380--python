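"""Phenocopy injection: PM1 relabeling, PM2 substitution, pedigree swaps."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from phenosim.cohorts import PoolSpec, build_cc_pool, build_pedigree_pool, sample_case_control
from phenosim.disease import make_single_snp_model
from phenosim.genosim import ParameterError
from phenosim.phenocopy import (
    InjectionError,
    PhenocopySpec,
    check_disjoint_loci,
    pm1_case_control,
    pm1_pedigree,
    pm2_case_control,
    round_half_away,
)


@pytest.fixture(scope="module")
def me_toy(toy_pool):
    """Small main-effect world on the 50-marker toy chromosome."""
    model = make_single_snp_model(toy_pool.markers, "RL0-10", beta=0.8, prevalence=0.1)
    ds = build_cc_pool(toy_pool, model, PoolSpec(5, 100, 100, seed=21))
    reservoir = sample_case_control(toy_pool, model, 0, 600, seed=22).genotypes
    return model, ds, reservoir


def test_rounding_is_half_away_from_zero():
    assert round_half_away(0.5) == 1
    assert round_half_away(4.5) == 5
    assert round_half_away(4.49) == 4
    assert round_half_away(0.0) == 0


class TestPM1CaseControl:
    def test_level_zero_is_identity(self, me_toy):
        _, ds, reservoir = me_toy
        out = pm1_case_control(ds, reservoir, 0.0, seed=1)
        assert np.array_equal(out.genotypes.genotypes, ds.genotypes.genotypes)
        assert (out.phenocopy == "").all()

    def test_exact_flag_count_and_case_total(self, me_toy):
        _, ds, reservoir = me_toy
        out = pm1_case_control(ds, reservoir, 0.45, seed=2)
        assert (out.phenocopy == "PM1").sum() == round(0.45 * ds.n_cases)
        assert out.n_cases == ds.n_cases
        # controls untouched
        ctrl = ds.status == 0
        assert np.array_equal(
            out.genotypes.genotypes[ctrl], ds.genotypes.genotypes[ctrl]
        )
        # input not mutated
        assert (ds.phenocopy == "").all()

    def test_nested_ladder_under_one_seed(self, me_toy):
        _, ds, reservoir = me_toy
        lo = pm1_case_control(ds, reservoir, 0.10, seed=3)
        hi = pm1_case_control(ds, reservoir, 0.30, seed=3)
        low_set = set(np.flatnonzero(lo.phenocopy == "PM1"))
        high_set = set(np.flatnonzero(hi.phenocopy == "PM1"))
        assert low_set < high_set

    def test_flagged_rows_look_like_controls(self, me_toy):
        _, ds, reservoir = me_toy
        out = pm1_case_control(ds, reservoir, 0.45, seed=4)
        col = ds.genotypes.marker_index("RL0-10")
        flagged = out.genotypes.genotypes[out.phenocopy == "PM1", col]
        res = reservoir.genotypes[:, col]
        obs = np.stack(
            [np.bincount(flagged, minlength=3), np.bincount(res, minlength=3)]
        )
        _, p, *_ = chi2_contingency(obs[:, obs.sum(axis=0) > 0])
        assert p > 1e-4  # same distribution by construction

    def test_reservoir_too_small(self, me_toy):
        _, ds, reservoir = me_toy
        small = type(reservoir)(
            reservoir.genotypes[:3], reservoir.markers, reservoir.individual_ids[:3]
        )
        with pytest.raises(InjectionError):
            pm1_case_control(ds, small, 0.45, seed=5)

    def test_dilution_law(self, me_toy):
        # case MAF after injection = (1-L)*p_case + L*p_reservoir within 3 SE
        _, ds, reservoir = me_toy
        col = ds.genotypes.marker_index("RL0-10")
        p_case = ds.genotypes.genotypes[ds.status == 1, col].mean() / 2
        p_res = reservoir.genotypes[:, col].mean() / 2
        for level in (0.10, 0.30, 0.45):
            out = pm1_case_control(ds, reservoir, level, seed=6)
            observed = out.genotypes.genotypes[out.status == 1, col].mean() / 2
            expected = (1 - level) * p_case + level * p_res
            se = np.sqrt(expected * (1 - expected) / (2 * out.n_cases))
            assert abs(observed - expected) < 3 * se


class TestPM2CaseControl:
    def test_level_zero_is_identity(self, me_toy, toy_pool):
        model, ds, _ = me_toy
        alt = [make_single_snp_model(toy_pool.markers, "RL0-30", prevalence=0.1)]
        spec = PhenocopySpec("PM2", 0.0, alt, seed=7)
        out = pm2_case_control(ds, spec, toy_pool, main_model=model)
        assert np.array_equal(out.genotypes.genotypes, ds.genotypes.genotypes)

    def test_flags_record_source_model(self, me_toy, toy_pool):
        model, ds, _ = me_toy
        alt = [
            make_single_snp_model(toy_pool.markers, mid, prevalence=0.1)
            for mid in ("RL0-30", "RL0-40")
        ]
        spec = PhenocopySpec("PM2", 0.20, alt, seed=8)
        out = pm2_case_control(ds, spec, toy_pool, main_model=model)
        flags = out.phenocopy[out.phenocopy != ""]
        assert len(flags) == round(0.20 * ds.n_cases)
        assert set(flags) <= {"PM2:00", "PM2:01"}
        assert out.genotypes.n_individuals == ds.genotypes.n_individuals

    def test_disjointness_guard(self, me_toy, toy_pool):
        model, ds, _ = me_toy
        clash = [make_single_snp_model(toy_pool.markers, "RL0-10", prevalence=0.1)]
        with pytest.raises(ParameterError):
            check_disjoint_loci(model, clash)
        spec = PhenocopySpec("PM2", 0.1, clash, seed=9)
        with pytest.raises(ParameterError):
            pm2_case_control(ds, spec, toy_pool, main_model=model)

    def test_empty_alt_models_rejected(self):
        with pytest.raises(ParameterError):
            PhenocopySpec("PM2", 0.1, [], seed=0)

    def test_phenocopies_carry_signal_at_their_own_locus_only(self, me_toy, toy_pool):
        # PM2 phenocopies are enriched at the alternative causal locus;
        # PM1 phenocopies are control-like everywhere (incl. the alt locus)
        model, ds, reservoir = me_toy
        alt = [make_single_snp_model(toy_pool.markers, "RL0-30", beta=0.8, prevalence=0.1)]
        spec = PhenocopySpec("PM2", 0.45, alt, seed=10)
        pm2 = pm2_case_control(ds, spec, toy_pool, main_model=model)
        pm1 = pm1_case_control(ds, reservoir, 0.45, seed=10)
        col = ds.genotypes.marker_index("RL0-30")
        ctrl_maf = ds.genotypes.genotypes[ds.status == 0, col].mean() / 2
        pm2_maf = pm2.genotypes.genotypes[pm2.phenocopy != "", col].mean() / 2
        pm1_maf = pm1.genotypes.genotypes[pm1.phenocopy != "", col].mean() / 2
        n = (pm2.phenocopy != "").sum()
        se = np.sqrt(ctrl_maf * (1 - ctrl_maf) / (2 * n))
        assert pm2_maf - ctrl_maf > 3 * se  # enriched at its own locus
        assert abs(pm1_maf - ctrl_maf) < 4 * se  # PM1: no signal anywhere


@pytest.fixture(scope="module")
def ped(toy_pool):
    model = make_single_snp_model(toy_pool.markers, "RL0-10", prevalence=0.15)
    return build_pedigree_pool(toy_pool, model, n_replicates=2, seed=31)


class TestPM1Pedigree:

    def test_level_zero_is_identity(self, ped):
        out = pm1_pedigree(ped, 0.0, seed=1)
        for a, b in zip(out.families, ped.families):
            assert [c.status for c in a.children] == [c.status for c in b.children]
            assert not any(c.phenocopy for c in a.children)

    def test_design_counts_preserved_and_flag_count_exact(self, ped):
        total_affected = sum(len(f.affected_children()) for f in ped.families)
        for level in (0.10, 0.45):
            out = pm1_pedigree(ped, level, seed=2)
            flagged = sum(
                1 for f in out.families for c in f.children if c.phenocopy
            )
            assert flagged == round(level * total_affected)
            for before, after in zip(ped.families, out.families):
                assert len(after.affected_children()) == len(before.affected_children())
                des_aff = sum(1 for c in after.children if c.role == "affected")
                assert sum(
                    c.status for c in after.children if c.role != "extra"
                ) == des_aff

    def test_flagged_sibs_are_former_unaffected(self, ped):
        out = pm1_pedigree(ped, 0.30, seed=3)
        for fam_before, fam_after in zip(ped.families, out.families):
            for cb, ca in zip(fam_before.children, fam_after.children):
                if ca.phenocopy:
                    assert cb.status == 0 and ca.status == 1

    def test_infeasible_level_raises(self, ped):
        with pytest.raises(InjectionError):
            pm1_pedigree(ped, 0.9, seed=4)

    def test_input_not_mutated(self, ped):
        statuses = [[c.status for c in f.children] for f in ped.families]
        pm1_pedigree(ped, 0.45, seed=5)
        assert statuses == [[c.status for c in f.children] for f in ped.families]
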
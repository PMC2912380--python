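"""Case-control pooling and ascertained family sampling."""

import numpy as np
import pytest

from phenosim.cohorts import (
    FAMILY_CONFIGS,
    PoolSpec,
    SamplingError,
    build_cc_pool,
    build_pedigree_pool,
    sample_case_control,
    sample_family,
)
from phenosim.disease import LogisticDiseaseModel, achieved_odds_ratio, table_penetrance
from phenosim.assoc import single_point_scan
from phenosim.genosim import ParameterError


class TestCaseControlSampling:
    def test_quota_exactness(self, toy_pool):
        model = LogisticDiseaseModel(-2.0, {})
        ds = sample_case_control(toy_pool, model, 200, 200, seed=1)
        assert ds.genotypes.n_individuals == 400
        assert ds.n_cases == 200 and ds.n_controls == 200
        assert (ds.phenocopy == "").all()

    def test_controls_only(self, toy_pool):
        model = LogisticDiseaseModel(-2.0, {})
        ds = sample_case_control(toy_pool, model, 0, 50, seed=2)
        assert ds.n_cases == 0 and ds.n_controls == 50

    def test_unreachable_quota_raises(self, toy_pool):
        never_affected = LogisticDiseaseModel(-50.0, {})
        with pytest.raises(SamplingError):
            sample_case_control(toy_pool, never_affected, 10, 0, seed=3, max_draws=2000)

    def test_high_risk_class_enrichment_matches_enumeration(self, epi_exp, epi_cc_small):
        table = epi_exp.main_model
        _, high = achieved_odds_ratio(table.cells, table.maf)
        pen = table_penetrance(table, epi_cc_small.genotypes)
        cols = [epi_cc_small.genotypes.marker_index(m) for m in table.loci]
        g = epi_cc_small.genotypes.genotypes[:, cols]
        in_high = high[g[:, 0], g[:, 1], g[:, 2]]
        case_frac = in_high[epi_cc_small.status == 1].mean()
        ctrl_frac = in_high[epi_cc_small.status == 0].mean()
        # expectation by exact enumeration over the 27 cells
        from phenosim.disease import hwe_genotype_probs

        probs = [hwe_genotype_probs(m) for m in table.maf]
        w = np.einsum("i,j,k->ijk", *probs)
        prev = float((w * table.cells).sum())
        exp_case = float((w * table.cells * high).sum() / prev)
        exp_ctrl = float((w * (1 - table.cells) * high).sum() / (1 - prev))
        n1, n0 = epi_cc_small.n_cases, epi_cc_small.n_controls
        assert abs(case_frac - exp_case) < 3 * np.sqrt(exp_case * (1 - exp_case) / n1)
        assert abs(ctrl_frac - exp_ctrl) < 3 * np.sqrt(exp_ctrl * (1 - exp_ctrl) / n0)
        assert case_frac > ctrl_frac


class TestPooling:
    def test_pool_dimensions_and_replicates(self, toy_pool):
        model = LogisticDiseaseModel(-2.0, {})
        ds = build_cc_pool(toy_pool, model, PoolSpec(3, 20, 30, seed=4))
        assert ds.genotypes.n_individuals == 3 * 50
        assert set(ds.replicate_id) == {0, 1, 2}
        assert ds.n_cases == 60

    def test_minimal_pool(self, toy_pool):
        model = LogisticDiseaseModel(-2.0, {})
        ds = build_cc_pool(toy_pool, model, PoolSpec(1, 1, 1, seed=5))
        assert ds.genotypes.n_individuals == 2

    def test_pooled_maf_is_mean_of_replicate_mafs(self, toy_pool):
        model = LogisticDiseaseModel(-2.0, {})
        ds = build_cc_pool(toy_pool, model, PoolSpec(4, 25, 25, seed=6))
        pooled = ds.genotypes.genotypes.mean(axis=0) / 2
        per_rep = np.stack(
            [
                ds.genotypes.genotypes[ds.replicate_id == r].mean(axis=0) / 2
                for r in range(4)
            ]
        )
        assert np.allclose(pooled, per_rep.mean(axis=0))

    def test_replicate_order_does_not_affect_scan(self, toy_pool):
        model = LogisticDiseaseModel(-2.0, {"RL0-10": 0.8})
        ds = build_cc_pool(toy_pool, model, PoolSpec(3, 40, 40, seed=7))
        scan = single_point_scan(ds)
        shuffled = ds.copy()
        perm = np.random.default_rng(0).permutation(ds.genotypes.n_individuals)
        shuffled.genotypes.genotypes = shuffled.genotypes.genotypes[perm]
        shuffled.status = shuffled.status[perm]
        shuffled.phenocopy = shuffled.phenocopy[perm]
        shuffled.replicate_id = shuffled.replicate_id[perm]
        scan2 = single_point_scan(shuffled)
        assert np.allclose(scan["chi2_allelic"], scan2["chi2_allelic"])


class TestFamilies:
    def test_configuration_sizes(self, toy_pool, rng):
        model = LogisticDiseaseModel(-2.0, {})
        for (na, nu, nx), size in zip(FAMILY_CONFIGS, (5, 6, 9)):
            fam = sample_family(toy_pool, model, na, nu, nx, rng)
            assert fam.size == size
            constrained = [c for c in fam.children if c.role != "extra"]
            assert sum(c.status for c in constrained if c.role == "affected") == na
            assert sum(c.status == 1 for c in constrained) == na
            assert sum(c.status == 0 for c in constrained) == nu

    def test_parents_only(self, toy_pool, rng):
        model = LogisticDiseaseModel(-2.0, {})
        fam = sample_family(toy_pool, model, 0, 0, 0, rng)
        assert fam.size == 2 and fam.children == []

    def test_children_mendelian_consistent(self, toy_pool, rng):
        model = LogisticDiseaseModel(-2.0, {})
        fam = sample_family(toy_pool, model, 2, 2, 3, rng)
        for i, child in enumerate(fam.children):
            g = fam.child_genotype(i)
            expected = (
                fam.father_haps[child.t_father] + fam.mother_haps[child.t_mother]
            )
            assert np.array_equal(g, expected)
            possible = np.zeros_like(g, dtype=bool)
            for fa in fam.father_haps:
                for ma in fam.mother_haps:
                    possible |= g == fa + ma
            assert possible.all()

    def test_pedigree_pool_arithmetic(self, toy_pool):
        model = LogisticDiseaseModel(-2.0, {})
        ped = build_pedigree_pool(toy_pool, model, n_replicates=1, seed=8)
        assert ped.n_individuals == 25 * (5 + 6 + 9)
        assert len(ped.families) == 75
        labels = [f.config_label for f in ped.families]
        for (na, nu, nx) in FAMILY_CONFIGS:
            assert labels.count(f"{na}aff_{nu}unaff_{nx}extra") == 25

    def test_ascertainment_pattern_holds_everywhere(self, toy_pool):
        model = LogisticDiseaseModel(-2.0, {})
        ped = build_pedigree_pool(
            toy_pool, model, n_replicates=2, families_per_config=5, seed=9
        )
        for fam in ped.families:
            na = sum(1 for c in fam.children if c.role == "affected")
            nu = sum(1 for c in fam.children if c.role == "unaffected")
            nx = sum(1 for c in fam.children if c.role == "extra")
            assert fam.config_label == f"{na}aff_{nu}unaff_{nx}extra"
            assert all(c.status == 1 for c in fam.children if c.role == "affected")
            assert all(c.status == 0 for c in fam.children if c.role == "unaffected")

    def test_negative_counts_rejected(self, toy_pool, rng):
        model = LogisticDiseaseModel(-2.0, {})
        with pytest.raises(ParameterError):
            sample_family(toy_pool, model, -1, 0, 0, rng)
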
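"""Disease models: logistic penetrance and the epistatic table search."""

import itertools

import numpy as np
import pytest

from phenosim.disease import (
    ConvergenceError,
    EpistaticSearchConfig,
    LogisticDiseaseModel,
    PenetranceTable,
    achieved_odds_ratio,
    assign_status,
    calibrate_intercept,
    generate_epistatic_table,
    hwe_genotype_probs,
    logistic_penetrance,
    model_prevalence,
    table_marginals,
)
from phenosim.genosim import sample_genotypes


class TestLogisticModel:
    def test_beta_to_odds_ratio_identity(self):
        model = LogisticDiseaseModel(-2.0, {"RL0-855": 0.80})
        assert model.odds_ratio("RL0-855") == pytest.approx(2.225540928, abs=1e-9)

    def test_null_model_flat_penetrance(self, toy_markers):
        model = LogisticDiseaseModel(-1.5, {})
        g = np.random.default_rng(0).integers(0, 3, (20, len(toy_markers)))
        pen = logistic_penetrance(model, g, toy_markers)
        assert np.allclose(pen, 1 / (1 + np.exp(1.5)))

    def test_odds_ratio_between_adjacent_dosages(self, toy_markers):
        model = LogisticDiseaseModel(-2.0, {"RL0-3": 0.8})
        rows = np.zeros((3, len(toy_markers)), dtype=np.int8)
        rows[:, 3] = [0, 1, 2]
        pen = logistic_penetrance(model, rows, toy_markers)
        odds = pen / (1 - pen)
        assert odds[1] / odds[0] == pytest.approx(np.exp(0.8), rel=1e-12)
        assert odds[2] / odds[1] == pytest.approx(np.exp(0.8), rel=1e-12)

    def test_interaction_term_enters_linear_predictor(self, toy_markers):
        model = LogisticDiseaseModel(
            0.0, {}, {("RL0-1", "RL0-2", "RL0-3"): 0.5}
        )
        row = np.zeros(len(toy_markers), dtype=np.int8)
        row[[1, 2, 3]] = [2, 1, 2]
        pen = logistic_penetrance(model, row, toy_markers)
        assert pen == pytest.approx(1 / (1 + np.exp(-0.5 * 4)))

    def test_intercept_calibration_hits_prevalence(self, me_exp):
        # exact enumeration and forward simulation must both agree
        assert model_prevalence(me_exp.main_model, me_exp.markers) == pytest.approx(0.10, abs=1e-9)
        gm = sample_genotypes(me_exp.pool, 20000, seed=1)
        status = assign_status(gm, me_exp.main_model, seed=2)
        se = np.sqrt(0.1 * 0.9 / 20000)
        assert abs(status.mean() - 0.10) < 4 * se

    def test_missing_marker_raises(self, toy_markers):
        from phenosim.disease import ModelError

        model = LogisticDiseaseModel(0.0, {"RL0-999": 1.0})
        with pytest.raises(ModelError):
            logistic_penetrance(model, np.zeros((2, len(toy_markers)), dtype=np.int8), toy_markers)


class TestTableMarginals:
    def test_flat_table(self):
        marg, prev = table_marginals(np.full((3, 3, 3), 0.2), np.array([0.3, 0.3, 0.3]))
        assert np.allclose(marg, 0.2) and prev == pytest.approx(0.2)

    def test_prevalence_matches_direct_summation(self, rng):
        cells = rng.random((3, 3, 3))
        maf = np.array([0.2, 0.35, 0.45])
        probs = [hwe_genotype_probs(m) for m in maf]
        direct = sum(
            cells[i, j, k] * probs[0][i] * probs[1][j] * probs[2][k]
            for i, j, k in itertools.product(range(3), repeat=3)
        )
        marg, prev = table_marginals(cells, maf)
        assert prev == pytest.approx(direct, abs=1e-12)
        # marginal oracle: direct conditional summation per locus/genotype
        for g in range(3):
            oracle = sum(
                cells[g, j, k] * probs[1][j] * probs[2][k]
                for j, k in itertools.product(range(3), repeat=2)
            )
            assert marg[0, g] == pytest.approx(oracle, abs=1e-12)

    def test_two_locus_xor_has_equal_marginals(self):
        # high penetrance iff exactly one locus heterozygous; at MAF 0.5 the
        # 9-cell enumeration gives identical marginals for every genotype
        a, b = 0.3, 0.05
        cells = np.full((3, 3), b)
        for i, j in itertools.product(range(3), repeat=2):
            if (i == 1) != (j == 1):
                cells[i, j] = a
        marg, prev = table_marginals(cells, np.array([0.5, 0.5]))
        assert np.allclose(marg, marg[0, 0])
        assert prev == pytest.approx(marg[0, 0])


class TestEpistaticSearch:
    def test_generated_table_meets_constraints(self, epi_exp):
        table = epi_exp.main_model
        assert isinstance(table, PenetranceTable)
        assert abs(np.log(table.achieved_or / 4.0)) <= np.log(1.02)
        assert table.marginal_dev <= 0.005
        assert 0.08 <= table.prevalence <= 0.12
        assert table.trace  # search trace retained

    def test_achieved_or_matches_exact_enumeration(self, epi_exp):
        table = epi_exp.main_model
        odds_ratio, high = achieved_odds_ratio(table.cells, table.maf)
        assert odds_ratio == pytest.approx(table.achieved_or)
        # independent oracle: recompute from scratch with explicit loops
        probs = [hwe_genotype_probs(m) for m in table.maf]
        num = den = wh = 0.0
        prev = table.prevalence
        for i, j, k in itertools.product(range(3), repeat=3):
            w = probs[0][i] * probs[1][j] * probs[2][k]
            if table.cells[i, j, k] > prev:
                num += w * table.cells[i, j, k]
                wh += w
            else:
                den += w * table.cells[i, j, k]
        p1, p0 = num / wh, den / (1 - wh)
        oracle = (p1 / (1 - p1)) / (p0 / (1 - p0))
        assert odds_ratio == pytest.approx(oracle, abs=1e-12)

    def test_flat_population_is_penalised(self):
        from phenosim.disease import _hwe_weight_tensor, _population_fitness

        w = _hwe_weight_tensor(np.full(3, 0.3))
        flat = np.full((1, 3, 3, 3), 0.2)
        fitness, odds_ratio, dev, prev = _population_fitness(flat, w, 4.0, (1.0, 10.0))
        assert dev[0] == pytest.approx(0.0)
        assert not np.isfinite(odds_ratio[0]) or odds_ratio[0] <= 0 or fitness[0] < -100
        assert fitness[0] < -100  # OR miss dominates

    def test_infeasible_budget_raises_with_best_table(self):
        cfg = EpistaticSearchConfig(maf=0.3, generations=2, population_size=20, seed=0)
        with pytest.raises(ConvergenceError) as err:
            generate_epistatic_table(cfg)
        assert isinstance(err.value.best_table, PenetranceTable)

    def test_search_determinism(self):
        cfg = EpistaticSearchConfig(maf=0.3, seed=9)
        a = generate_epistatic_table(cfg)
        b = generate_epistatic_table(cfg)
        assert np.array_equal(a.cells, b.cells)


class TestAssignStatus:
    def test_certain_penetrance(self, toy_pool):
        gm = sample_genotypes(toy_pool, 200, seed=3)
        model = LogisticDiseaseModel(50.0, {})  # expit(50) ~ 1
        assert assign_status(gm, model, seed=4).all()

    def test_binomial_fraction(self, toy_pool):
        gm = sample_genotypes(toy_pool, 100000, seed=5)
        model = calibrate_intercept(
            LogisticDiseaseModel(0.0, {}), toy_pool.markers, 0.1
        )
        status = assign_status(gm, model, seed=6)
        se = np.sqrt(0.1 * 0.9 / 100000)
        assert abs(status.mean() - 0.1) < 3 * se

    def test_main_effect_enriches_minor_allele_in_cases(self, me_exp):
        gm = sample_genotypes(me_exp.pool, 20000, seed=7)
        status = assign_status(gm, me_exp.main_model, seed=8)
        col = gm.marker_index("RL0-855")
        g = gm.genotypes[:, col]
        case_maf = g[status == 1].mean() / 2
        ctrl_maf = g[status == 0].mean() / 2
        n1, n0 = (status == 1).sum(), (status == 0).sum()
        se = np.sqrt(case_maf * (1 - case_maf) / (2 * n1) + ctrl_maf * (1 - ctrl_maf) / (2 * n0))
        # one-sided z test, p < 0.001 corresponds to z > 3.09
        assert (case_maf - ctrl_maf) / se > 3.09
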
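"""Disease models: mixed logistic main-effect model and purely epistatic tables.

Two penetrance machineries assign affection status:

* :class:`LogisticDiseaseModel` — P(affected | g) = expit(a + sum b_i g_i +
  sum c_T prod_{i in T} g_i), additive dosage coding; a per-allele odds ratio
  is exp(beta), so the target beta 0.80 corresponds to OR 2.225540928.
* :class:`PenetranceTable` — a 27-cell three-locus table with no single-locus
  main effect ("purely epistatic"): every single-locus marginal penetrance,
  computed under HWE at the assumed MAFs, equals the table prevalence to a
  small tolerance. Tables are found by a genetic algorithm whose fitness
  rewards hitting a target odds ratio and punishes marginal deviation.

The "achieved" odds ratio of a table is defined over the HWE-weighted
dichotomy of cells into a high-penetrance class (cells above the weighted
mean penetrance) versus the rest — the same dichotomy MDR estimates from
data, which makes the target directly comparable with the cross-validated
MDR odds ratio downstream.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .genosim import GenotypeMatrix, MarkerInfo, ParameterError


class ModelError(ValueError):
    """A disease model references markers missing from the data."""


class ConvergenceError(RuntimeError):
    """The table search failed its tolerance; carries the best table found."""

    def __init__(self, message: str, best_table: "PenetranceTable"):
        super().__init__(message)
        self.best_table = best_table


# ---------------------------------------------------------------------------
# Logistic (mixed) model


@dataclass
class LogisticDiseaseModel:
    """Logistic penetrance with main effects and dosage-product interactions."""

    intercept: float
    main_effects: dict[str, float] = field(default_factory=dict)
    interactions: dict[tuple[str, ...], float] = field(default_factory=dict)

    @property
    def loci(self) -> list[str]:
        seen: dict[str, None] = {}
        for mid in self.main_effects:
            seen.setdefault(mid)
        for combo in self.interactions:
            for mid in combo:
                seen.setdefault(mid)
        return list(seen)

    def odds_ratio(self, marker_id: str) -> float:
        """Per-minor-allele odds ratio implied by a main-effect coefficient."""
        return float(np.exp(self.main_effects[marker_id]))


def logistic_penetrance(
    model: LogisticDiseaseModel,
    genotypes: np.ndarray | GenotypeMatrix,
    markers: list[MarkerInfo] | None = None,
) -> np.ndarray:
    """Penetrance for each row of a dosage matrix (or a single row)."""
    if isinstance(genotypes, GenotypeMatrix):
        markers = genotypes.markers
        genotypes = genotypes.genotypes
    if markers is None:
        raise ModelError("marker metadata required alongside a raw dosage array")
    index = {m.id: m.index for m in markers}
    g = np.atleast_2d(np.asarray(genotypes, dtype=float))
    eta = np.full(g.shape[0], model.intercept)
    try:
        for mid, beta in model.main_effects.items():
            eta += beta * g[:, index[mid]]
        for combo, gamma in model.interactions.items():
            prod = np.ones(g.shape[0])
            for mid in combo:
                prod *= g[:, index[mid]]
            eta += gamma * prod
    except KeyError as exc:
        raise ModelError(f"model references missing marker {exc}") from None
    pen = expit(eta)
    return pen[0] if np.ndim(genotypes) == 1 else pen


def hwe_genotype_probs(maf: float) -> np.ndarray:
    """P(dosage = 0, 1, 2) under HWE at minor-allele frequency ``maf``."""
    p = maf
    return np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])


def model_prevalence(
    model: LogisticDiseaseModel, markers: list[MarkerInfo]
) -> float:
    """Population prevalence by exact enumeration over the referenced loci.

    Assumes the causal loci are in linkage equilibrium with each other (they
    are placed in distinct LD blocks in the benchmark maps).
    """
    loci = model.loci
    maf = {m.id: m.maf for m in markers}
    probs = [hwe_genotype_probs(maf[mid]) for mid in loci]
    prev = 0.0
    for combo in itertools.product((0, 1, 2), repeat=len(loci)):
        w = 1.0
        for k, g in enumerate(combo):
            w *= probs[k][g]
        eta = model.intercept
        for mid, beta in model.main_effects.items():
            eta += beta * combo[loci.index(mid)]
        for tup, gamma in model.interactions.items():
            prod = 1.0
            for mid in tup:
                prod *= combo[loci.index(mid)]
            eta += gamma * prod
        prev += w * expit(eta)
    return prev


def calibrate_intercept(
    model: LogisticDiseaseModel,
    markers: list[MarkerInfo],
    target_prevalence: float = 0.10,
) -> LogisticDiseaseModel:
    """Return a copy with the intercept tuned to the target prevalence."""
    if not 0.0 < target_prevalence < 1.0:
        raise ParameterError("target_prevalence must be in (0, 1)")

    def gap(alpha: float) -> float:
        trial = LogisticDiseaseModel(alpha, model.main_effects, model.interactions)
        return model_prevalence(trial, markers) - target_prevalence

    alpha = brentq(gap, -30.0, 30.0, xtol=1e-12)
    return LogisticDiseaseModel(
        intercept=float(alpha),
        main_effects=dict(model.main_effects),
        interactions=dict(model.interactions),
    )


def make_main_effect_model(
    markers: list[MarkerInfo],
    causal: str = "RL0-855",
    beta: float = 0.80,
    aux_loci: tuple[str, ...] = ("RL0-75", "RL0-245", "RL0-457"),
    aux_beta: float = 0.05,
    aux_gamma: float = 0.30,
    prevalence: float = 0.10,
) -> LogisticDiseaseModel:
    """The mixed main-effect disease model: one strong SNP (per-allele OR
    exp(beta) = 2.2255 at the default) plus three SNPs with very small
    marginal effects and a three-way interaction."""
    main = {causal: beta}
    main.update({mid: aux_beta for mid in aux_loci})
    interactions = {tuple(aux_loci): aux_gamma} if aux_gamma else {}
    raw = LogisticDiseaseModel(0.0, main, interactions)
    return calibrate_intercept(raw, markers, prevalence)


def make_single_snp_model(
    markers: list[MarkerInfo],
    causal: str,
    beta: float = 0.80,
    prevalence: float = 0.10,
) -> LogisticDiseaseModel:
    """A one-SNP logistic model (used for the alternative-determinant sets)."""
    raw = LogisticDiseaseModel(0.0, {causal: beta}, {})
    return calibrate_intercept(raw, markers, prevalence)


# ---------------------------------------------------------------------------
# Purely epistatic penetrance tables


@dataclass
class PenetranceTable:
    """Three-locus penetrance table with zero single-locus main effects."""

    loci: tuple[str, str, str]
    cells: np.ndarray  # (3, 3, 3) penetrances in [0, 1]
    maf: np.ndarray  # (3,) assumed minor-allele frequency per locus
    achieved_or: float
    marginal_dev: float
    seed: int | None = None
    trace: list[float] | None = None  # best fitness per GA generation

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=float)
        self.maf = np.asarray(self.maf, dtype=float)
        if self.cells.shape != (3, 3, 3):
            raise ParameterError("cells must be a 3x3x3 array")
        if np.any(self.cells < 0) or np.any(self.cells > 1):
            raise ParameterError("penetrances must lie in [0, 1]")

    @property
    def prevalence(self) -> float:
        return float(np.sum(self.cells * _hwe_weight_tensor(self.maf)))


@dataclass
class EpistaticSearchConfig:
    """Controls for the genetic-algorithm table search."""

    target_or: float = 4.0
    maf: float | tuple[float, float, float] = 0.30
    population_size: int = 240
    generations: int = 600
    mutation_rate: float = 0.15
    mutation_scale: float = 0.12
    crossover_rate: float = 0.9
    repair_fraction: float = 0.5
    marginal_tolerance: float = 0.005
    or_tolerance: float = 0.02
    fitness_weights: tuple[float, float] = (1.0, 10.0)
    target_prevalence: float | None = 0.10
    prevalence_tolerance: float = 0.02
    prevalence_weight: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_or <= 1:
            raise ParameterError("target_or must be > 1")
        if self.marginal_tolerance <= 0:
            raise ParameterError("marginal_tolerance must be > 0")

    @property
    def maf_vector(self) -> np.ndarray:
        if np.isscalar(self.maf):
            return np.full(3, float(self.maf))
        return np.asarray(self.maf, dtype=float)


def _hwe_weight_tensor(maf: np.ndarray) -> np.ndarray:
    w1, w2, w3 = (hwe_genotype_probs(m) for m in maf)
    return np.einsum("i,j,k->ijk", w1, w2, w3)


def table_marginals(
    cells: np.ndarray | PenetranceTable, maf: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Single-locus marginal penetrances and overall prevalence under HWE.

    Returns an (n_loci, 3) array: row l gives P(affected | locus l dosage g)
    with the other loci integrated out at their HWE weights. Works for any
    number of loci (cells of shape (3,)*k).
    """
    if isinstance(cells, PenetranceTable):
        maf = cells.maf
        cells = cells.cells
    cells = np.asarray(cells, dtype=float)
    maf = np.asarray(maf, dtype=float)
    k = cells.ndim
    probs = [hwe_genotype_probs(m) for m in maf]
    full_w = probs[0]
    for p in probs[1:]:
        full_w = np.multiply.outer(full_w, p)
    prevalence = float(np.sum(cells * full_w))
    marg = np.empty((k, 3))
    for axis in range(k):
        w = np.ones(())
        for other in range(k):
            if other != axis:
                w = np.multiply.outer(w, probs[other])
        moved = np.moveaxis(cells, axis, 0)
        marg[axis] = np.tensordot(moved, w, axes=k - 1)
    return marg, prevalence


def achieved_odds_ratio(
    cells: np.ndarray, maf: np.ndarray
) -> tuple[float, np.ndarray]:
    """Odds ratio of disease for the high-penetrance cell class vs the rest.

    High class = cells above the HWE-weighted mean penetrance. Returns NaN if
    either class is empty or degenerate.
    """
    cells = np.asarray(cells, dtype=float)
    w = _hwe_weight_tensor(np.asarray(maf, dtype=float))
    prevalence = float(np.sum(cells * w))
    high = cells > prevalence
    w_high = float(np.sum(w[high]))
    if w_high <= 0.0 or w_high >= 1.0:
        return float("nan"), high
    p1 = float(np.sum((w * cells)[high])) / w_high
    p0 = float(np.sum((w * cells)[~high])) / (1.0 - w_high)
    if p1 >= 1.0 or p0 <= 0.0 or p0 >= 1.0:
        return float("nan"), high
    return (p1 / (1 - p1)) / (p0 / (1 - p0)), high


def _population_fitness(
    pop: np.ndarray,
    w: np.ndarray,
    target_or: float,
    weights: tuple[float, float],
    target_prevalence: float | None = None,
    prevalence_weight: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised GA fitness over a (P, 3, 3, 3) population.

    fitness = -w1*|log(OR/target)| - w2*marginal_dev - w3*|prevalence - pi0|;
    an undefined OR is heavily penalised so flat tables never win. The
    prevalence pull keeps tables at a disease-like baseline risk without
    being part of the convergence test.
    """
    w1, w2 = weights
    prev = np.einsum("pijk,ijk->p", pop, w)
    # w is a product measure, so summing out one axis leaves the outer
    # product of the other two loci's HWE weights.
    m1 = np.einsum("pijk,jk->pi", pop, w.sum(axis=0))
    m2 = np.einsum("pijk,ik->pj", pop, w.sum(axis=1))
    m3 = np.einsum("pijk,ij->pk", pop, w.sum(axis=2))
    margs = np.stack([m1, m2, m3], axis=1)  # (P, 3, 3)
    dev = np.abs(margs - prev[:, None, None]).max(axis=(1, 2))

    high = pop > prev[:, None, None, None]
    w_high = np.einsum("pijk,ijk->p", high.astype(float), w)
    num_high = np.einsum("pijk,ijk->p", pop * high, w)
    num_low = prev - num_high
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = num_high / w_high
        p0 = num_low / (1.0 - w_high)
        odds_ratio = (p1 / (1 - p1)) / (p0 / (1 - p0))
        or_term = np.abs(np.log(odds_ratio / target_or))
    bad = (
        ~np.isfinite(odds_ratio)
        | (odds_ratio <= 0)
        | (w_high <= 0)
        | (w_high >= 1)
    )
    or_term = np.where(bad, 1e3, or_term)
    fitness = -w1 * or_term - w2 * dev
    if target_prevalence is not None and prevalence_weight:
        fitness = fitness - prevalence_weight * np.abs(prev - target_prevalence)
    return fitness, odds_ratio, dev, prev


def _repair_marginals(pop: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Nudge tables toward flat single-locus marginals (additive correction)."""
    prev = np.einsum("pijk,ijk->p", pop, w)
    m1 = np.einsum("pijk,jk->pi", pop, w.sum(axis=0))
    m2 = np.einsum("pijk,ik->pj", pop, w.sum(axis=1))
    m3 = np.einsum("pijk,ij->pk", pop, w.sum(axis=2))
    adj = (
        (prev[:, None] - m1)[:, :, None, None]
        + (prev[:, None] - m2)[:, None, :, None]
        + (prev[:, None] - m3)[:, None, None, :]
    )
    return np.clip(pop + adj, 0.0, 1.0)


def generate_epistatic_table(
    config: EpistaticSearchConfig,
    loci: tuple[str, str, str] = ("RL0-75", "RL0-153", "RL0-272"),
) -> PenetranceTable:
    """Search penetrance space for a purely epistatic table at the target OR.

    A real-coded genetic algorithm over 27 penetrance cells: tournament
    selection, uniform crossover, Gaussian mutation, an elitist survivor, and
    a marginal-flattening repair operator applied to a fraction of offspring.
    Stops early once the marginal deviation and the relative OR error are both
    inside tolerance; raises :class:`ConvergenceError` (carrying the best
    table) if the budget is exhausted first.
    """
    rng = np.random.default_rng(config.seed)
    maf = config.maf_vector
    w = _hwe_weight_tensor(maf)
    P = config.population_size
    pop = rng.random((P, 3, 3, 3))
    trace: list[float] = []
    best_cells: np.ndarray | None = None
    best_key = (np.inf, np.inf)  # (marginal_dev, |log OR error|) lexicographic

    prev_tol = (
        np.inf if config.target_prevalence is None else config.prevalence_tolerance
    )
    target_prev = config.target_prevalence or 0.0
    for _gen in range(config.generations):
        fitness, odds_ratio, dev, prev = _population_fitness(
            pop,
            w,
            config.target_or,
            config.fitness_weights,
            config.target_prevalence,
            config.prevalence_weight,
        )
        ibest = int(np.argmax(fitness))
        trace.append(float(fitness[ibest]))
        with np.errstate(invalid="ignore", divide="ignore"):
            or_err = np.abs(np.log(odds_ratio / config.target_or))
        or_err = np.where(np.isfinite(or_err), or_err, np.inf)
        prev_gap = (
            np.abs(prev - target_prev)
            if config.target_prevalence is not None
            else np.zeros_like(prev)
        )
        feasible = (dev <= config.marginal_tolerance) & (prev_gap <= prev_tol)
        cand = np.where(feasible, or_err, np.inf)
        icand = int(np.argmin(cand))
        key = (
            (0.0, float(cand[icand]))
            if feasible[icand]
            else (float(dev[ibest] + prev_gap[ibest]), float(or_err[ibest]))
        )
        if key < best_key:
            best_key = key
            best_cells = pop[icand if feasible[icand] else ibest].copy()
        if feasible[icand] and or_err[icand] <= np.log(1.0 + config.or_tolerance):
            best_cells = pop[icand].copy()
            break

        # next generation
        order = np.argsort(fitness)[::-1]
        elite = pop[order[0]].copy()
        t1 = rng.integers(P, size=P)
        t2 = rng.integers(P, size=P)
        parents = np.where((fitness[t1] >= fitness[t2])[:, None, None, None], pop[t1], pop[t2])
        mates = parents[rng.permutation(P)]
        cross = rng.random((P, 3, 3, 3)) < 0.5
        do_cross = (rng.random(P) < config.crossover_rate)[:, None, None, None]
        offspring = np.where(do_cross & cross, mates, parents)
        mut = rng.random((P, 3, 3, 3)) < config.mutation_rate
        offspring = np.clip(
            offspring + mut * rng.normal(0.0, config.mutation_scale, (P, 3, 3, 3)),
            0.0,
            1.0,
        )
        n_rep = int(config.repair_fraction * P)
        if n_rep:
            offspring[:n_rep] = _repair_marginals(offspring[:n_rep], w)
        offspring[0] = elite
        pop = offspring

    assert best_cells is not None
    cells = best_cells
    marg, prev = table_marginals(cells, maf)
    dev_final = float(np.abs(marg - prev).max())
    or_final, _ = achieved_odds_ratio(cells, maf)
    table = PenetranceTable(
        loci=tuple(loci),
        cells=cells,
        maf=maf,
        achieved_or=float(or_final),
        marginal_dev=dev_final,
        seed=config.seed,
        trace=trace,
    )
    or_ok = np.isfinite(or_final) and abs(
        np.log(or_final / config.target_or)
    ) <= np.log(1.0 + config.or_tolerance)
    prev_ok = (
        config.target_prevalence is None
        or abs(prev - config.target_prevalence) <= config.prevalence_tolerance
    )
    if dev_final > config.marginal_tolerance or not or_ok or not prev_ok:
        raise ConvergenceError(
            f"table search did not converge: marginal_dev={dev_final:.4g}, "
            f"achieved_or={or_final:.4g} (target {config.target_or}), "
            f"prevalence={prev:.4g}",
            table,
        )
    return table


def table_penetrance(
    table: PenetranceTable,
    genotypes: np.ndarray | GenotypeMatrix,
    markers: list[MarkerInfo] | None = None,
) -> np.ndarray:
    """Penetrance lookup for each row of a dosage matrix."""
    if isinstance(genotypes, GenotypeMatrix):
        markers = genotypes.markers
        genotypes = genotypes.genotypes
    if markers is None:
        raise ModelError("marker metadata required alongside a raw dosage array")
    index = {m.id: m.index for m in markers}
    try:
        cols = [index[mid] for mid in table.loci]
    except KeyError as exc:
        raise ModelError(f"table references missing marker {exc}") from None
    g = np.atleast_2d(genotypes)
    pen = table.cells[g[:, cols[0]], g[:, cols[1]], g[:, cols[2]]]
    return pen[0] if np.ndim(genotypes) == 1 else pen


DiseaseModel = LogisticDiseaseModel | PenetranceTable


def penetrance(
    model: DiseaseModel,
    genotypes: np.ndarray | GenotypeMatrix,
    markers: list[MarkerInfo] | None = None,
) -> np.ndarray:
    """Dispatch penetrance computation on the model type."""
    if isinstance(model, LogisticDiseaseModel):
        return logistic_penetrance(model, genotypes, markers)
    if isinstance(model, PenetranceTable):
        return table_penetrance(model, genotypes, markers)
    raise ModelError(f"unknown disease model type {type(model)!r}")


def model_loci(model: DiseaseModel) -> list[str]:
    if isinstance(model, LogisticDiseaseModel):
        return model.loci
    return list(model.loci)


def assign_status(
    genotypes: GenotypeMatrix,
    model: DiseaseModel,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Bernoulli affection status: affected with the model penetrance."""
    rng = np.random.default_rng(seed)
    pen = penetrance(model, genotypes)
    return (rng.random(genotypes.n_individuals) < pen).astype(np.int8)
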
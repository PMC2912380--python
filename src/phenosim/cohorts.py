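"""Cohort construction: pooled case-control samples and ascertained sibships.

The study design pools 50 independently sampled datasets of 200 cases and
200 controls (20,000 individuals per phenocopy level), and, for pedigrees,
50 replicates of three nuclear-family configurations (25 families each of:
1 affected + 2 unaffected sibs; 3 affected + 1 unaffected; 2 affected +
2 unaffected + 3 unconstrained extra sibs), i.e. 25,000 individuals.

Sampling is by rejection against the disease model. For sibships, children
are drawn one batch at a time given the parents and slotted into the
required affected/unaffected pattern; because sibs are i.i.d. given parents,
conditioning each child independently on its status yields the correct
ascertained joint distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .disease import DiseaseModel, penetrance
from .genosim import (
    GenotypeMatrix,
    HaplotypePool,
    MarkerInfo,
    ParameterError,
)

MAX_DRAWS = 10**6  # rejection-sampling guard per quota


class SamplingError(RuntimeError):
    """A rejection-sampling quota could not be met within the draw budget."""


@dataclass
class CaseControlDataset:
    """Genotypes + affection status + phenocopy provenance."""

    genotypes: GenotypeMatrix
    status: np.ndarray  # (N,) int8, 1 = affected
    phenocopy: np.ndarray  # (N,) object, "" | "PM1" | "PM2:<model id>"
    replicate_id: np.ndarray  # (N,) int

    def __post_init__(self) -> None:
        n = self.genotypes.n_individuals
        if not (len(self.status) == len(self.phenocopy) == len(self.replicate_id) == n):
            raise ParameterError("per-individual arrays must match genotype rows")
        if np.any((self.status != 0) & (self.status != 1)):
            raise ParameterError("status must be 0/1")
        if np.any((self.status == 0) & (self.phenocopy != "")):
            raise ParameterError("controls cannot carry phenocopy flags")

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    @property
    def n_controls(self) -> int:
        return int(len(self.status) - self.status.sum())

    def copy(self) -> "CaseControlDataset":
        g = self.genotypes
        return CaseControlDataset(
            genotypes=GenotypeMatrix(
                g.genotypes.copy(), list(g.markers), list(g.individual_ids)
            ),
            status=self.status.copy(),
            phenocopy=self.phenocopy.copy(),
            replicate_id=self.replicate_id.copy(),
        )


@dataclass
class ChildRecord:
    """A sib with its transmission record (which parental haplotype came down)."""

    status: int
    t_father: int
    t_mother: int
    role: str  # "affected" | "unaffected" | "extra" (ascertainment role)
    phenocopy: bool = False


@dataclass
class FamilyRecord:
    """Nuclear family: parental haplotypes and the children's records."""

    family_id: str
    config_label: str
    father_haps: np.ndarray  # (2, M) int8
    mother_haps: np.ndarray  # (2, M) int8
    children: list[ChildRecord]

    @property
    def father_genotype(self) -> np.ndarray:
        return (self.father_haps[0] + self.father_haps[1]).astype(np.int8)

    @property
    def mother_genotype(self) -> np.ndarray:
        return (self.mother_haps[0] + self.mother_haps[1]).astype(np.int8)

    def child_genotype(self, i: int) -> np.ndarray:
        c = self.children[i]
        return (self.father_haps[c.t_father] + self.mother_haps[c.t_mother]).astype(
            np.int8
        )

    @property
    def size(self) -> int:
        return 2 + len(self.children)

    def affected_children(self) -> list[int]:
        return [i for i, c in enumerate(self.children) if c.status == 1]

    def unaffected_children(self) -> list[int]:
        return [i for i, c in enumerate(self.children) if c.status == 0]


@dataclass
class PedigreeDataset:
    families: list[FamilyRecord]
    markers: list[MarkerInfo]

    @property
    def n_individuals(self) -> int:
        return sum(f.size for f in self.families)

    def copy(self) -> "PedigreeDataset":
        fams = [
            replace(
                f,
                father_haps=f.father_haps.copy(),
                mother_haps=f.mother_haps.copy(),
                children=[replace(c) for c in f.children],
            )
            for f in self.families
        ]
        return PedigreeDataset(families=fams, markers=list(self.markers))


@dataclass
class PoolSpec:
    """Pooled case-control sampling design."""

    n_replicates: int = 50
    cases_per_replicate: int = 200
    controls_per_replicate: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_replicates, self.cases_per_replicate, self.controls_per_replicate) < 1:
            raise ParameterError("pool counts must be >= 1")


def sample_case_control(
    pool: HaplotypePool,
    model: DiseaseModel,
    n_cases: int,
    n_controls: int,
    seed: int | np.random.SeedSequence = 0,
    max_draws: int = MAX_DRAWS,
    replicate_id: int = 0,
    id_prefix: str = "cc",
) -> CaseControlDataset:
    """Rejection-sample individuals until the case and control quotas are met."""
    if n_cases < 0 or n_controls < 0:
        raise ParameterError("quotas must be non-negative")
    rng = np.random.default_rng(seed)
    markers = pool.markers
    case_rows: list[np.ndarray] = []
    ctrl_rows: list[np.ndarray] = []
    got_cases = got_controls = drawn = 0
    batch = max(64, min(8192, 4 * (n_cases + n_controls)))
    while got_cases < n_cases or got_controls < n_controls:
        if drawn >= max_draws:
            raise SamplingError(
                f"case-control quota unreachable after {drawn} draws "
                f"({got_cases}/{n_cases} cases, {got_controls}/{n_controls} controls)"
            )
        b = min(batch, max_draws - drawn)
        h1 = pool.sample_haplotypes(b, rng)
        h2 = pool.sample_haplotypes(b, rng)
        g = (h1 + h2).astype(np.int8)
        drawn += b
        pen = penetrance(model, g, markers)
        affected = rng.random(b) < pen
        if got_cases < n_cases:
            take = g[affected][: n_cases - got_cases]
            case_rows.append(take)
            got_cases += len(take)
        if got_controls < n_controls:
            take = g[~affected][: n_controls - got_controls]
            ctrl_rows.append(take)
            got_controls += len(take)
    g_all = np.vstack(
        [r for r in case_rows + ctrl_rows if len(r)]
        or [np.empty((0, pool.n_markers), dtype=np.int8)]
    )
    status = np.r_[np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)]
    ids = [f"{id_prefix}{replicate_id}_{i}" for i in range(n_cases + n_controls)]
    gm = GenotypeMatrix(genotypes=g_all, markers=list(markers), individual_ids=ids)
    return CaseControlDataset(
        genotypes=gm,
        status=status,
        phenocopy=np.full(n_cases + n_controls, "", dtype=object),
        replicate_id=np.full(n_cases + n_controls, replicate_id, dtype=int),
    )


def build_cc_pool(
    pool: HaplotypePool, model: DiseaseModel, spec: PoolSpec
) -> CaseControlDataset:
    """Pool ``n_replicates`` independent case-control samples into one dataset."""
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_replicates)
    parts = [
        sample_case_control(
            pool,
            model,
            spec.cases_per_replicate,
            spec.controls_per_replicate,
            seed=children[r],
            replicate_id=r,
        )
        for r in range(spec.n_replicates)
    ]
    g = np.vstack([p.genotypes.genotypes for p in parts])
    ids = [iid for p in parts for iid in p.genotypes.individual_ids]
    return CaseControlDataset(
        genotypes=GenotypeMatrix(g, list(pool.markers), ids),
        status=np.concatenate([p.status for p in parts]),
        phenocopy=np.concatenate([p.phenocopy for p in parts]),
        replicate_id=np.concatenate([p.replicate_id for p in parts]),
    )


def sample_family(
    pool: HaplotypePool,
    model: DiseaseModel,
    n_affected_sibs: int,
    n_unaffected_sibs: int,
    n_random_sibs: int,
    rng: np.random.Generator,
    family_id: str = "fam0",
    config_label: str | None = None,
    max_draws: int = MAX_DRAWS,
    max_child_draws_per_parents: int = 4096,
) -> FamilyRecord:
    """Ascertain one nuclear family matching the required sibling pattern.

    Constrained sibs are filled by rejection on their simulated status; the
    "random extra" sibs keep whatever status the model assigns. Parental
    affection status is treated as unknown throughout (the TDT only uses
    transmissions). Parents are redrawn if their offspring distribution makes
    a slot too rare to fill.
    """
    if min(n_affected_sibs, n_unaffected_sibs, n_random_sibs) < 0:
        raise ParameterError("sib counts must be non-negative")
    if config_label is None:
        config_label = f"{n_affected_sibs}aff_{n_unaffected_sibs}unaff_{n_random_sibs}extra"
    markers = pool.markers
    total_drawn = 0
    while True:
        fh = pool.sample_haplotypes(2, rng)
        mh = pool.sample_haplotypes(2, rng)
        children: list[ChildRecord] = []
        need_aff, need_unaff, need_extra = (
            n_affected_sibs,
            n_unaffected_sibs,
            n_random_sibs,
        )
        drawn_here = 0
        while (need_aff or need_unaff or need_extra) and (
            drawn_here < max_child_draws_per_parents
        ):
            if total_drawn >= max_draws:
                raise SamplingError(
                    f"family ascertainment unreachable after {total_drawn} child draws"
                )
            b = 16
            t = rng.integers(0, 2, size=(b, 2))
            g = (fh[t[:, 0]] + mh[t[:, 1]]).astype(np.int8)
            pen = penetrance(model, g, markers)
            aff = rng.random(b) < pen
            drawn_here += b
            total_drawn += b
            for i in range(b):
                if need_extra:
                    children.append(
                        ChildRecord(int(aff[i]), int(t[i, 0]), int(t[i, 1]), "extra")
                    )
                    need_extra -= 1
                elif aff[i] and need_aff:
                    children.append(
                        ChildRecord(1, int(t[i, 0]), int(t[i, 1]), "affected")
                    )
                    need_aff -= 1
                elif not aff[i] and need_unaff:
                    children.append(
                        ChildRecord(0, int(t[i, 0]), int(t[i, 1]), "unaffected")
                    )
                    need_unaff -= 1
                if not (need_aff or need_unaff or need_extra):
                    break
        if not (need_aff or need_unaff or need_extra):
            return FamilyRecord(
                family_id=family_id,
                config_label=config_label,
                father_haps=fh,
                mother_haps=mh,
                children=children,
            )
        # unlucky parents (e.g. penetrance ~0 for all their offspring): redraw


FAMILY_CONFIGS: tuple[tuple[int, int, int], ...] = ((1, 2, 0), (3, 1, 0), (2, 2, 3))


def build_pedigree_pool(
    pool: HaplotypePool,
    model: DiseaseModel,
    n_replicates: int = 50,
    families_per_config: int = 25,
    configs: tuple[tuple[int, int, int], ...] = FAMILY_CONFIGS,
    seed: int = 0,
) -> PedigreeDataset:
    """Pool replicates of the three family configurations (default: 25 each of
    5-, 6- and 9-person families per replicate; 50 replicates = 25,000
    individuals)."""
    ss = np.random.SeedSequence(seed)
    fams: list[FamilyRecord] = []
    for r, child_ss in enumerate(ss.spawn(n_replicates)):
        rng = np.random.default_rng(child_ss)
        for ci, (na, nu, nx) in enumerate(configs):
            for f in range(families_per_config):
                fams.append(
                    sample_family(
                        pool,
                        model,
                        na,
                        nu,
                        nx,
                        rng,
                        family_id=f"rep{r}_cfg{ci}_fam{f}",
                    )
                )
    return PedigreeDataset(families=fams, markers=list(pool.markers))
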
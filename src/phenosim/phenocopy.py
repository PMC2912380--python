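"""Phenocopy injection.

Two mechanisms turn a fraction of cases into phenocopies — affected
individuals whose disease does not arise from the modelled loci:

* **PM1** (control relabeling): replace cases with individuals drawn from
  the unaffected population and mark them affected. Phenocopies then carry
  no association signal anywhere.
* **PM2** (alternative-determinant substitution): replace cases with
  affected individuals generated under one of five alternative disease
  models with disjoint causal loci, chosen uniformly. Phenocopies carry real
  signal — at the *wrong* loci.

For pedigrees only PM1 applies: in selected families one unaffected sib is
relabeled affected (the phenocopy) and one affected sib relabeled
unaffected, preserving the family's designed affected/unaffected pattern.

Selection of which cases to replace uses a permutation prefix, and PM2
phenocopies get per-slot child seeds, so with a fixed seed the replaced set
at a lower level is nested inside the set at a higher level (common random
numbers across the phenocopy ladder).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cohorts import (
    CaseControlDataset,
    PedigreeDataset,
    sample_case_control,
)
from .disease import DiseaseModel, model_loci
from .genosim import GenotypeMatrix, HaplotypePool, ParameterError

STANDARD_LEVELS: tuple[float, ...] = (0.0, 0.05, 0.10, 0.20, 0.30, 0.45)


class InjectionError(RuntimeError):
    """The requested phenocopy level cannot be realised on this dataset."""


def round_half_away(x: float) -> int:
    """Round half away from zero (0.5 -> 1), the declared rounding rule."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class PhenocopySpec:
    """How to inject phenocopies: method, level and (PM2) alternative models."""

    method: str  # "PM1" | "PM2"
    level: float
    alt_models: list[DiseaseModel] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("PM1", "PM2"):
            raise ParameterError(f"unknown phenocopy method {self.method!r}")
        if not 0.0 <= self.level < 1.0:
            raise ParameterError("level must be in [0, 1)")
        if self.method == "PM2" and not self.alt_models:
            raise ParameterError("PM2 requires at least one alternative model")


def check_disjoint_loci(main_model: DiseaseModel, alt_models: list[DiseaseModel]) -> None:
    """PM2 precondition: alternative causal loci disjoint from the main model's."""
    main = set(model_loci(main_model))
    for k, alt in enumerate(alt_models):
        overlap = main & set(model_loci(alt))
        if overlap:
            raise ParameterError(
                f"alternative model {k} shares causal loci with the main model: "
                f"{sorted(overlap)}"
            )


def pm1_case_control(
    ds: CaseControlDataset,
    full_population_controls: GenotypeMatrix,
    level: float,
    seed: int = 0,
) -> CaseControlDataset:
    """Replace round(level * n_cases) cases with relabeled population controls.

    The reservoir should be freshly drawn unaffected individuals; its rows
    are consumed by permutation prefix (no duplicates). Controls and the
    case count are untouched; level 0 is a strict no-op.
    """
    if not 0.0 <= level < 1.0:
        raise ParameterError("level must be in [0, 1)")
    out = ds.copy()
    k = round_half_away(level * ds.n_cases)
    if k == 0:
        return out
    if full_population_controls.n_markers != ds.genotypes.n_markers:
        raise ParameterError("reservoir marker map does not match the dataset")
    if full_population_controls.n_individuals < k:
        raise InjectionError(
            f"reservoir has {full_population_controls.n_individuals} controls, "
            f"need {k}"
        )
    rng = np.random.default_rng(seed)
    case_idx = np.flatnonzero(ds.status == 1)
    sel = case_idx[rng.permutation(len(case_idx))[:k]]
    res = rng.permutation(full_population_controls.n_individuals)[:k]
    out.genotypes.genotypes[sel] = full_population_controls.genotypes[res]
    out.phenocopy[sel] = "PM1"
    return out


def pm2_case_control(
    ds: CaseControlDataset,
    spec: PhenocopySpec,
    pool: HaplotypePool,
    main_model: DiseaseModel | None = None,
) -> CaseControlDataset:
    """Substitute cases with affected individuals from alternative models.

    Each of the round(level * n_cases) substitution slots picks an
    alternative model uniformly, generates one affected individual under it
    (rejection sampling against the same haplotype pool) and overwrites a
    distinct original case. Flags record the source model index.
    """
    if spec.method != "PM2":
        raise ParameterError("spec.method must be PM2")
    if main_model is not None:
        check_disjoint_loci(main_model, spec.alt_models)
    out = ds.copy()
    k = round_half_away(spec.level * ds.n_cases)
    if k == 0:
        return out
    rng = np.random.default_rng(spec.seed)
    case_idx = np.flatnonzero(ds.status == 1)
    sel = case_idx[rng.permutation(len(case_idx))[:k]]
    # full-length assignment vector so lower levels use a prefix of the same choices
    alt_choice = rng.integers(len(spec.alt_models), size=len(case_idx))[:k]
    for slot in range(k):
        alt = spec.alt_models[int(alt_choice[slot])]
        child = np.random.SeedSequence([int(spec.seed), slot])
        rep = sample_case_control(pool, alt, 1, 0, seed=child)
        out.genotypes.genotypes[sel[slot]] = rep.genotypes.genotypes[0]
        out.phenocopy[sel[slot]] = f"PM2:{int(alt_choice[slot]):02d}"
    return out


def pm1_pedigree(
    ds: PedigreeDataset, level: float, seed: int = 0
) -> PedigreeDataset:
    """Swap affected/unaffected labels within families to create phenocopies.

    k = round(level * total affected sibs) swaps are performed. A swap picks
    a family with spare capacity, relabels one constrained unaffected sib as
    affected (flagged as the phenocopy) and one constrained affected sib as
    unaffected, so every family's designed affected/unaffected counts are
    preserved. Swap slots are consumed by permutation prefix for nesting
    across levels.
    """
    if not 0.0 <= level < 1.0:
        raise ParameterError("level must be in [0, 1)")
    out = ds.copy()
    total_affected = sum(len(f.affected_children()) for f in ds.families)
    k = round_half_away(level * total_affected)
    if k == 0:
        return out
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    # capacity: constrained (designed) sibs only, so the ascertainment pattern
    # among designed sibs is preserved exactly
    slots: list[tuple[int, int]] = []  # (family index, slot number within family)
    for fi, fam in enumerate(ds.families):
        n_aff = sum(1 for c in fam.children if c.role == "affected")
        n_unaff = sum(1 for c in fam.children if c.role == "unaffected")
        for s in range(min(n_aff, n_unaff)):
            slots.append((fi, s))
    if k > len(slots):
        raise InjectionError(
            f"level {level} needs {k} swaps but only {len(slots)} are feasible"
        )
    order = rng.permutation(len(slots))[:k]
    per_family: dict[int, int] = {}
    for oi in order:
        fi, _ = slots[oi]
        per_family[fi] = per_family.get(fi, 0) + 1
    for fi, n_swaps in per_family.items():
        fam = out.families[fi]
        fam_rng = np.random.default_rng(np.random.SeedSequence([int(seed), fi]))
        aff = [i for i, c in enumerate(fam.children) if c.role == "affected"]
        unaff = [i for i, c in enumerate(fam.children) if c.role == "unaffected"]
        aff = [aff[j] for j in fam_rng.permutation(len(aff))]
        unaff = [unaff[j] for j in fam_rng.permutation(len(unaff))]
        for s in range(n_swaps):
            fam.children[aff[s]].status = 0
            fam.children[unaff[s]].status = 1
            fam.children[unaff[s]].phenocopy = True
    return out


def inject(
    ds: CaseControlDataset | PedigreeDataset,
    spec: PhenocopySpec,
    pool: HaplotypePool | None = None,
    reservoir: GenotypeMatrix | None = None,
    main_model: DiseaseModel | None = None,
):
    """Dispatch the right injection routine for the dataset/method pair."""
    if isinstance(ds, PedigreeDataset):
        if spec.method != "PM1":
            raise ParameterError("only PM1 applies to pedigree datasets")
        return pm1_pedigree(ds, spec.level, spec.seed)
    if spec.method == "PM1":
        if reservoir is None:
            raise ParameterError("PM1 needs a population-control reservoir")
        return pm1_case_control(ds, reservoir, spec.level, spec.seed)
    if pool is None:
        raise ParameterError("PM2 needs the haplotype pool")
    return pm2_case_control(ds, spec, pool, main_model)
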
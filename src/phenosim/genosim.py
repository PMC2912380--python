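"""Block-LD genotype simulation.

Generates a synthetic chromosome of biallelic markers organised in linkage
blocks, builds a haplotype pool with first-order (AR(1)) correlation inside
each block and independence across blocks, and samples unrelated genotypes
and parent-offspring trios from it.

Genotypes are coded as minor-allele dosage (0/1/2) throughout. Marker labels
follow the ``RL0-<index>`` convention so that positions quoted for the two
study chromosomes (1,362 and 401 markers) resolve to real markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm


class ParameterError(ValueError):
    """Invalid simulation parameter."""


@dataclass(frozen=True)
class MarkerInfo:
    """A biallelic marker on the synthetic chromosome."""

    id: str
    index: int
    maf: float
    block_id: int

    def __post_init__(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise ParameterError(f"maf must be in (0, 0.5], got {self.maf}")


@dataclass
class HaplotypePool:
    """Pool of haplotypes sampled block-wise.

    ``haplotypes`` is an H x M minor-allele indicator matrix. A sampled
    haplotype is assembled by drawing, independently for every block, one pool
    row according to that block's weights; this makes blocks exactly
    independent while preserving the within-block allelic correlation laid
    down at pool construction.
    """

    haplotypes: np.ndarray  # (H, M) int8
    markers: list[MarkerInfo]
    block_bounds: np.ndarray  # (n_blocks + 1,) marker index boundaries
    weights: np.ndarray  # (n_blocks, H), each row sums to 1
    _cum_weights: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.haplotypes.shape[0] < 2:
            raise ParameterError("pool must contain at least 2 haplotypes")
        if not np.allclose(self.weights.sum(axis=1), 1.0):
            raise ParameterError("weights must sum to 1 within each block")
        if np.any(self.weights < 0):
            raise ParameterError("weights must be non-negative")
        object.__setattr__(self, "_cum_weights", np.cumsum(self.weights, axis=1))

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def n_blocks(self) -> int:
        return len(self.block_bounds) - 1

    def empirical_maf(self) -> np.ndarray:
        """Weighted minor-allele frequency of each marker in the pool."""
        freqs = np.empty(self.n_markers)
        for b in range(self.n_blocks):
            s, e = self.block_bounds[b], self.block_bounds[b + 1]
            freqs[s:e] = self.weights[b] @ self.haplotypes[:, s:e]
        return freqs

    def sample_haplotypes(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` haplotypes (n x M int8), blocks independent."""
        out = np.empty((n, self.n_markers), dtype=np.int8)
        for b in range(self.n_blocks):
            s, e = self.block_bounds[b], self.block_bounds[b + 1]
            rows = np.searchsorted(self._cum_weights[b], rng.random(n))
            out[:, s:e] = self.haplotypes[rows, s:e]
        return out


@dataclass
class GenotypeMatrix:
    """N x M minor-allele dosage matrix with marker metadata."""

    genotypes: np.ndarray  # (N, M) int8, values in {0, 1, 2}
    markers: list[MarkerInfo]
    individual_ids: list[str]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        g = self.genotypes
        if g.ndim != 2 or g.shape[1] != len(self.markers):
            raise ParameterError("genotype matrix does not match marker map")
        if g.size and (g.min() < 0 or g.max() > 2):
            raise ParameterError("genotype dosages must be in {0, 1, 2}")
        if len(self.individual_ids) != g.shape[0]:
            raise ParameterError("individual_ids length mismatch")
        self._index = {m.id: m.index for m in self.markers}

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def marker_index(self, marker_id: str) -> int:
        try:
            return self._index[marker_id]
        except KeyError:
            raise KeyError(f"marker {marker_id!r} not on this chromosome") from None

    def marker_ids(self) -> list[str]:
        return [m.id for m in self.markers]


@dataclass
class TrioRecord:
    """Parent genotypes plus the transmission bookkeeping a TDT needs.

    ``t_father``/``t_mother`` index which of each parent's two haplotypes was
    transmitted to the child; the untransmitted one is the complementary row.
    """

    father_haps: np.ndarray  # (2, M) int8
    mother_haps: np.ndarray  # (2, M) int8
    t_father: int
    t_mother: int

    @property
    def father_genotype(self) -> np.ndarray:
        return (self.father_haps[0] + self.father_haps[1]).astype(np.int8)

    @property
    def mother_genotype(self) -> np.ndarray:
        return (self.mother_haps[0] + self.mother_haps[1]).astype(np.int8)

    @property
    def child_genotype(self) -> np.ndarray:
        return (
            self.father_haps[self.t_father] + self.mother_haps[self.t_mother]
        ).astype(np.int8)


def build_marker_map(
    n_markers: int,
    block_size_range: tuple[int, int] = (5, 15),
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    maf_overrides: dict[int, float] | None = None,
) -> list[MarkerInfo]:
    """Lay out ``n_markers`` markers partitioned into contiguous LD blocks.

    Block sizes are drawn uniformly from ``block_size_range`` (the last block
    is truncated to fit); MAFs are drawn uniformly from ``maf_range``.
    ``maf_overrides`` maps marker index -> MAF, used to pin disease loci to a
    chosen frequency. Deterministic for a fixed seed.
    """
    if n_markers < 1:
        raise ParameterError("n_markers must be >= 1")
    lo, hi = block_size_range
    if not (1 <= lo <= hi):
        raise ParameterError(f"invalid block_size_range {block_size_range}")
    flo, fhi = maf_range
    if not (0.0 < flo <= fhi <= 0.5):
        raise ParameterError(f"maf_range must lie within (0, 0.5], got {maf_range}")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(flo, fhi, size=n_markers)
    if maf_overrides:
        for idx, maf in maf_overrides.items():
            if not 0 <= idx < n_markers:
                raise ParameterError(f"maf override index {idx} out of range")
            mafs[idx] = maf
    markers: list[MarkerInfo] = []
    pos, block = 0, 0
    while pos < n_markers:
        size = min(int(rng.integers(lo, hi + 1)), n_markers - pos)
        for j in range(pos, pos + size):
            markers.append(
                MarkerInfo(id=f"RL0-{j}", index=j, maf=float(mafs[j]), block_id=block)
            )
        pos += size
        block += 1
    return markers


def with_causal_maf(
    markers: list[MarkerInfo],
    marker_ids: list[str],
    seed: int,
    maf_low: float = 0.30,
    maf_high: float = 0.45,
) -> list[MarkerInfo]:
    """Return a marker map with the given loci redrawn at common-variant MAF.

    Disease loci are pinned to MAF uniform in [maf_low, maf_high], honouring
    the common-variant condition (MAF > 0.30) while keeping the allele minor.
    """
    rng = np.random.default_rng(seed)
    wanted = {mid: float(rng.uniform(maf_low, maf_high)) for mid in sorted(marker_ids)}
    out = []
    for m in markers:
        out.append(replace(m, maf=wanted[m.id]) if m.id in wanted else m)
    if len(wanted) != len(marker_ids):
        raise ParameterError("duplicate causal marker ids")
    missing = set(marker_ids) - {m.id for m in markers}
    if missing:
        raise ParameterError(f"causal markers not on map: {sorted(missing)}")
    return out


def build_haplotype_pool(
    markers: list[MarkerInfo],
    ld_decay: float = 0.8,
    pool_size: int = 2000,
    seed: int = 0,
) -> HaplotypePool:
    """Build a haplotype pool with AR(1) within-block allelic correlation.

    A latent Gaussian chain x_j = r*x_{j-1} + sqrt(1-r^2)*eps runs along each
    block (r = ``ld_decay``) and is thresholded at the normal quantile of each
    marker's MAF, so pairwise r^2 decays with marker distance inside a block
    and is structurally zero across blocks. ``ld_decay=0`` gives independent
    markers; ``ld_decay=1`` with equal MAFs gives perfect LD.
    """
    if not 0.0 <= ld_decay <= 1.0:
        raise ParameterError("ld_decay must be in [0, 1]")
    if pool_size < 2:
        raise ParameterError("pool_size must be >= 2")
    rng = np.random.default_rng(seed)
    M = len(markers)
    block_ids = np.array([m.block_id for m in markers])
    bounds = np.flatnonzero(np.r_[True, block_ids[1:] != block_ids[:-1], True])
    mafs = np.array([m.maf for m in markers])
    thresholds = norm.ppf(mafs)
    haps = np.empty((pool_size, M), dtype=np.int8)
    innov_scale = np.sqrt(1.0 - ld_decay**2)
    for b in range(len(bounds) - 1):
        s, e = bounds[b], bounds[b + 1]
        x = rng.standard_normal((pool_size, e - s))
        for j in range(1, e - s):
            x[:, j] = ld_decay * x[:, j - 1] + innov_scale * x[:, j]
        haps[:, s:e] = x < thresholds[s:e]
    n_blocks = len(bounds) - 1
    weights = np.full((n_blocks, pool_size), 1.0 / pool_size)
    return HaplotypePool(
        haplotypes=haps, markers=list(markers), block_bounds=bounds, weights=weights
    )


def sample_genotypes(
    pool: HaplotypePool, n_individuals: int, seed: int | np.random.SeedSequence = 0
) -> GenotypeMatrix:
    """Sample unrelated individuals: two independent haplotype draws each.

    Because the two draws are independent and identically distributed, every
    marker is in Hardy-Weinberg proportions at the pool's allele frequency.
    """
    if n_individuals < 1:
        raise ParameterError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    g = sample_genotype_rows(pool, n_individuals, rng)
    ids = [f"ind{i}" for i in range(n_individuals)]
    return GenotypeMatrix(genotypes=g, markers=list(pool.markers), individual_ids=ids)


def sample_genotype_rows(
    pool: HaplotypePool, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Raw (n, M) dosage rows without the GenotypeMatrix wrapper."""
    h1 = pool.sample_haplotypes(n, rng)
    h2 = pool.sample_haplotypes(n, rng)
    return (h1 + h2).astype(np.int8)


def sample_trio(pool: HaplotypePool, rng: np.random.Generator) -> TrioRecord:
    """Sample a father/mother/child trio with the transmission record kept."""
    fh = pool.sample_haplotypes(2, rng)
    mh = pool.sample_haplotypes(2, rng)
    return TrioRecord(
        father_haps=fh,
        mother_haps=mh,
        t_father=int(rng.integers(2)),
        t_mother=int(rng.integers(2)),
    )


def pairwise_r2(genotypes: np.ndarray) -> np.ndarray:
    """Pairwise squared allelic correlation between marker dosage columns."""
    g = genotypes.astype(float)
    g = g - g.mean(axis=0)
    sd = g.std(axis=0)
    sd[sd == 0] = np.nan
    corr = (g.T @ g) / (len(g) * np.outer(sd, sd))
    return corr**2
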
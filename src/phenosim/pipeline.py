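"""Benchmark orchestration.

Runs the full experiment grid — two disease models (main-effect ME on a
1,362-marker chromosome; purely epistatic EPI on a 401-marker chromosome),
two phenocopy methods, six phenocopy levels, case-control and pedigree
designs — and collects per-cell association results plus a degradation
table (headline statistic, causal-marker rank, false-positive count per
grid cell).

Every stage gets an independent child seed spawned from the master seed, so
runs are reproducible end to end and stages can be re-created in isolation.
Injection uses one seed per (model, design, method), shared across levels,
which makes the phenocopy ladders nested (common random numbers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import io as psio
from .assoc import (
    logistic_interaction_test,
    marker_rank,
    single_point_scan,
    tdt_scan,
)
from .cohorts import (
    CaseControlDataset,
    PoolSpec,
    build_cc_pool,
    build_pedigree_pool,
    sample_case_control,
)
from .disease import (
    DiseaseModel,
    EpistaticSearchConfig,
    generate_epistatic_table,
    make_main_effect_model,
    make_single_snp_model,
    model_loci,
)
from .genosim import (
    GenotypeMatrix,
    HaplotypePool,
    MarkerInfo,
    ParameterError,
    build_haplotype_pool,
    build_marker_map,
    with_causal_maf,
)
from .mdr import MDRConfig, evaluate_combination
from .phenocopy import (
    STANDARD_LEVELS,
    PhenocopySpec,
    pm1_case_control,
    pm1_pedigree,
    pm2_case_control,
)

ME_CAUSAL = "RL0-855"
ME_AUX = ("RL0-75", "RL0-245", "RL0-457")
ME_ALT = ("RL0-179", "RL0-111", "RL0-210", "RL0-503", "RL0-995")
EPI_TRIPLE = ("RL0-75", "RL0-153", "RL0-272")
EPI_ALT_TRIPLES = (
    ("RL0-66", "RL0-155", "RL0-268"),
    ("RL0-123", "RL0-79", "RL0-337"),
    ("RL0-63", "RL0-125", "RL0-332"),
    ("RL0-66", "RL0-116", "RL0-292"),
    ("RL0-63", "RL0-120", "RL0-329"),
)


@dataclass
class BenchmarkConfig:
    """Resolved benchmark parameters (defaults = the full study design)."""

    models: tuple[str, ...] = ("ME", "EPI")
    designs: tuple[str, ...] = ("case_control", "pedigree")
    methods: tuple[str, ...] = ("PM1", "PM2")
    levels: tuple[float, ...] = STANDARD_LEVELS
    me_n_markers: int = 1362
    epi_n_markers: int = 401
    me_causal: str = ME_CAUSAL
    me_beta: float = 0.80
    me_aux: tuple[str, ...] = ME_AUX
    me_alt: tuple[str, ...] = ME_ALT
    epi_triple: tuple[str, str, str] = EPI_TRIPLE
    epi_alt_triples: tuple[tuple[str, str, str], ...] = EPI_ALT_TRIPLES
    target_or: float = 4.0
    prevalence: float = 0.10
    n_replicates: int = 50
    cases_per_replicate: int = 200
    controls_per_replicate: int = 200
    ped_replicates: int = 50
    families_per_config: int = 25
    pool_size: int = 2000
    ld_decay: float = 0.8
    block_size_range: tuple[int, int] = (5, 15)
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_maf_range: tuple[float, float] = (0.30, 0.45)
    ga: EpistaticSearchConfig = field(default_factory=EpistaticSearchConfig)
    run_mdr: bool = True
    fp_threshold: float | None = None  # None -> Bonferroni 0.05/M
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        lv = tuple(self.levels)
        if lv != tuple(sorted(lv)) or (lv and lv[0] != 0):
            raise ParameterError("levels must be sorted ascending and start at 0")

    @classmethod
    def toy(cls, seed: int = 0, out_dir: str | None = None) -> "BenchmarkConfig":
        """A CI-speed preset: tiny chromosome, two replicates, two levels."""
        return cls(
            models=("ME", "EPI"),
            designs=("case_control", "pedigree"),
            methods=("PM1", "PM2"),
            levels=(0.0, 0.45),
            me_n_markers=60,
            epi_n_markers=60,
            me_causal="RL0-20",
            me_aux=("RL0-5", "RL0-35", "RL0-50"),
            me_alt=("RL0-11", "RL0-28", "RL0-44"),
            epi_triple=("RL0-8", "RL0-25", "RL0-42"),
            epi_alt_triples=(("RL0-2", "RL0-31", "RL0-55"),),
            n_replicates=2,
            ped_replicates=2,
            families_per_config=10,
            pool_size=400,
            ga=EpistaticSearchConfig(generations=400, population_size=160),
            seed=seed,
            out_dir=out_dir,
        )

    @classmethod
    def from_yaml(cls, path) -> "BenchmarkConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        ga = EpistaticSearchConfig(**raw.pop("ga", {}))
        for key in (
            "models", "designs", "methods", "levels", "me_aux", "me_alt",
            "block_size_range", "maf_range", "causal_maf_range",
        ):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "epi_triple" in raw:
            raw["epi_triple"] = tuple(raw["epi_triple"])
        if "epi_alt_triples" in raw:
            raw["epi_alt_triples"] = tuple(tuple(t) for t in raw["epi_alt_triples"])
        return cls(ga=ga, **raw)


@dataclass
class Experiment:
    """One disease model's simulated world."""

    model_name: str
    markers: list[MarkerInfo]
    pool: HaplotypePool
    main_model: DiseaseModel
    alt_models: list[DiseaseModel]
    causal_ids: tuple[str, ...]


def _stage_seed(master: int, *tags: str) -> np.random.SeedSequence:
    """Deterministic named child seed (tags hashed to small integers)."""
    ints = [master % (2**31)]
    for tag in tags:
        ints.append(sum((i + 1) * b for i, b in enumerate(tag.encode())) % (2**31))
    return np.random.SeedSequence(ints)


def _stage_int(master: int, *tags: str) -> int:
    return int(_stage_seed(master, *tags).generate_state(1)[0] % (2**31))


def build_experiment(model_name: str, cfg: BenchmarkConfig) -> Experiment:
    """Build markers, haplotype pool and disease models for one study arm."""
    if model_name == "ME":
        n_markers = cfg.me_n_markers
        causal_ids = (cfg.me_causal, *cfg.me_aux, *cfg.me_alt)
    elif model_name == "EPI":
        n_markers = cfg.epi_n_markers
        causal_ids = tuple(
            dict.fromkeys(
                list(cfg.epi_triple) + [m for t in cfg.epi_alt_triples for m in t]
            )
        )
    else:
        raise ParameterError(f"unknown model {model_name!r}")
    markers = build_marker_map(
        n_markers,
        block_size_range=cfg.block_size_range,
        maf_range=cfg.maf_range,
        seed=_stage_int(cfg.seed, model_name, "map"),
    )
    markers = with_causal_maf(
        markers,
        list(causal_ids),
        seed=_stage_int(cfg.seed, model_name, "causal_maf"),
        maf_low=cfg.causal_maf_range[0],
        maf_high=cfg.causal_maf_range[1],
    )
    pool = build_haplotype_pool(
        markers,
        ld_decay=cfg.ld_decay,
        pool_size=cfg.pool_size,
        seed=_stage_int(cfg.seed, model_name, "pool"),
    )
    if model_name == "ME":
        main_model: DiseaseModel = make_main_effect_model(
            markers,
            causal=cfg.me_causal,
            beta=cfg.me_beta,
            aux_loci=cfg.me_aux,
            prevalence=cfg.prevalence,
        )
        alt_models: list[DiseaseModel] = [
            make_single_snp_model(markers, mid, beta=cfg.me_beta, prevalence=cfg.prevalence)
            for mid in cfg.me_alt
        ]
    else:
        maf_of = {m.id: m.maf for m in markers}
        main_model = generate_epistatic_table(
            replace(
                cfg.ga,
                target_or=cfg.target_or,
                maf=tuple(maf_of[mid] for mid in cfg.epi_triple),
                seed=_stage_int(cfg.seed, model_name, "ga_main"),
            ),
            loci=cfg.epi_triple,
        )
        alt_models = [
            generate_epistatic_table(
                replace(
                    cfg.ga,
                    target_or=cfg.target_or,
                    maf=tuple(maf_of[mid] for mid in triple),
                    seed=_stage_int(cfg.seed, model_name, f"ga_alt{k}"),
                ),
                loci=triple,
            )
            for k, triple in enumerate(cfg.epi_alt_triples)
        ]
    return Experiment(
        model_name=model_name,
        markers=markers,
        pool=pool,
        main_model=main_model,
        alt_models=alt_models,
        causal_ids=causal_ids,
    )


def draw_control_reservoir(
    exp: Experiment, n: int, cfg: BenchmarkConfig
) -> GenotypeMatrix:
    """Freshly drawn unaffected individuals for PM1 replacement."""
    ds = sample_case_control(
        exp.pool,
        exp.main_model,
        0,
        n,
        seed=_stage_seed(cfg.seed, exp.model_name, "reservoir"),
        id_prefix="res",
    )
    return ds.genotypes


def inject_cc(
    exp: Experiment,
    base: CaseControlDataset,
    reservoir: GenotypeMatrix,
    method: str,
    level: float,
    cfg: BenchmarkConfig,
) -> CaseControlDataset:
    seed = _stage_int(cfg.seed, exp.model_name, "cc_inject", method)
    if method == "PM1":
        return pm1_case_control(base, reservoir, level, seed=seed)
    spec = PhenocopySpec(
        method="PM2", level=level, alt_models=exp.alt_models, seed=seed
    )
    return pm2_case_control(base, spec, exp.pool, main_model=exp.main_model)


def summarize_false_positives(
    results: pd.DataFrame,
    threshold: float,
    causal_markers: tuple[str, ...] = (),
    markers: list[MarkerInfo] | None = None,
    p_column: str = "p_allelic",
) -> int:
    """Count non-causal markers with p below threshold.

    If marker metadata is given, whole LD blocks containing causal loci are
    excluded as well, since their signal is real (carried by LD), not false.
    """
    if not 0.0 < threshold <= 1.0:
        raise ParameterError("threshold must be in (0, 1]")
    excluded = set(causal_markers)
    if markers is not None:
        causal_blocks = {m.block_id for m in markers if m.id in excluded}
        excluded |= {m.id for m in markers if m.block_id in causal_blocks}
    mask = ~results["marker"].isin(excluded)
    pvals = results.loc[mask, p_column]
    # threshold 1.0 means "count every non-causal marker" (p is in (0, 1])
    return int((pvals <= threshold).sum() if threshold >= 1.0 else (pvals < threshold).sum())


def _grid_row(**kw) -> dict:
    base = {
        "model": None,
        "design": None,
        "method": None,
        "level": None,
        "analysis": None,
        "statistic_name": None,
        "statistic": np.nan,
        "causal_marker": None,
        "causal_rank": np.nan,
        "n_false_positives": np.nan,
    }
    base.update(kw)
    return base


def run_benchmark(cfg: BenchmarkConfig) -> pd.DataFrame:
    """Execute the grid; returns the degradation table.

    When ``cfg.out_dir`` is set, per-cell association tables, PED/MAP files
    of the level-0 datasets, the degradation table and a manifest of all
    resolved parameters are written there; cells whose result files already
    exist are loaded instead of recomputed (cheap resume).
    """
    out = psio.ensure_dir(cfg.out_dir) if cfg.out_dir else None
    rows: list[dict] = []
    for model_name in cfg.models:
        exp = build_experiment(model_name, cfg)
        fp_thresh = cfg.fp_threshold or 0.05 / len(exp.markers)
        causal_main = (
            (cfg.me_causal, *cfg.me_aux)
            if model_name == "ME"
            else tuple(cfg.epi_triple)
        )
        alt_loci = tuple(
            mid for m in exp.alt_models for mid in model_loci(m)
        )
        if "case_control" in cfg.designs:
            base = build_cc_pool(
                exp.pool,
                exp.main_model,
                PoolSpec(
                    n_replicates=cfg.n_replicates,
                    cases_per_replicate=cfg.cases_per_replicate,
                    controls_per_replicate=cfg.controls_per_replicate,
                    seed=_stage_int(cfg.seed, model_name, "cc_base"),
                ),
            )
            reservoir = draw_control_reservoir(
                exp, math.ceil(max(cfg.levels) * base.n_cases) + 1, cfg
            )
            if out:
                psio.write_map(exp.markers, out / f"{model_name}.map")
                psio.write_ped_case_control(base, out / f"{model_name}_cc_level0.ped")
            for method in cfg.methods:
                for level in cfg.levels:
                    cell = f"{model_name}_cc_{method}_{int(round(level * 100))}"
                    cell_path = out / f"{cell}.assoc.tsv" if out else None
                    if cell_path is not None and cell_path.exists():
                        scan = psio.read_results_table(cell_path)
                        ds = None
                    else:
                        ds = inject_cc(exp, base, reservoir, method, level, cfg)
                        scan = single_point_scan(ds)
                        if cell_path is not None:
                            psio.write_results_table(scan, cell_path)
                    exclude = causal_main + (alt_loci if method == "PM2" else ())
                    best = min(
                        ((marker_rank(scan, mid), mid) for mid in causal_main)
                    )
                    stat = float(
                        scan.loc[scan["marker"] == best[1], "neg_log10_p"].iloc[0]
                    )
                    rows.append(
                        _grid_row(
                            model=model_name,
                            design="case_control",
                            method=method,
                            level=level,
                            analysis="single_point",
                            statistic_name="neg_log10_p",
                            statistic=stat,
                            causal_marker=best[1],
                            causal_rank=best[0],
                            n_false_positives=summarize_false_positives(
                                scan, fp_thresh, exclude, exp.markers
                            ),
                        )
                    )
                    if model_name == "EPI" and ds is not None:
                        inter = logistic_interaction_test(ds, cfg.epi_triple)
                        rows.append(
                            _grid_row(
                                model=model_name,
                                design="case_control",
                                method=method,
                                level=level,
                                analysis="logistic_interaction",
                                statistic_name="neg_log10_p",
                                statistic=float(-np.log10(max(inter.p_value, 1e-320)))
                                if np.isfinite(inter.p_value)
                                else np.nan,
                                causal_marker="x".join(cfg.epi_triple),
                            )
                        )
                        if cfg.run_mdr:
                            res = evaluate_combination(
                                ds,
                                cfg.epi_triple,
                                MDRConfig(
                                    seed=_stage_int(cfg.seed, model_name, "mdr", method)
                                ),
                            )
                            for name, value in (
                                ("testing_or", res.odds_ratio),
                                ("testing_accuracy", res.testing_accuracy),
                            ):
                                rows.append(
                                    _grid_row(
                                        model=model_name,
                                        design="case_control",
                                        method=method,
                                        level=level,
                                        analysis="mdr_forced",
                                        statistic_name=name,
                                        statistic=float(value),
                                        causal_marker="x".join(cfg.epi_triple),
                                    )
                                )
        if "pedigree" in cfg.designs:
            ped_base = build_pedigree_pool(
                exp.pool,
                exp.main_model,
                n_replicates=cfg.ped_replicates,
                families_per_config=cfg.families_per_config,
                seed=_stage_int(cfg.seed, model_name, "ped_base"),
            )
            if out:
                psio.write_ped_pedigree(ped_base, out / f"{model_name}_ped_level0.ped")
            for level in cfg.levels:
                cell = f"{model_name}_ped_PM1_{int(round(level * 100))}"
                cell_path = out / f"{cell}.tdt.tsv" if out else None
                if cell_path is not None and cell_path.exists():
                    scan = psio.read_results_table(cell_path)
                else:
                    ped = pm1_pedigree(
                        ped_base,
                        level,
                        seed=_stage_int(cfg.seed, model_name, "ped_inject"),
                    )
                    scan = tdt_scan(ped)
                    if cell_path is not None:
                        psio.write_results_table(scan, cell_path)
                best = min(
                    ((marker_rank(scan, mid, "p_tdt"), mid) for mid in causal_main)
                )
                stat = float(scan.loc[scan["marker"] == best[1], "neg_log10_p"].iloc[0])
                rows.append(
                    _grid_row(
                        model=model_name,
                        design="pedigree",
                        method="PM1",
                        level=level,
                        analysis="tdt",
                        statistic_name="neg_log10_p",
                        statistic=stat,
                        causal_marker=best[1],
                        causal_rank=best[0],
                        n_false_positives=summarize_false_positives(
                            scan, fp_thresh, causal_main, exp.markers, p_column="p_tdt"
                        ),
                    )
                )
    table = pd.DataFrame(rows)
    if out:
        psio.write_results_table(table, out / "degradation.tsv")
        manifest = {
            f"config.{k}": v
            for k, v in vars(cfg).items()
            if k != "ga"
        }
        manifest.update({f"config.ga.{k}": v for k, v in vars(cfg.ga).items()})
        psio.write_manifest(manifest, out / "manifest.txt")
    return table
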
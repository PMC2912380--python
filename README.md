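# phenosim

A simulation benchmark for measuring how **phenocopies** — individuals
labeled affected whose disease does not arise from the genetic model under
study — degrade the standard analysis methods of genetic epidemiology:
single-point case-control association, the transmission disequilibrium test
(TDT), logistic regression on interaction terms, and multifactor
dimensionality reduction (MDR).

It is aimed at statistical geneticists planning association studies of
complex traits, where phenocopy fractions of 5–45% are plausible and the
question is which analyses stay informative as the fraction rises.

## What it simulates

Two disease architectures on a synthetic chromosome of biallelic markers
with block linkage-disequilibrium structure:

* **ME (main effect)** — a mixed logistic model on a 1,362-marker
  chromosome: one strong SNP (`RL0-855`) with per-allele odds ratio
  exp(β) = exp(0.80) = 2.2255, plus three SNPs with very small marginal
  effects and a three-way interaction. Penetrance is
  P(affected | g) = expit(α + Σ βᵢgᵢ + γ·g₁g₂g₃), with α anchored so the
  population prevalence is 10%.
* **EPI (purely epistatic)** — a three-locus 27-cell penetrance table on a
  401-marker chromosome (`RL0-75`/`RL0-153`/`RL0-272`) found by a genetic
  algorithm under the constraint that every single-locus marginal
  penetrance equals the prevalence (no main effects), calibrated to a
  target odds ratio of 4 for the high-penetrance genotype class versus the
  rest, under Hardy-Weinberg weights.

From each model it draws the study datasets — pooled case-control samples
(50 replicates of 200 cases + 200 controls = 20,000 individuals) and
ascertained nuclear families (50 replicates of 25 families each of three
sibship configurations = 25,000 individuals) — then injects phenocopies at
levels 0–45% by two mechanisms:

* **PM1**: cases replaced by relabeled population controls (phenocopies
  carry no genetic signal anywhere);
* **PM2**: cases replaced by affected individuals generated under five
  alternative disease models with disjoint causal loci (phenocopies carry
  real signal at the *wrong* loci).

## Worked example

Build the purely epistatic arm, pool a 4,000-individual case-control
dataset, and evaluate the causal triple with cross-validated MDR before and
after heavy phenocopy injection:

```python
from phenosim import BenchmarkConfig, build_experiment, build_cc_pool, PoolSpec
from phenosim.mdr import MDRConfig, evaluate_combination
from phenosim.phenocopy import PhenocopySpec, pm2_case_control

cfg = BenchmarkConfig(seed=7)
exp = build_experiment("EPI", cfg)
print(f"penetrance table: achieved OR = {exp.main_model.achieved_or:.3f}, "
      f"max marginal deviation = {exp.main_model.marginal_dev:.4f}, "
      f"prevalence = {exp.main_model.prevalence:.3f}")

ds = build_cc_pool(exp.pool, exp.main_model, PoolSpec(n_replicates=10, seed=1))
print(evaluate_combination(ds, cfg.epi_triple, MDRConfig(seed=2)).summary())

ds45 = pm2_case_control(ds, PhenocopySpec("PM2", 0.45, exp.alt_models, seed=3),
                        exp.pool, main_model=exp.main_model)
res45 = evaluate_combination(ds45, cfg.epi_triple, MDRConfig(seed=2))
print(f"testing OR after 45% PM2 phenocopies: {res45.odds_ratio:.4f}")
```

which prints:

```
penetrance table: achieved OR = 3.953, max marginal deviation = 0.0033, prevalence = 0.114
MDR evaluation of RL0-75 x RL0-153 x RL0-272
  testing accuracy (balanced): 0.6498
  testing sensitivity:         0.6465
  testing specificity:         0.6530
  testing odds ratio:          3.4416 (3.0223, 3.9191)
  training accuracy:           0.6608
  CV consistency:              0.97
  pooled confusion (TP FN TN FP): 1293 707 1306 694
testing OR after 45% PM2 phenocopies: 2.0129
```

The table is genuinely epistatic — no single locus deviates from the 11.4%
baseline risk by more than 0.33 percentage points — yet the forced-triple
MDR recovers a testing odds ratio near the modelled 4 on clean data
(3.44 here at a 10-replicate pool; ≈3.8 at the full 50-replicate design),
and replacing 45% of cases with phenocopies from other disease models
halves it. Single-point scans never see these loci at all.

The grid runner reproduces the whole design
(models × methods × levels × designs) from one seed:

```sh
phenosim benchmark --toy --seed 2 --out results/   # minutes-scale preset
phenosim report --results results/
```

`phenosim simulate`, `inject` and `analyze` expose the individual stages on
PLINK-style PED/MAP files.

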
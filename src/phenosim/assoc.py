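"""Association testing battery.

Single-point case-control scan (allelic chi-square + Cochran-Armitage trend,
no continuity correction), Hardy-Weinberg screening, the transmission
disequilibrium test on pedigrees (using the stored transmission records,
chi-square (b-c)^2/(b+c)), and a logistic regression with a three-way
dosage-product interaction term.

Results are returned as pandas DataFrames with one row per marker, using
conventional association-output column names; p values come from the 1-df
chi-square survival function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2 as chi2_dist

from .cohorts import CaseControlDataset, PedigreeDataset
from .genosim import ParameterError

_TINY_P = 1e-320  # floor for -log10(p) to stay finite


def _genotype_counts(g: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """(3, M) genotype counts within a row mask."""
    sub = g[mask]
    return np.stack([(sub == k).sum(axis=0) for k in (0, 1, 2)])


def _neglog10(p: np.ndarray) -> np.ndarray:
    return -np.log10(np.maximum(p, _TINY_P))


def single_point_scan(ds: CaseControlDataset) -> pd.DataFrame:
    """Allelic (2x2) and Cochran-Armitage trend chi-square for every marker.

    Monomorphic markers get chi2 = 0, p = 1 and an undefined odds ratio
    (NaN), flagged in the ``monomorphic`` column. A Bonferroni-adjusted p
    column is included; no continuity correction is applied.
    """
    if ds.n_cases < 1 or ds.n_controls < 1:
        raise ParameterError("need at least one case and one control")
    g = ds.genotypes.genotypes
    case_mask = ds.status == 1
    cc = _genotype_counts(g, case_mask).astype(float)  # (3, M) cases
    nc = _genotype_counts(g, ~case_mask).astype(float)  # (3, M) controls
    n_case, n_ctrl = float(case_mask.sum()), float((~case_mask).sum())

    # allelic 2x2: minor/major allele counts in cases and controls
    a = cc[1] + 2 * cc[2]  # minor alleles, cases
    b = 2 * n_case - a
    c = nc[1] + 2 * nc[2]
    d = 2 * n_ctrl - c
    n = a + b + c + d
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2_allelic = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        odds_ratio = (a * d) / (b * c)
    mono = (a + c == 0) | (b + d == 0)
    chi2_allelic = np.where(mono, 0.0, chi2_allelic)
    odds_ratio = np.where(mono | (b * c == 0), np.nan, odds_ratio)
    p_allelic = np.where(mono, 1.0, chi2_dist.sf(chi2_allelic, df=1))

    # Cochran-Armitage trend on the 2x3 genotype table, weights (0, 1, 2)
    wgt = np.array([0.0, 1.0, 2.0])
    tot = cc + nc  # (3, M) genotype totals
    N = n_case + n_ctrl
    t_stat = wgt @ cc - n_case / N * (wgt @ tot)
    var = (
        n_case
        * n_ctrl
        / N
        * ((wgt**2) @ tot - ((wgt @ tot) ** 2) / N)
        / N
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2_trend = np.where(var > 0, t_stat**2 / var, 0.0)
    p_trend = np.where(var > 0, chi2_dist.sf(chi2_trend, df=1), 1.0)

    m = g.shape[1]
    return pd.DataFrame(
        {
            "marker": ds.genotypes.marker_ids(),
            "chi2_allelic": chi2_allelic,
            "p_allelic": p_allelic,
            "neg_log10_p": _neglog10(p_allelic),
            "chi2_trend": chi2_trend,
            "p_trend": p_trend,
            "odds_ratio": odds_ratio,
            "p_bonferroni": np.minimum(1.0, p_allelic * m),
            "monomorphic": mono,
            "case_0": cc[0].astype(int),
            "case_1": cc[1].astype(int),
            "case_2": cc[2].astype(int),
            "ctrl_0": nc[0].astype(int),
            "ctrl_1": nc[1].astype(int),
            "ctrl_2": nc[2].astype(int),
        }
    )


def hwe_scan(
    ds: CaseControlDataset, group: str = "controls", flag_threshold: float = 1e-3
) -> pd.DataFrame:
    """1-df chi-square of observed vs HWE-expected genotype counts.

    ``group`` selects controls (default), cases or all individuals.
    Monomorphic markers get chi2 = 0, p = 1.
    """
    masks = {
        "controls": ds.status == 0,
        "cases": ds.status == 1,
        "all": np.ones(len(ds.status), dtype=bool),
    }
    if group not in masks:
        raise ParameterError(f"group must be one of {sorted(masks)}")
    mask = masks[group]
    if not mask.any():
        raise ParameterError(f"no individuals in group {group!r}")
    counts = _genotype_counts(ds.genotypes.genotypes, mask).astype(float)
    n = counts.sum(axis=0)
    p_hat = (counts[1] + 2 * counts[2]) / (2 * n)
    exp = np.stack([n * (1 - p_hat) ** 2, 2 * n * p_hat * (1 - p_hat), n * p_hat**2])
    mono = (p_hat == 0) | (p_hat == 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(mono, 0.0, ((counts - exp) ** 2 / exp).sum(axis=0))
    p = np.where(mono, 1.0, chi2_dist.sf(chi2, df=1))
    return pd.DataFrame(
        {
            "marker": ds.genotypes.marker_ids(),
            "chi2_hwe": chi2,
            "p_hwe": p,
            "flag": p < flag_threshold,
            "monomorphic": mono,
        }
    )


def tdt_scan(ds: PedigreeDataset) -> pd.DataFrame:
    """Transmission disequilibrium test over all affected offspring.

    For every heterozygous parent of an affected child, counts transmissions
    of the minor (b) and major (c) allele from the stored transmission
    records; chi2 = (b-c)^2/(b+c). Markers with no informative transmission
    are flagged (``informative`` False, p = 1). Multiple affected sibs per
    family all contribute, as in a whole-sample TDT run.
    """
    m = len(ds.markers)
    b = np.zeros(m)
    c = np.zeros(m)
    any_informative = False
    for fam in ds.families:
        aff = [ch for ch in fam.children if ch.status == 1]
        if not aff:
            continue
        f_het = fam.father_haps[0] != fam.father_haps[1]
        m_het = fam.mother_haps[0] != fam.mother_haps[1]
        for ch in aff:
            ft = fam.father_haps[ch.t_father]
            mt = fam.mother_haps[ch.t_mother]
            b += f_het * (ft == 1)
            c += f_het * (ft == 0)
            b += m_het * (mt == 1)
            c += m_het * (mt == 0)
            any_informative = True
    if not any_informative:
        raise ParameterError("no affected offspring with heterozygous parents")
    n = b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(n > 0, (b - c) ** 2 / n, 0.0)
    p = np.where(n > 0, chi2_dist.sf(chi2, df=1), 1.0)
    return pd.DataFrame(
        {
            "marker": [mk.id for mk in ds.markers],
            "transmitted": b.astype(int),
            "untransmitted": c.astype(int),
            "chi2_tdt": chi2,
            "p_tdt": p,
            "neg_log10_p": _neglog10(p),
            "informative": n > 0,
        }
    )


@dataclass
class InteractionResult:
    """Wald test of the three-way dosage-product term in a logistic fit."""

    loci: tuple[str, ...]
    coefficient: float
    p_value: float
    converged: bool

    def __str__(self) -> str:
        state = "" if self.converged else " [not converged]"
        return (
            f"interaction {'x'.join(self.loci)}: coef={self.coefficient:.4g}, "
            f"p={self.p_value:.3g}{state}"
        )


def logistic_interaction_test(
    ds: CaseControlDataset, loci: tuple[str, str, str]
) -> InteractionResult:
    """Fit status ~ g1 + g2 + g3 + g1*g2*g3 and test the product term."""
    cols = [ds.genotypes.marker_index(mid) for mid in loci]
    g = ds.genotypes.genotypes[:, cols].astype(float)
    x = np.column_stack([g, g.prod(axis=1)])
    x = sm.add_constant(x, has_constant="add")
    try:
        fit = sm.Logit(ds.status, x).fit(disp=0, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", True))
        coef = float(fit.params[-1])
        p = float(fit.pvalues[-1])
    except Exception:
        return InteractionResult(tuple(loci), float("nan"), float("nan"), False)
    if not np.isfinite(p):
        converged = False
    return InteractionResult(tuple(loci), coef, p, converged)


def top_marker(results: pd.DataFrame, p_column: str = "p_allelic") -> str:
    """Marker with the smallest p value."""
    return str(results.loc[results[p_column].idxmin(), "marker"])


def marker_rank(results: pd.DataFrame, marker: str, p_column: str = "p_allelic") -> int:
    """1-based rank of a marker when sorted by ascending p value."""
    order = results.sort_values(p_column, kind="mergesort")["marker"].tolist()
    return order.index(marker) + 1
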
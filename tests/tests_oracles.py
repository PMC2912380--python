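"""Independent brute-force oracles shared by the statistic test suites.

These are written from the textbook definitions with explicit expected
counts and loops, on purpose: they must stay independent of the vectorised
implementations they check.
"""

import numpy as np

from phenosim.cohorts import (
    CaseControlDataset,
    ChildRecord,
    FamilyRecord,
    PedigreeDataset,
)
from phenosim.genosim import GenotypeMatrix, MarkerInfo


def marker_stub(n):
    return [MarkerInfo(f"RL0-{i}", i, 0.3, i) for i in range(n)]


def dataset_from_counts(case_counts, ctrl_counts):
    """Build a one-marker dataset realising the given 2x3 genotype table."""
    rows, status = [], []
    for g, n in enumerate(case_counts):
        rows += [g] * n
        status += [1] * n
    for g, n in enumerate(ctrl_counts):
        rows += [g] * n
        status += [0] * n
    g = np.array(rows, dtype=np.int8)[:, None]
    gm = GenotypeMatrix(g, marker_stub(1), [f"i{k}" for k in range(len(rows))])
    n = len(rows)
    return CaseControlDataset(
        gm,
        np.array(status, dtype=np.int8),
        np.full(n, "", dtype=object),
        np.zeros(n, dtype=int),
    )


def allelic_chi2_oracle(case_counts, ctrl_counts):
    """Pearson chi-square on the 2x2 allele table via explicit expecteds."""
    a = case_counts[1] + 2 * case_counts[2]
    b = 2 * sum(case_counts) - a
    c = ctrl_counts[1] + 2 * ctrl_counts[2]
    d = 2 * sum(ctrl_counts) - c
    obs = np.array([[a, b], [c, d]], dtype=float)
    total = obs.sum()
    if obs.sum(axis=0).min() == 0:
        return 0.0
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    return float(((obs - exp) ** 2 / exp).sum())


def trend_chi2_oracle(case_counts, ctrl_counts):
    """Cochran-Armitage trend statistic from the definition: the case score
    sum against its finite-population null variance."""
    w = np.array([0.0, 1.0, 2.0])
    r = np.array(case_counts, dtype=float)
    n = r + np.array(ctrl_counts, dtype=float)
    N, R = n.sum(), r.sum()
    t = float(w @ r - R / N * (w @ n))
    pop_var = float((w**2) @ n / N - ((w @ n) / N) ** 2)
    var = R * (N - R) / N * pop_var
    return 0.0 if var == 0 else t**2 / var


def hwe_chi2_oracle(counts):
    n = sum(counts)
    if n == 0:
        return 0.0
    p = (counts[1] + 2 * counts[2]) / (2 * n)
    if p in (0.0, 1.0):
        return 0.0
    exp = [n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2]
    return float(sum((o - e) ** 2 / e for o, e in zip(counts, exp)))


def family_with_transmissions(n_minor, n_major, m=1):
    """Het-father trios engineered to transmit the minor allele ``n_minor``
    times and the major allele ``n_major`` times to affected children."""
    fams = []
    for k in range(n_minor + n_major):
        t = 0 if k < n_minor else 1
        fams.append(
            FamilyRecord(
                family_id=f"f{k}",
                config_label="trio",
                father_haps=np.array([[1] * m, [0] * m], dtype=np.int8),
                mother_haps=np.array([[0] * m, [0] * m], dtype=np.int8),
                children=[ChildRecord(status=1, t_father=t, t_mother=0, role="affected")],
            )
        )
    return PedigreeDataset(fams, marker_stub(m))
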
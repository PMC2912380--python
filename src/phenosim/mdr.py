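"""Multifactor dimensionality reduction (MDR).

MDR collapses a multilocus genotype table into one attribute: each cell of
the k-locus genotype grid is labeled high-risk when its training-set
case:control ratio reaches a threshold (the dataset-wide ratio by default;
ties go high), low-risk otherwise, and empty cells classify test individuals
as low-risk. Performance is measured by stratified cross-validation with
predictions pooled over folds into a single 2x2 confusion table:

* balanced testing accuracy = (sensitivity + specificity) / 2
* testing odds ratio = (TP*TN)/(FP*FN), equivalently
  [sens/(1-sens)]*[spec/(1-spec)] when all four cells are positive,
  with a 95% Woolf (log-method) confidence interval.

Besides forced evaluation of a given locus combination, a seeded random
non-exhaustive search over 2- to 4-way combinations is provided (budget
5,000 evaluations by default), falling back to exhaustive enumeration when
the budget covers the whole space.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .cohorts import CaseControlDataset
from .genosim import ParameterError

HIGH, LOW, EMPTY = 1, 0, -1


@dataclass
class MDRConfig:
    cv_folds: int = 10
    ratio_threshold: float | None = None  # None -> dataset case:control ratio
    search_budget: int = 5000
    min_way: int = 2
    max_way: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ParameterError("cv_folds must be >= 2")
        if not 1 <= self.min_way <= self.max_way:
            raise ParameterError("need 1 <= min_way <= max_way")


@dataclass
class MDRResult:
    """Cross-validated evaluation of one attribute combination."""

    attributes: tuple[str, ...]
    cell_labels: dict[tuple[int, ...], int]  # full-data labels, HIGH/LOW/EMPTY
    testing_accuracy: float
    sensitivity: float
    specificity: float
    odds_ratio: float
    or_ci: tuple[float, float]
    training_accuracy: float
    cv_consistency: float
    confusion: tuple[int, int, int, int]  # (TP, FN, TN, FP)
    flagged: bool = False  # Haldane-Anscombe correction applied

    def summary(self) -> str:
        tp, fn, tn, fp = self.confusion
        lines = [
            f"MDR evaluation of {' x '.join(self.attributes)}",
            f"  testing accuracy (balanced): {self.testing_accuracy:.4f}",
            f"  testing sensitivity:         {self.sensitivity:.4f}",
            f"  testing specificity:         {self.specificity:.4f}",
            f"  testing odds ratio:          {self.odds_ratio:.4f} "
            f"({self.or_ci[0]:.4f}, {self.or_ci[1]:.4f})"
            + (" [Haldane-corrected]" if self.flagged else ""),
            f"  training accuracy:           {self.training_accuracy:.4f}",
            f"  CV consistency:              {self.cv_consistency:.2f}",
            f"  pooled confusion (TP FN TN FP): {tp} {fn} {tn} {fp}",
        ]
        return "\n".join(lines)


def _cell_codes(g: np.ndarray, cols: list[int]) -> np.ndarray:
    """Base-3 cell index for each individual over the chosen attribute columns."""
    code = np.zeros(g.shape[0], dtype=np.int64)
    for c in cols:
        code = code * 3 + g[:, c]
    return code


def label_cells(
    cell_codes: np.ndarray,
    status: np.ndarray,
    n_cells: int,
    ratio_threshold: float,
) -> np.ndarray:
    """Label each genotype cell HIGH/LOW/EMPTY from training counts.

    A cell is high-risk iff cases >= threshold * controls (ties high; a cell
    with cases and no controls is high).
    """
    case_counts = np.bincount(cell_codes[status == 1], minlength=n_cells)
    ctrl_counts = np.bincount(cell_codes[status == 0], minlength=n_cells)
    labels = np.full(n_cells, EMPTY, dtype=np.int8)
    nonempty = (case_counts + ctrl_counts) > 0
    high = case_counts >= ratio_threshold * ctrl_counts
    labels[nonempty & high] = HIGH
    labels[nonempty & ~high] = LOW
    return labels


def _decode_cell(code: int, k: int) -> tuple[int, ...]:
    digits = []
    for _ in range(k):
        code, d = divmod(code, 3)
        digits.append(d)
    return tuple(reversed(digits))


def _stratified_folds(
    status: np.ndarray, cv_folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold id per individual, stratified by status, seeded."""
    folds = np.empty(len(status), dtype=np.int32)
    for s in (0, 1):
        idx = np.flatnonzero(status == s)
        idx = idx[rng.permutation(len(idx))]
        folds[idx] = np.arange(len(idx)) % cv_folds
    return folds


def _woolf_ci(tp: float, fn: float, tn: float, fp: float) -> tuple[float, float]:
    se = math.sqrt(1 / tp + 1 / fn + 1 / tn + 1 / fp)
    log_or = math.log((tp * tn) / (fp * fn))
    return (math.exp(log_or - 1.96 * se), math.exp(log_or + 1.96 * se))


def evaluate_combination(
    ds: CaseControlDataset,
    attributes: tuple[str, ...],
    config: MDRConfig | None = None,
) -> MDRResult:
    """Cross-validated MDR evaluation of one forced attribute combination."""
    config = config or MDRConfig()
    cols = [ds.genotypes.marker_index(a) for a in attributes]
    status = np.asarray(ds.status)
    n_case, n_ctrl = int(status.sum()), int(len(status) - status.sum())
    if n_case < config.cv_folds or n_ctrl < config.cv_folds:
        raise ParameterError("need at least cv_folds cases and controls")
    threshold = (
        config.ratio_threshold
        if config.ratio_threshold is not None
        else n_case / n_ctrl
    )
    codes = _cell_codes(ds.genotypes.genotypes, cols)
    n_cells = 3 ** len(cols)
    rng = np.random.default_rng(config.seed)
    folds = _stratified_folds(status, config.cv_folds, rng)

    full_labels = label_cells(codes, status, n_cells, threshold)
    tp = fn = tn = fp = 0
    train_acc = []
    label_agreement = []
    for f in range(config.cv_folds):
        test = folds == f
        train = ~test
        labels = label_cells(codes[train], status[train], n_cells, threshold)
        pred_train = labels[codes[train]] == HIGH
        st_train = status[train] == 1
        sens_t = (pred_train & st_train).sum() / max(st_train.sum(), 1)
        spec_t = (~pred_train & ~st_train).sum() / max((~st_train).sum(), 1)
        train_acc.append((sens_t + spec_t) / 2)
        seen = labels != EMPTY
        both = seen & (full_labels != EMPTY)
        label_agreement.append(
            float((labels[both] == full_labels[both]).mean()) if both.any() else 1.0
        )
        pred = labels[codes[test]] == HIGH  # empty cells classify low-risk
        st = status[test] == 1
        tp += int((pred & st).sum())
        fn += int((~pred & st).sum())
        tn += int((~pred & ~st).sum())
        fp += int((pred & ~st).sum())

    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    accuracy = (sens + spec) / 2
    flagged = 0 in (tp, fn, tn, fp)
    if flagged:
        a, b, c, d = tp + 0.5, fn + 0.5, tn + 0.5, fp + 0.5
    else:
        a, b, c, d = float(tp), float(fn), float(tn), float(fp)
    odds_ratio = (a * c) / (d * b)
    ci = _woolf_ci(a, b, c, d)
    cells = {
        _decode_cell(code, len(cols)): int(full_labels[code])
        for code in range(n_cells)
    }
    return MDRResult(
        attributes=tuple(attributes),
        cell_labels=cells,
        testing_accuracy=accuracy,
        sensitivity=sens,
        specificity=spec,
        odds_ratio=odds_ratio,
        or_ci=ci,
        training_accuracy=float(np.mean(train_acc)),
        cv_consistency=float(np.mean(label_agreement)),
        confusion=(tp, fn, tn, fp),
        flagged=flagged,
    )


def _total_combinations(m: int, min_way: int, max_way: int) -> int:
    return sum(math.comb(m, k) for k in range(min_way, max_way + 1))


def random_search(
    ds: CaseControlDataset, config: MDRConfig | None = None
) -> list[MDRResult]:
    """Random non-exhaustive MDR search, ranked by testing accuracy.

    Combinations are drawn uniformly without replacement over all way-sizes
    from ``min_way`` to ``max_way``. If the budget covers the whole space the
    search is exhaustive. Deterministic under the config seed.
    """
    config = config or MDRConfig()
    if config.search_budget < 1:
        raise ParameterError("search_budget must be >= 1")
    ids = ds.genotypes.marker_ids()
    m = len(ids)
    sizes = list(range(config.min_way, min(config.max_way, m) + 1))
    total = _total_combinations(m, sizes[0], sizes[-1])
    rng = np.random.default_rng(config.seed)
    combos: list[tuple[int, ...]] = []
    if config.search_budget >= total:
        for k in sizes:
            combos.extend(itertools.combinations(range(m), k))
    else:
        weights = np.array([math.comb(m, k) for k in sizes], dtype=float)
        weights /= weights.sum()
        seen: set[tuple[int, ...]] = set()
        while len(combos) < config.search_budget:
            k = sizes[rng.choice(len(sizes), p=weights)]
            combo = tuple(sorted(rng.choice(m, size=k, replace=False).tolist()))
            if combo not in seen:
                seen.add(combo)
                combos.append(combo)
    results = [
        evaluate_combination(ds, tuple(ids[i] for i in combo), config)
        for combo in combos
    ]
    results.sort(key=lambda r: (-r.testing_accuracy, r.attributes))
    return results
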
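"""Detection-power evaluation over replicate datasets.

Three nested success criteria are tallied for a batch of replicates
simulated from the same disease model:

* Power1 -- the optimizer's returned best combination equals the embedded
  functional combination (set equality);
* Power2 -- additionally, the G-test of the functional combination is
  significant at the Bonferroni-style threshold 1 / C(n, k);
* Power3 -- additionally, a multifactor-dimensionality-reduction (MDR)
  classifier built on the functional combination attains a 10-fold
  stratified cross-validated prediction error below a threshold
  (default 0.45).

Also included: a paired two-tailed t-test and a Friedman rank test (with
tie correction) for comparing per-model power vectors across algorithms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2, rankdata, ttest_rel

from .genotype_data import GenotypeDataset
from .scores import ContingencyTable, genotype_cell_index, lr_score


@dataclass(frozen=True)
class GTestResult:
    statistic: float
    df: int
    p_value: float


def g_test(t: ContingencyTable) -> GTestResult:
    """Likelihood-ratio (G) test of genotype-status independence.

    Degrees of freedom count only genotype rows that are actually
    occupied, so sparse high-order tables are not inflated; df = 0 gives
    p = 1.
    """
    stat = lr_score(t)
    occupied = int((t.counts.sum(axis=1) > 0).sum())
    df = max(occupied - 1, 0) * (t.counts.shape[1] - 1)
    p = float(chi2.sf(stat, df)) if df > 0 else 1.0
    return GTestResult(stat, df, p)


def g_test_threshold(n: int, k: int) -> float:
    """Per-replicate significance threshold 1 / C(n, k)."""
    return 1.0 / math.comb(n, k)


def _as_set(combo: Sequence[int]) -> frozenset[int]:
    return frozenset(int(c) for c in combo)


def power1(detected: Sequence[Sequence[int]], truth: Sequence[int]) -> float:
    """Fraction of replicates whose detected best equals the truth."""
    if len(detected) == 0:
        raise ValueError("need at least one replicate")
    t = _as_set(truth)
    return sum(_as_set(d) == t for d in detected) / len(detected)


@dataclass(frozen=True)
class MDRResult:
    error: float
    balanced_accuracy: float


def _stratified_folds(
    phenotype: np.ndarray, n_folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold id per sample, stratified by class with shuffled assignment."""
    fold = np.empty(phenotype.size, dtype=np.int64)
    for cls in (0, 1):
        idx = np.flatnonzero(phenotype == cls)
        if idx.size < n_folds:
            raise ValueError(
                f"class {cls} has {idx.size} samples, fewer than "
                f"{n_folds} folds"
            )
        rng.shuffle(idx)
        fold[idx] = np.arange(idx.size) % n_folds
    return fold


def mdr_cv(
    ds: GenotypeDataset,
    combo: Sequence[int],
    n_folds: int = 10,
    seed: int = 0,
) -> MDRResult:
    """MDR classifier on ``combo`` with stratified cross-validation.

    In each training split a genotype cell is labeled high-risk iff its
    case:control ratio strictly exceeds the overall training ratio
    (ties and empty cells are low-risk); held-out samples are classified
    by their cell label.  Returns the mean per-fold prediction error and
    the pooled balanced accuracy (sensitivity + specificity) / 2.
    """
    cols = ds.genotypes[:, [int(c) - 1 for c in combo]]
    cells = genotype_cell_index(cols)
    n_cells = 3 ** len(combo)
    y = ds.phenotype
    rng = np.random.default_rng(seed)
    fold = _stratified_folds(y, n_folds, rng)

    errors = []
    tp = tn = fp = fn = 0
    for f in range(n_folds):
        test = fold == f
        train = ~test
        case_counts = np.bincount(cells[train & (y == 1)], minlength=n_cells)
        ctrl_counts = np.bincount(cells[train & (y == 0)], minlength=n_cells)
        case_total = case_counts.sum()
        ctrl_total = ctrl_counts.sum()
        # high-risk iff cell case:control ratio > overall ratio, compared
        # by cross-multiplication so empty cells (0:0) stay low-risk
        high_risk = case_counts * ctrl_total > ctrl_counts * case_total
        pred = high_risk[cells[test]].astype(np.int64)
        truth_y = y[test]
        errors.append(float((pred != truth_y).mean()))
        tp += int(((pred == 1) & (truth_y == 1)).sum())
        tn += int(((pred == 0) & (truth_y == 0)).sum())
        fp += int(((pred == 1) & (truth_y == 0)).sum())
        fn += int(((pred == 0) & (truth_y == 1)).sum())

    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    return MDRResult(float(np.mean(errors)), (sens + spec) / 2.0)


@dataclass
class ReplicateRecord:
    detected: tuple[int, ...]
    g_p_value: float | None = None
    mdr_error: float | None = None
    balanced_accuracy: float | None = None


@dataclass
class PowerResult:
    """Success tallies for one disease model over T replicates."""

    label: str
    n_replicates: int
    s1: int
    s2: int
    s3: int
    records: list[ReplicateRecord]

    def __post_init__(self) -> None:
        if not 0 <= self.s3 <= self.s2 <= self.s1 <= self.n_replicates:
            raise ValueError("success counts must nest: s3 <= s2 <= s1 <= T")

    @property
    def power1(self) -> float:
        return self.s1 / self.n_replicates

    @property
    def power2(self) -> float:
        return self.s2 / self.n_replicates

    @property
    def power3(self) -> float:
        return self.s3 / self.n_replicates


def evaluate_power(
    detections: Sequence[Sequence[int]],
    truth: Sequence[int],
    datasets: Sequence[GenotypeDataset],
    label: str = "",
    error_threshold: float = 0.45,
    n_folds: int = 10,
    seed: int = 0,
) -> PowerResult:
    """Tally Power1/2/3 for one model's replicate batch.

    The G-test and MDR are evaluated on the truth combination, and only
    for replicates that are already Power1 successes, so the criteria are
    nested by construction.
    """
    if len(detections) != len(datasets):
        raise ValueError("one dataset per detection is required")
    truth_t = tuple(sorted(int(c) for c in truth))
    s1 = s2 = s3 = 0
    records: list[ReplicateRecord] = []
    for i, (det, ds) in enumerate(zip(detections, datasets)):
        rec = ReplicateRecord(tuple(int(c) for c in det))
        if _as_set(det) == _as_set(truth_t):
            s1 += 1
            from .scores import build_contingency

            g = g_test(build_contingency(ds, truth_t))
            rec.g_p_value = g.p_value
            threshold = g_test_threshold(ds.n_snps, len(truth_t))
            mdr = mdr_cv(ds, truth_t, n_folds=n_folds, seed=seed + i)
            rec.mdr_error = mdr.error
            rec.balanced_accuracy = mdr.balanced_accuracy
            if g.p_value < threshold:
                s2 += 1
                if mdr.error < error_threshold:
                    s3 += 1
        records.append(rec)
    return PowerResult(label, len(records), s1, s2, s3, records)


def paired_t_test(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Paired two-tailed t-test on per-model power vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors with >= 2 entries")
    d = x - y
    if np.allclose(d, 0.0):
        return 0.0, 1.0
    res = ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class FriedmanResult:
    average_ranks: np.ndarray
    statistic: float
    p_value: float


def friedman_test(power_matrix: np.ndarray) -> FriedmanResult:
    """Friedman rank test over a (models x algorithms) power matrix.

    Within each model, algorithms are ranked so that higher power gets the
    higher rank value (ties averaged).  The chi-square statistic uses the
    standard tie correction; a fully tied matrix yields statistic 0 and
    p = 1.
    """
    m = np.asarray(power_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need at least 2 models and 2 algorithms")
    n_models, n_algo = m.shape
    ranks = np.apply_along_axis(rankdata, 1, m)
    avg = ranks.mean(axis=0)
    stat = (
        12.0 * n_models / (n_algo * (n_algo + 1))
        * ((avg - (n_algo + 1) / 2.0) ** 2).sum()
    )
    # tie correction: 1 - sum(t^3 - t) / (N K (K^2 - 1))
    tie_sum = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float((counts ** 3 - counts).sum())
    correction = 1.0 - tie_sum / (n_models * n_algo * (n_algo ** 2 - 1))
    if correction <= 0.0 or stat == 0.0:
        stat = 0.0
    else:
        stat /= correction
    p = float(chi2.sf(stat, n_algo - 1)) if stat > 0 else 1.0
    return FriedmanResult(avg, float(stat), p)
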
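"""Contingency tables and statistical epistasis scores.

For a combination of k SNPs the 3^k multi-locus genotypes are crossed with
the binary disease status into a 3^k x 2 contingency table, from which four
association scores are computed:

* ``lr_score`` -- the likelihood-ratio G statistic
  ``2 * sum o_ij * ln(o_ij / e_ij)`` against row/column independence;
* ``k2_score`` -- the Bayesian-network K2 metric, reported as the negative
  logarithm of the classic product form and evaluated in log-gamma space so
  it stays finite for tables with thousands of samples;
* ``mi_score`` -- mutual information between the multi-locus genotype and
  the phenotype, in bits;
* ``gini_score`` -- the Gini impurity of the phenotype within genotype
  cells, weighted by cell frequency.

``oriented_score`` exposes all four in a unified "lower = stronger
association" orientation (LR and MI are negated) so any of them, or a
min-max-normalized sum of two of them (the linear mixed model,
``lmse_combine``), can serve directly as a minimization fitness.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln

from .errors import DataError
from .genotype_data import GenotypeDataset

SCORE_KINDS = ("lr", "k2", "mi", "gini")

#: The ten fitness configurations: four single scores and the six pairwise
#: linear mixed combinations.
FITNESS_NAMES = SCORE_KINDS + (
    "lr-k2", "lr-mi", "lr-gini", "k2-mi", "k2-gini", "mi-gini",
)


@dataclass(frozen=True)
class ContingencyTable:
    """Genotype-by-status counts (I x 2) for one SNP combination.

    Tables built from a dataset have I = 3^k rows in lexicographic
    genotype order; ``k=None`` admits generic row counts (useful for
    closed-form checks on small tables).
    """

    counts: np.ndarray
    k: int | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[1] != 2:
            raise ValueError("counts must be an I x 2 matrix")
        if self.k is not None and counts.shape[0] != 3 ** self.k:
            raise ValueError(
                f"expected {3 ** self.k} genotype rows for order {self.k}, "
                f"got {counts.shape[0]}"
            )
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def genotype_cell_index(genotypes: np.ndarray) -> np.ndarray:
    """Lexicographic cell index of each sample's k-locus genotype.

    The first SNP varies slowest, i.e. index = sum_j g_j * 3^(k-1-j).
    """
    genotypes = np.asarray(genotypes)
    k = genotypes.shape[1]
    powers = 3 ** np.arange(k - 1, -1, -1)
    return genotypes @ powers


def build_contingency(
    ds: GenotypeDataset, combo: Sequence[int]
) -> ContingencyTable:
    """Cross-tabulate the genotypes of ``combo`` (1-based SNP indices)
    against disease status."""
    combo = tuple(int(c) for c in combo)
    k = len(combo)
    if len(set(combo)) != k:
        raise ValueError(f"duplicate SNP index in combination {combo}")
    for c in combo:
        if not 1 <= c <= ds.n_snps:
            raise ValueError(
                f"SNP index {c} out of range [1, {ds.n_snps}]"
            )
    if ds.has_missing:
        raise DataError("cannot score a dataset with missing genotypes")
    cols = ds.genotypes[:, [c - 1 for c in combo]]
    counts = counts_from_columns(cols, ds.phenotype)
    return ContingencyTable(counts, k)


def counts_from_columns(columns: np.ndarray, phenotype: np.ndarray) -> np.ndarray:
    """Raw 3^k x 2 count matrix from genotype columns and phenotype."""
    idx = genotype_cell_index(columns)
    n_cells = 3 ** columns.shape[1]
    return np.bincount(idx * 2 + phenotype, minlength=2 * n_cells).reshape(
        n_cells, 2
    )


# -- score kernels on raw count matrices (hot path for the optimizer) -------

def _lr(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        raise ValueError("empty contingency table")
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total
    mask = counts > 0
    o = counts[mask]
    return float(2.0 * (o * np.log(o / expected[mask])).sum())


def _k2(counts: np.ndarray) -> float:
    # -log of prod_i (J-1)!/(N_i+J-1)! prod_j N_ij! with J = 2;
    # ln((J-1)!) = lnGamma(2) = 0 and drops out.
    rows = counts.sum(axis=1)
    return float(gammaln(rows + 2).sum() - gammaln(counts + 1).sum())


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _mi(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        raise ValueError("empty contingency table")
    joint = counts / total
    return (
        _entropy_bits(joint.sum(axis=1))
        + _entropy_bits(joint.sum(axis=0))
        - _entropy_bits(joint.ravel())
    )


def _gini(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        raise ValueError("empty contingency table")
    rows = counts.sum(axis=1)
    nz = rows > 0
    p_cell = counts[nz] / rows[nz, None]
    impurity = 1.0 - (p_cell ** 2).sum(axis=1)
    return float(((rows[nz] / total) * impurity).sum())


_KERNELS = {"lr": _lr, "k2": _k2, "mi": _mi, "gini": _gini}
# Sign applied so that every kind is minimized when association is strong.
_ORIENTATION = {"lr": -1.0, "k2": 1.0, "mi": -1.0, "gini": 1.0}


def lr_score(t: ContingencyTable) -> float:
    """Likelihood-ratio G statistic (>= 0; 0 iff observed == expected)."""
    return _lr(t.counts)


def k2_score(t: ContingencyTable) -> float:
    """Negative-log K2 metric; lower values mean stronger association."""
    return _k2(t.counts)


def mi_score(t: ContingencyTable) -> float:
    """Mutual information between genotype combination and status, in bits."""
    return _mi(t.counts)


def gini_score(t: ContingencyTable) -> float:
    """Frequency-weighted Gini impurity; in [0, 0.5] for two classes."""
    return _gini(t.counts)


def oriented_from_counts(kind: str, counts: np.ndarray) -> float:
    try:
        return _ORIENTATION[kind] * _KERNELS[kind](counts)
    except KeyError:
        raise ValueError(
            f"unknown score kind {kind!r}; choose from {SCORE_KINDS}"
        ) from None


def oriented_score(kind: str, t: ContingencyTable) -> float:
    """Score ``t`` so that lower values always mean stronger association."""
    return oriented_from_counts(kind, t.counts)


@dataclass(frozen=True)
class ScoreSpec:
    """A fitness specification: one score kind, or a mixed pair with
    min-max bounds estimated during optimizer initialization."""

    kinds: tuple[str, ...]
    mins: tuple[float, ...] | None = None
    maxs: tuple[float, ...] | None = None
    constant: tuple[bool, ...] | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.kinds) <= 2:
            raise ValueError("a fitness uses one score or a mixed pair")
        if len(set(self.kinds)) != len(self.kinds):
            raise ValueError("mixed fitness needs two distinct score kinds")
        for kind in self.kinds:
            if kind not in SCORE_KINDS:
                raise ValueError(f"unknown score kind {kind!r}")

    @classmethod
    def parse(cls, name: str) -> "ScoreSpec":
        """Parse a fitness name such as ``mi`` or ``k2-gini``."""
        parts = tuple(name.lower().split("-"))
        return cls(parts)

    @property
    def name(self) -> str:
        return "-".join(self.kinds)

    @property
    def is_mixed(self) -> bool:
        return len(self.kinds) == 2

    @property
    def is_calibrated(self) -> bool:
        return self.mins is not None


def calibrate_bounds(
    kinds: Sequence[str] | ScoreSpec, tables: Iterable[ContingencyTable]
) -> ScoreSpec:
    """Estimate per-component min/max oriented scores from ``tables``.

    Components whose score never varies over the calibration set are
    flagged constant and later contribute 0 to the mixed fitness.
    """
    spec = kinds if isinstance(kinds, ScoreSpec) else ScoreSpec(tuple(kinds))
    scores = np.array(
        [[oriented_score(kind, t) for kind in spec.kinds] for t in tables]
    )
    if scores.shape[0] < 2:
        raise ValueError("calibration needs at least two tables")
    mins = scores.min(axis=0)
    maxs = scores.max(axis=0)
    return replace(
        spec,
        mins=tuple(float(v) for v in mins),
        maxs=tuple(float(v) for v in maxs),
        constant=tuple(bool(hi <= lo) for lo, hi in zip(mins, maxs)),
    )


def lmse_from_components(spec: ScoreSpec, components: Sequence[float]) -> float:
    """Linear mixed fitness: clamped min-max normalized components, summed."""
    if not spec.is_calibrated:
        raise ValueError("ScoreSpec bounds are not calibrated")
    lm = 0.0
    for value, lo, hi, const in zip(
        components, spec.mins, spec.maxs, spec.constant
    ):
        if const:
            continue
        lm += min(1.0, max(0.0, (value - lo) / (hi - lo)))
    return lm


def lmse_combine(spec: ScoreSpec, t: ContingencyTable) -> float:
    """Evaluate the linear mixed fitness of ``t`` under calibrated bounds."""
    components = [oriented_score(kind, t) for kind in spec.kinds]
    return lmse_from_components(spec, components)
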
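"""Penetrance-table disease models and case-control dataset simulation.

A :class:`PenetranceModel` specifies, for k interacting SNPs, the minor
allele frequency of each locus and the disease probability (penetrance)
``f(g)`` of each of the 3^k multi-locus genotypes.  Under Hardy-Weinberg
equilibrium and locus independence this determines the population
prevalence ``K = sum_g P(g) f(g)``, the single-locus marginal penetrances,
and the broad-sense heritability on the observed scale,

    h2 = sum_g P(g) (f(g) - K)^2 / (K (1 - K)),

the variance-ratio definition used by the GAMETES simulator.

``generate_dataset`` draws a case-control panel by rejection sampling:
multi-locus genotypes for the functional SNPs are drawn under HWE, disease
status is assigned with probability ``f(g)``, and individuals are routed
into the case or control pool until both are full.  The remaining "noise"
SNPs are independent of status, each with its own MAF drawn uniformly from
a configurable interval (default (0.05, 0.5)).  Functional SNPs are placed
at random recorded positions.

The built-in model catalog provides small synthetic fixtures (parity/XOR
models without marginal effects, a multiplicative model with marginal
effects, and second/third-order additive models) for tests and examples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import InfeasibleModelError
from .genotype_data import GenotypeDataset

DEFAULT_NOISE_MAF_RANGE = (0.05, 0.5)


@dataclass
class PenetranceModel:
    """Order-k disease model: per-SNP MAFs plus a 3^k penetrance table.

    The table is row-major in the same lexicographic genotype order as the
    contingency tables (first SNP varies slowest).
    """

    label: str
    mafs: np.ndarray
    table: np.ndarray

    def __post_init__(self) -> None:
        self.mafs = np.asarray(self.mafs, dtype=float)
        self.table = np.asarray(self.table, dtype=float).ravel()
        if self.mafs.ndim != 1 or self.mafs.size < 1:
            raise ValueError("mafs must be a non-empty vector")
        if not ((self.mafs > 0) & (self.mafs <= 0.5)).all():
            raise ValueError("all MAFs must lie in (0, 0.5]")
        if self.table.size != 3 ** self.k:
            raise ValueError(
                f"penetrance table needs {3 ** self.k} entries for order "
                f"{self.k}, got {self.table.size}"
            )
        if not ((self.table >= 0) & (self.table <= 1)).all():
            raise ValueError("penetrances must lie in [0, 1]")

    @property
    def k(self) -> int:
        return self.mafs.size

    def genotype_probs(self) -> np.ndarray:
        """HWE probability of each multi-locus genotype (first SNP slowest)."""
        probs = np.ones(1)
        for p in self.mafs:
            trip = np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
            probs = np.outer(probs, trip).ravel()
        return probs

    def genotype_digits(self) -> np.ndarray:
        """(3^k, k) matrix decoding each cell index to per-SNP genotypes."""
        cells = np.arange(3 ** self.k)
        digits = np.empty((cells.size, self.k), dtype=np.int64)
        for j in range(self.k):
            digits[:, j] = (cells // 3 ** (self.k - 1 - j)) % 3
        return digits

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({
            "label": self.label,
            "order": self.k,
            "mafs": self.mafs.tolist(),
            "table": self.table.tolist(),
        }, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PenetranceModel":
        data = json.loads(Path(path).read_text())
        model = cls(data["label"], np.asarray(data["mafs"]),
                    np.asarray(data["table"]))
        if "order" in data and int(data["order"]) != model.k:
            raise ValueError(
                f"declared order {data['order']} does not match "
                f"{model.k} MAFs"
            )
        return model


@dataclass(frozen=True)
class ModelStats:
    prevalence: float
    heritability: float
    marginal_penetrance: np.ndarray  # (k, 3)


def model_stats(model: PenetranceModel) -> ModelStats:
    """Prevalence, heritability, and per-SNP marginal penetrances."""
    probs = model.genotype_probs()
    f = model.table
    prevalence = float((probs * f).sum())
    if prevalence < 1e-12 or prevalence > 1.0 - 1e-12:
        raise ValueError(
            f"model {model.label!r} has degenerate prevalence "
            f"{prevalence}; heritability is undefined"
        )
    var = float((probs * (f - prevalence) ** 2).sum())
    h2 = var / (prevalence * (1.0 - prevalence))
    digits = model.genotype_digits()
    marginals = np.empty((model.k, 3))
    for j in range(model.k):
        for a in range(3):
            sel = digits[:, j] == a
            marginals[j, a] = (probs[sel] * f[sel]).sum() / probs[sel].sum()
    return ModelStats(prevalence, h2, marginals)


@dataclass
class SimulationConfig:
    """Dataset dimensions and noise structure for one simulated panel."""

    n_cases: int = 400
    n_controls: int = 400
    n_snps: int = 1000
    noise_maf_range: tuple[float, float] = DEFAULT_NOISE_MAF_RANGE
    functional_positions: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("both case and control pools must be non-empty")
        lo, hi = self.noise_maf_range
        if not (0.0 < lo < hi < 0.5) and not (0.0 < lo <= hi <= 0.5):
            raise ValueError("noise_maf_range must be an interval in (0, 0.5]")


def sample_cohort(
    model: PenetranceModel, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Unconditioned draw of ``n`` individuals: functional genotypes under
    HWE and Bernoulli(f(g)) disease status.  Returns (genotypes, status)."""
    probs = model.genotype_probs()
    cells = rng.choice(probs.size, size=n, p=probs)
    status = (rng.random(n) < model.table[cells]).astype(np.int64)
    return model.genotype_digits()[cells], status


def generate_dataset(
    model: PenetranceModel,
    sim: SimulationConfig,
    max_draw_factor: int = 200,
) -> tuple[GenotypeDataset, tuple[int, ...]]:
    """Simulate one balanced-or-not case-control panel.

    Returns the dataset and the 1-based positions of the functional SNPs.
    Raises :class:`InfeasibleModelError` when one pool cannot be filled
    within ``max_draw_factor`` times the expected number of draws.
    """
    if sim.n_snps < model.k:
        raise ValueError(
            f"n_snps={sim.n_snps} cannot hold a {model.k}-SNP model"
        )
    try:
        stats = model_stats(model)  # validates 0 < K < 1
    except ValueError as exc:
        raise InfeasibleModelError(
            f"model {model.label!r}: one pool is unreachable ({exc})"
        ) from exc
    rng = np.random.default_rng(sim.seed)
    k = model.k
    n_total = sim.n_cases + sim.n_controls
    rarer = min(stats.prevalence, 1.0 - stats.prevalence)
    max_draws = int(max_draw_factor * n_total / rarer) + 1000

    cases: list[np.ndarray] = []
    controls: list[np.ndarray] = []
    drawn = 0
    while len(cases) < sim.n_cases or len(controls) < sim.n_controls:
        if drawn >= max_draws:
            raise InfeasibleModelError(
                f"model {model.label!r}: could not fill "
                f"{sim.n_cases} cases / {sim.n_controls} controls within "
                f"{max_draws} draws (prevalence {stats.prevalence:.3g})"
            )
        batch = min(max(1024, n_total), max_draws - drawn)
        geno, status = sample_cohort(model, batch, rng)
        drawn += batch
        for row, s in zip(geno, status):
            if s and len(cases) < sim.n_cases:
                cases.append(row)
            elif not s and len(controls) < sim.n_controls:
                controls.append(row)

    functional = np.vstack(cases + controls)
    phenotype = np.concatenate(
        [np.ones(sim.n_cases, dtype=np.int64),
         np.zeros(sim.n_controls, dtype=np.int64)]
    )

    n_noise = sim.n_snps - k
    noise_mafs = rng.uniform(*sim.noise_maf_range, size=n_noise)
    noise = rng.binomial(2, noise_mafs, size=(n_total, n_noise))

    if sim.functional_positions is not None:
        truth = tuple(sorted(int(p) for p in sim.functional_positions))
        if len(truth) != k or len(set(truth)) != k:
            raise ValueError(f"need {k} distinct functional positions")
        if truth[0] < 1 or truth[-1] > sim.n_snps:
            raise ValueError("functional positions out of range")
    else:
        truth = tuple(sorted(
            int(p) + 1 for p in rng.choice(sim.n_snps, size=k, replace=False)
        ))

    genotypes = np.empty((n_total, sim.n_snps), dtype=np.int64)
    truth_idx = [p - 1 for p in truth]
    noise_idx = [j for j in range(sim.n_snps) if j + 1 not in truth]
    genotypes[:, truth_idx] = functional
    genotypes[:, noise_idx] = noise

    perm = rng.permutation(n_total)
    ds = GenotypeDataset(genotypes[perm], phenotype[perm])
    return ds, truth


def parity_model(
    order: int = 2,
    penetrance: float = 0.1,
    baseline: float = 0.0,
    h2: float | None = None,
    label: str | None = None,
) -> PenetranceModel:
    """Pure parity (XOR-style) model at MAF 0.5: disease probability is
    ``penetrance`` when the genotype codes sum to an odd number, else
    ``baseline``.

    All marginal penetrances equal K, so the model has no marginal effect
    at any order.  With MAF 0.5 the odd-parity probability is 1/2, giving
    K = (baseline + penetrance) / 2 and, writing d = penetrance - baseline,
    h2 = (d^2 / 4) / (K (1 - K)).  Passing ``h2`` solves this for d at the
    given baseline (closed form penetrance = 2 h2 / (1 + h2) when the
    baseline is 0).

    A nonzero baseline matters when the model is used to study how power
    responds to h2: with baseline 0 every case carries an odd-parity
    genotype whatever the penetrance, so balanced case-control panels are
    equally easy at any heritability.
    """
    if h2 is not None:
        if baseline == 0.0:
            penetrance = 2.0 * h2 / (1.0 + h2)
        else:
            from scipy.optimize import brentq

            def gap(d: float) -> float:
                k = baseline + d / 2.0
                return d * d / 4.0 - h2 * k * (1.0 - k)

            penetrance = baseline + brentq(gap, 1e-9, 1.0 - baseline)
    mafs = np.full(order, 0.5)
    digits_sum = np.zeros(3 ** order, dtype=np.int64)
    for j in range(order):
        digits_sum += (np.arange(3 ** order) // 3 ** (order - 1 - j)) % 3
    table = np.where(digits_sum % 2 == 1, penetrance, baseline)
    return PenetranceModel(
        label or f"parity{order}-a{penetrance:.4g}", mafs, table
    )


def multiplicative_model(
    baseline: float = 0.05,
    risk: float = 1.8,
    mafs: Sequence[float] = (0.3, 0.3),
    label: str = "multiplicative2",
) -> PenetranceModel:
    """Two-locus multiplicative-interaction model with marginal effects:
    f(g1, g2) = baseline * risk^(g1*g2), capped at 1."""
    g = np.arange(3)
    table = np.minimum(1.0, baseline * risk ** np.outer(g, g)).ravel()
    return PenetranceModel(label, np.asarray(mafs, dtype=float), table)


def additive_model(
    order: int = 3,
    baseline: float = 0.05,
    slope: float = 0.15,
    maf: float = 0.25,
    label: str | None = None,
) -> PenetranceModel:
    """Additive model f(g) = baseline + slope * sum(g), clipped to [0, 1];
    strong marginal effects at every locus (a high-order, easy-detection
    regime)."""
    digits_sum = np.zeros(3 ** order, dtype=np.int64)
    for j in range(order):
        digits_sum += (np.arange(3 ** order) // 3 ** (order - 1 - j)) % 3
    table = np.clip(baseline + slope * digits_sum, 0.0, 1.0)
    return PenetranceModel(
        label or f"additive{order}", np.full(order, maf), table
    )


def builtin_models() -> dict[str, PenetranceModel]:
    """Catalog of synthetic fixture disease models.

    These are stand-in models constructed for testing and examples, not
    transcriptions of any published penetrance tables.
    """
    return {
        "xor": parity_model(order=2, penetrance=0.1, label="xor"),
        "multiplicative": multiplicative_model(label="multiplicative"),
        "parity3": parity_model(order=3, penetrance=0.2, label="parity3"),
        "additive3": additive_model(order=3, label="additive3"),
    }
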
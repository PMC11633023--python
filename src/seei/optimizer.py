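"""Spherical-evolution search with a feedback mechanism over k-SNP
combinations.

The optimizer maintains a population of real-valued k-vectors in
``[1, n]^k``.  Each vector decodes (round half-up, clamp, repair
duplicates) to a combination of k distinct SNP indices whose oriented
association score is the fitness to minimize.  New candidates are produced
by a spherical move around the parent: a uniformly random direction in a
2-D or 3-D coordinate subspace with Euclidean radius exactly
``scale * (||a_pbest - a_i|| + ||a_r1 - a_h||)``, where ``a_pbest`` is
drawn from the current elite fraction, ``a_r1`` from the population and
``a_h`` from an archive of past winners.  The feedback mechanism consists
of (i) a success-history memory of effective scale factors updated with a
winning-intensity-weighted Lehmer mean and sampled through a Cauchy
distribution, (ii) the winner archive that diversifies donors, and
(iii) linear population-size reduction from ``pop_size`` down to
``min_pop_size`` over the fitness-evaluation budget.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np

from .errors import DataError
from .genotype_data import GenotypeDataset
from .scores import (
    ScoreSpec,
    counts_from_columns,
    lmse_from_components,
    oriented_from_counts,
)

TWO_PI = 2.0 * math.pi


def default_max_fes(k: int) -> int:
    """Default evaluation budget: 20000 at order 2, 20000*k at order >= 3."""
    return 20000 if k == 2 else 20000 * k


@dataclass
class SEEIConfig:
    """Optimizer settings; the defaults are the recommended values
    (pop_size 50, p_best_rate 0.11, arc_rate 2.6, memory_size 6,
    min_pop_size 4)."""

    k: int = 2
    fitness: str | ScoreSpec = "mi"
    pop_size: int = 50
    min_pop_size: int = 4
    p_best_rate: float = 0.11
    arc_rate: float = 2.6
    memory_size: int = 6
    max_fes: int | None = None
    seed: int = 0
    top_k: int = 10

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("interaction order k must be >= 2")
        if self.min_pop_size < 4:
            raise ValueError("min_pop_size must be >= 4")
        if self.pop_size < self.min_pop_size:
            raise ValueError("pop_size must be >= min_pop_size")
        if not 0.0 < self.p_best_rate <= 1.0:
            raise ValueError("p_best_rate must lie in (0, 1]")
        if self.memory_size < 1:
            raise ValueError("memory_size must be >= 1")
        if isinstance(self.fitness, str):
            self.fitness = ScoreSpec.parse(self.fitness)

    @property
    def resolved_max_fes(self) -> int:
        return self.max_fes if self.max_fes is not None else default_max_fes(self.k)


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def decode_solution(
    position: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Map a real k-vector in [1, n]^k to k distinct sorted SNP indices.

    Coordinates are rounded half-up and clamped; collisions are repaired by
    redrawing uniformly among indices not already used.
    """
    idx = np.floor(np.asarray(position, dtype=float) + 0.5).astype(np.int64)
    np.clip(idx, 1, n, out=idx)
    unique, first = np.unique(idx, return_index=True)
    n_dup = idx.size - unique.size
    if n_dup:
        unused = np.setdiff1d(np.arange(1, n + 1), unique, assume_unique=True)
        repl = rng.choice(unused, size=n_dup, replace=False)
        dup_slots = np.setdiff1d(np.arange(idx.size), first)
        idx[dup_slots] = repl
    idx.sort()
    return idx


def spherical_offset(
    style: int,
    scale: float,
    d1: float,
    d2: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Offset of exact Euclidean norm ``scale * (d1 + d2)`` in a random
    direction of a 2-D (``style=2``) or 3-D (``style=3``) subspace."""
    r = scale * (d1 + d2)
    if style == 2:
        theta = rng.uniform(0.0, TWO_PI)
        return np.array([r * math.sin(theta), r * math.cos(theta)])
    if style == 3:
        t1 = rng.uniform(0.0, TWO_PI)
        t2 = rng.uniform(0.0, TWO_PI)
        s2 = math.sin(t2)
        return np.array(
            [r * math.sin(t1) * s2, r * math.cos(t1) * s2, r * math.cos(t2)]
        )
    raise ValueError(f"spherical search style must be 2 or 3, got {style}")


def shrink_schedule(pop_size: int, min_pop_size: int, max_fes: int, fes: int) -> int:
    """Linear population-size reduction target after ``fes`` evaluations."""
    if not 0 <= fes <= max_fes:
        raise ValueError("fes must lie in [0, max_fes]")
    return round_half_up(
        (min_pop_size - pop_size) / max_fes * fes + pop_size
    )


class ScaleMemory:
    """Success-history store of effective spherical-search scale factors."""

    def __init__(self, size: int, initial: float = 0.5) -> None:
        self.slots = np.full(size, initial, dtype=float)
        self.cursor = 0

    def update(self, delta_f: Sequence[float], scales: Sequence[float]) -> None:
        """Write the winning-intensity-weighted Lehmer mean of successful
        scales into the current slot; no successes leave the memory
        untouched."""
        if len(delta_f) == 0:
            return
        d = np.asarray(delta_f, dtype=float)
        s = np.asarray(scales, dtype=float)
        w = d / d.sum()
        self.slots[self.cursor] = float((w * s ** 2).sum() / (w * s).sum())
        self.cursor = (self.cursor + 1) % self.slots.size

    def sample(self, rng: np.random.Generator) -> float:
        """Draw a scale from Cauchy(slot, 0.1): truncated above at 1,
        redrawn while non-positive."""
        loc = self.slots[rng.integers(self.slots.size)]
        while True:
            t = loc + 0.1 * rng.standard_cauchy()
            if t > 0.0:
                return min(t, 1.0)


class EpistasisFitness:
    """Memoized oriented-score evaluator over k-SNP combinations.

    Combination keys are sorted 1-based index tuples.  For mixed fitness
    the component bounds must be calibrated (from the initial population)
    before evaluation.
    """

    def __init__(self, ds: GenotypeDataset, spec: ScoreSpec) -> None:
        if ds.has_missing:
            raise DataError("optimizer requires a dataset without missing "
                            "genotypes (run QC first)")
        self.X = np.ascontiguousarray(ds.genotypes)
        self.y = np.ascontiguousarray(ds.phenotype)
        self.spec = spec
        self.cache: dict[tuple[int, ...], float] = {}

    def counts(self, combo: tuple[int, ...]) -> np.ndarray:
        cols = self.X[:, [c - 1 for c in combo]]
        return counts_from_columns(cols, self.y)

    def components(self, combo: tuple[int, ...]) -> list[float]:
        counts = self.counts(combo)
        return [oriented_from_counts(kind, counts) for kind in self.spec.kinds]

    def calibrate(self, combos: Sequence[tuple[int, ...]]) -> None:
        scores = np.array([self.components(c) for c in combos])
        mins = scores.min(axis=0)
        maxs = scores.max(axis=0)
        from dataclasses import replace

        self.spec = replace(
            self.spec,
            mins=tuple(map(float, mins)),
            maxs=tuple(map(float, maxs)),
            constant=tuple(bool(hi <= lo) for lo, hi in zip(mins, maxs)),
        )

    def __call__(self, combo: tuple[int, ...]) -> float:
        f = self.cache.get(combo)
        if f is None:
            if self.spec.is_mixed:
                f = lmse_from_components(self.spec, self.components(combo))
            else:
                f = oriented_from_counts(self.spec.kinds[0], self.counts(combo))
            self.cache[combo] = f
        return f


class GenerationRecord(NamedTuple):
    generation: int
    fes: int
    pop_size: int
    best_fitness: float
    best_combo: tuple[int, ...]
    memory: tuple[float, ...]


@dataclass
class SEEIResult:
    """Outcome of one optimizer run."""

    best_combo: tuple[int, ...]
    best_fitness: float
    top: list[tuple[tuple[int, ...], float]]
    trace: list[GenerationRecord]
    n_evaluations: int
    config: SEEIConfig
    fitness_spec: ScoreSpec


def init_population(
    cfg: SEEIConfig, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform positions a_min + u * (a_max - a_min) on [1, n]^k."""
    if n < cfg.k:
        raise ValueError(f"need at least k={cfg.k} SNPs, dataset has {n}")
    return 1.0 + rng.random((cfg.pop_size, cfg.k)) * (n - 1.0)


def run_seei(ds: GenotypeDataset, cfg: SEEIConfig) -> SEEIResult:
    """Run the full search loop on ``ds`` and return the best combination.

    Every candidate evaluation increments the budget counter exactly once
    (memoized repeats included); the loop stops, mid-generation if
    necessary, as soon as the budget ``max_fes`` is exhausted.  Identical
    seeds give identical results.
    """
    n = ds.n_snps
    max_fes = cfg.resolved_max_fes
    if max_fes < cfg.pop_size:
        raise ValueError("max_fes must cover at least the initial population")
    rng = np.random.default_rng(cfg.seed)
    spec = cfg.fitness if isinstance(cfg.fitness, ScoreSpec) else ScoreSpec.parse(cfg.fitness)
    evaluator = EpistasisFitness(ds, spec)

    pos = init_population(cfg, n, rng)
    combos = [tuple(int(v) for v in decode_solution(p, n, rng)) for p in pos]
    if spec.is_mixed:
        evaluator.calibrate(combos)
    fit = np.array([evaluator(c) for c in combos])
    fes = len(combos)

    best_i = int(np.argmin(fit))
    best_combo, best_fit = combos[best_i], float(fit[best_i])

    memory = ScaleMemory(cfg.memory_size)
    archive: list[np.ndarray] = []
    trace: list[GenerationRecord] = []
    generation = 0

    while fes < max_fes:
        n_pop = fit.size
        order = np.argsort(fit, kind="stable")
        pool = max(2, math.ceil(cfg.p_best_rate * n_pop))
        use_3d = cfg.k >= 3 and generation % 2 == 1
        delta_f: list[float] = []
        win_scales: list[float] = []
        elites: list[np.ndarray] = []

        for i in range(n_pop):
            if fes >= max_fes:
                break
            scale = memory.sample(rng)
            a_pbest = pos[order[rng.integers(pool)]]
            r1 = int(rng.integers(n_pop - 1))
            if r1 >= i:
                r1 += 1
            a_r1 = pos[r1]
            if archive:
                a_h = archive[rng.integers(len(archive))]
            else:
                h = int(rng.integers(n_pop - 1))
                if h >= r1:
                    h += 1
                a_h = pos[h]
            d1 = float(np.linalg.norm(a_pbest - pos[i]))
            d2 = float(np.linalg.norm(a_r1 - a_h))

            if cfg.k == 2:
                dims = np.array([0, 1])
                style = 2
            elif use_3d:
                dims = rng.choice(cfg.k, 3, replace=False)
                style = 3
            else:
                dims = rng.choice(cfg.k, 2, replace=False)
                style = 2

            cand = pos[i].copy()
            cand[dims] += spherical_offset(style, scale, d1, d2, rng)
            # boundary repair: midpoint between the violated bound and the
            # parent coordinate
            for j in dims:
                if cand[j] < 1.0:
                    cand[j] = (1.0 + pos[i, j]) / 2.0
                elif cand[j] > n:
                    cand[j] = (n + pos[i, j]) / 2.0

            combo = tuple(int(v) for v in decode_solution(cand, n, rng))
            f = evaluator(combo)
            fes += 1
            if f < best_fit:
                best_fit, best_combo = f, combo
            if f < fit[i]:
                delta_f.append(float(fit[i] - f))
                win_scales.append(scale)
                elites.append(cand.copy())
                pos[i] = cand
                fit[i] = f
                combos[i] = combo

        memory.update(delta_f, win_scales)
        archive.extend(elites)

        target = shrink_schedule(cfg.pop_size, cfg.min_pop_size, max_fes, fes)
        if target < fit.size:
            keep = np.argsort(fit, kind="stable")[:target]
            pos = pos[keep]
            fit = fit[keep]
            combos = [combos[i] for i in keep]
        cap = round_half_up(cfg.arc_rate * fit.size)
        while len(archive) > cap:
            archive.pop(int(rng.integers(len(archive))))

        trace.append(
            GenerationRecord(
                generation, fes, int(fit.size), best_fit, best_combo,
                tuple(float(s) for s in memory.slots),
            )
        )
        generation += 1

    ranked = sorted(evaluator.cache.items(), key=lambda kv: (kv[1], kv[0]))
    top = [(combo, float(f)) for combo, f in ranked[: cfg.top_k]]
    return SEEIResult(
        best_combo=best_combo,
        best_fitness=float(best_fit),
        top=top,
        trace=trace,
        n_evaluations=fes,
        config=cfg,
        fitness_spec=evaluator.spec,
    )


def exhaustive_search(
    ds: GenotypeDataset, k: int, fitness: str | ScoreSpec = "mi"
) -> tuple[tuple[int, ...], float]:
    """Score every k-combination and return the minimizer (ties broken
    lexicographically).  Mixed fitness is calibrated over all combinations."""
    spec = ScoreSpec.parse(fitness) if isinstance(fitness, str) else fitness
    evaluator = EpistasisFitness(ds, spec)
    all_combos = list(combinations(range(1, ds.n_snps + 1), k))
    if spec.is_mixed and not spec.is_calibrated:
        evaluator.calibrate(all_combos)
    best_combo, best_fit = None, math.inf
    for combo in all_combos:
        f = evaluator(combo)
        if f < best_fit:
            best_combo, best_fit = combo, f
    return best_combo, float(best_fit)
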
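import numpy as np
import pytest
from scipy.stats import kstest

from seei import (
    GenotypeDataset,
    ScaleMemory,
    SEEIConfig,
    decode_solution,
    default_max_fes,
    exhaustive_search,
    init_population,
    run_seei,
    shrink_schedule,
    spherical_offset,
)
from seei.optimizer import EpistasisFitness, round_half_up


class TestConfig:
    def test_default_budget_scales_with_order(self):
        assert default_max_fes(2) == 20000
        assert default_max_fes(3) == 60000
        assert default_max_fes(4) == 80000

    @pytest.mark.parametrize(
        "kwargs", [dict(k=1), dict(min_pop_size=3), dict(p_best_rate=0.0),
                   dict(pop_size=3), dict(memory_size=0)]
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SEEIConfig(**kwargs)


class TestInitPopulation:
    def test_size_and_bounds(self, rng):
        cfg = SEEIConfig(k=2, pop_size=50)
        pop = init_population(cfg, 100, rng)
        assert pop.shape == (50, 2)
        assert (pop >= 1).all() and (pop <= 100).all()

    def test_coordinates_uniform_on_search_space(self, rng):
        cfg = SEEIConfig(k=2, pop_size=5000)
        pop = init_population(cfg, 41, rng)
        stat = kstest(pop.ravel(), "uniform", args=(1, 40))
        assert stat.pvalue > 0.01

    def test_too_few_snps(self, rng):
        with pytest.raises(ValueError):
            init_population(SEEIConfig(k=3), 2, rng)


class TestDecode:
    def test_round_half_up(self, rng):
        assert list(decode_solution(np.array([3.2, 7.8]), 10, rng)) == [3, 8]
        assert list(decode_solution(np.array([2.5, 9.5]), 10, rng)) == [3, 10]

    def test_duplicate_repair_draws_unused_index(self, rng):
        out = decode_solution(np.array([5.4, 4.6]), 10, rng)
        assert 5 in out and len(set(out)) == 2

    def test_property_sweep_sorted_distinct_in_range(self, rng):
        for _ in range(1000):
            k = int(rng.integers(2, 5))
            n = int(rng.integers(k, 20))
            pos = 1 + rng.random(k) * (n - 1)
            out = decode_solution(pos, n, rng)
            assert len(set(out)) == k
            assert list(out) == sorted(out)
            assert out.min() >= 1 and out.max() <= n


class TestSphericalOffset:
    def test_zero_radius(self, rng):
        assert np.allclose(spherical_offset(2, 0.0, 0.0, 0.0, rng), 0.0)

    def test_norm_identity_both_styles(self, rng):
        for _ in range(2000):
            scale = float(rng.uniform(0.01, 1))
            d1, d2 = rng.uniform(0, 10, 2)
            for style in (2, 3):
                off = spherical_offset(style, scale, d1, d2, rng)
                assert len(off) == style
                assert np.linalg.norm(off) == pytest.approx(
                    scale * (d1 + d2), abs=1e-12 * (1 + d1 + d2)
                )

    def test_2d_direction_at_theta_zero(self):
        class FixedRng:
            def uniform(self, lo, hi):
                return 0.0

        off = spherical_offset(2, 0.5, 1.0, 1.0, FixedRng())
        assert off == pytest.approx([0.0, 1.0])

    def test_unknown_style(self, rng):
        with pytest.raises(ValueError):
            spherical_offset(4, 0.5, 1, 1, rng)


class TestScaleMemory:
    def test_single_success_lehmer_mean_is_the_scale(self):
        mem = ScaleMemory(6)
        mem.update([0.7], [0.4])
        assert mem.slots[0] == pytest.approx(0.4)

    def test_equal_weights_hand_example(self):
        # (0.5*0.04 + 0.5*0.36) / (0.5*0.2 + 0.5*0.6) = 0.5
        mem = ScaleMemory(6)
        mem.update([1.0, 1.0], [0.2, 0.6])
        assert mem.slots[0] == pytest.approx(0.5)

    def test_no_success_leaves_slots_unchanged(self):
        mem = ScaleMemory(3)
        before = mem.slots.copy()
        mem.update([], [])
        assert np.array_equal(mem.slots, before)
        assert mem.cursor == 0

    def test_cursor_wraps_circularly(self):
        mem = ScaleMemory(2)
        for s in (0.1, 0.2, 0.3):
            mem.update([1.0], [s])
        assert mem.slots == pytest.approx([0.3, 0.2])

    def test_samples_always_in_unit_interval(self, rng):
        mem = ScaleMemory(4)
        draws = [mem.sample(rng) for _ in range(5000)]
        assert all(0 < t <= 1 for t in draws)

    def test_cauchy_median_matches_conditional_location(self, rng):
        # redrawing non-positive values conditions the Cauchy(0.5, 0.1) on
        # t > 0, shifting its median to
        # 0.5 + 0.1 * tan(pi * (1 - F(0)) / 2 - pi/2 + pi*F(0)/2) ~ 0.50990
        from scipy.stats import cauchy

        f0 = cauchy.cdf(0.0, loc=0.5, scale=0.1)
        expected = cauchy.ppf(f0 + (1 - f0) / 2, loc=0.5, scale=0.1)
        mem = ScaleMemory(3, initial=0.5)
        draws = np.array([mem.sample(rng) for _ in range(100_000)])
        assert np.median(draws) == pytest.approx(expected, abs=0.005)

    def test_truncation_visible_near_upper_bound(self, rng):
        mem = ScaleMemory(3, initial=0.99)
        draws = np.array([mem.sample(rng) for _ in range(2000)])
        assert (draws == 1.0).mean() > 0.2


class TestShrinkSchedule:
    def test_endpoints_and_midpoint(self):
        assert shrink_schedule(50, 4, 20000, 0) == 50
        assert shrink_schedule(50, 4, 20000, 20000) == 4
        assert shrink_schedule(50, 4, 20000, 10000) == 27

    def test_monotone_non_increasing(self):
        sizes = [shrink_schedule(50, 4, 20000, f) for f in range(0, 20001, 97)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_round_half_up_convention(self):
        assert round_half_up(2.5) == 3
        assert round_half_up(-0.5) == 0
        assert shrink_schedule(50, 4, 20000, 5000) == round_half_up(38.5)


def _small_dataset(seed=0, n_snps=12, m=80):
    rng = np.random.default_rng(seed)
    return GenotypeDataset(
        rng.integers(0, 3, size=(m, n_snps)), rng.integers(0, 2, size=m)
    )


class TestRunSeei:
    def test_same_seed_identical_traces(self):
        ds = _small_dataset()
        cfg = SEEIConfig(k=2, fitness="k2", max_fes=800, seed=11)
        r1 = run_seei(ds, cfg)
        r2 = run_seei(ds, SEEIConfig(k=2, fitness="k2", max_fes=800, seed=11))
        assert r1.best_combo == r2.best_combo
        assert r1.trace == r2.trace
        assert r1.top == r2.top

    def test_budget_accounting_exact(self):
        ds = _small_dataset()
        for budget in (137, 500):
            res = run_seei(ds, SEEIConfig(k=2, max_fes=budget, seed=2))
            assert res.n_evaluations == budget
            assert res.trace[-1].fes == budget

    def test_population_follows_reduction_schedule(self):
        ds = _small_dataset()
        cfg = SEEIConfig(k=2, fitness="gini", max_fes=2000, seed=5)
        res = run_seei(ds, cfg)
        sizes = [rec.pop_size for rec in res.trace]
        assert sizes[0] <= cfg.pop_size
        assert sizes[-1] == cfg.min_pop_size
        for rec in res.trace:
            assert rec.pop_size == shrink_schedule(
                cfg.pop_size, cfg.min_pop_size, cfg.resolved_max_fes, rec.fes
            )
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_single_combination_space(self):
        ds = _small_dataset(n_snps=2)
        res = run_seei(ds, SEEIConfig(k=2, max_fes=60, seed=1))
        assert res.best_combo == (1, 2)

    def test_best_is_min_over_all_evaluated(self):
        ds = _small_dataset(seed=3)
        res = run_seei(ds, SEEIConfig(k=2, fitness="mi", max_fes=600, seed=4))
        assert res.top[0][0] == res.best_combo
        assert res.top[0][1] == res.best_fitness
        fits = [f for _, f in res.top]
        assert fits == sorted(fits)

    def test_mixed_fitness_runs_and_calibrates(self):
        ds = _small_dataset(seed=6)
        res = run_seei(ds, SEEIConfig(k=2, fitness="k2-mi", max_fes=400,
                                      seed=7))
        assert res.fitness_spec.is_calibrated
        assert all(0.0 <= f <= 2.0 for _, f in res.top)

    def test_three_order_search(self):
        ds = _small_dataset(seed=8, n_snps=8)
        res = run_seei(ds, SEEIConfig(k=3, fitness="mi", max_fes=900, seed=9))
        assert len(res.best_combo) == 3
        assert len(set(res.best_combo)) == 3

    def test_errors_on_infeasible_setup(self):
        ds = _small_dataset(n_snps=2)
        with pytest.raises(ValueError):
            run_seei(ds, SEEIConfig(k=3, max_fes=500))
        with pytest.raises(ValueError):
            run_seei(ds, SEEIConfig(k=2, max_fes=10))

    def test_finds_exhaustive_optimum_on_planted_pair(self, xor_dataset):
        ds, _ = xor_dataset
        target, f_target = exhaustive_search(ds, 2, "mi")
        hits = 0
        for seed in range(10):
            res = run_seei(ds, SEEIConfig(k=2, fitness="mi", max_fes=3000,
                                          seed=seed))
            hits += res.best_fitness <= f_target + 1e-12
        assert hits >= 9


class TestEvaluatorBookkeeping:
    def test_cache_hits_do_not_change_scores(self):
        ds = _small_dataset()
        ev = EpistasisFitness(ds, __import__("seei").ScoreSpec.parse("mi"))
        f1 = ev((3, 7))
        f2 = ev((3, 7))
        assert f1 == f2 and len(ev.cache) == 1

    def test_missing_data_rejected(self):
        from seei import MISSING, DataError

        gt = np.zeros((10, 3), dtype=int)
        gt[0, 0] = MISSING
        gt[:, 1] = 1
        ds = GenotypeDataset(gt, np.tile([0, 1], 5))
        with pytest.raises(DataError):
            EpistasisFitness(ds, __import__("seei").ScoreSpec.parse("mi"))
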
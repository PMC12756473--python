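"""Sparrow-search mechanics: repair, role updates, fitness, optimization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssafbcsp import (
    FitnessEvaluator,
    SSAConfig,
    SynthConfig,
    bank_from_position,
    generate_epochs,
    make_uniform_bank,
    optimize,
    position_from_bank,
    repair,
)
from ssafbcsp.exceptions import ConfigurationError
from ssafbcsp.ssa import (
    follower_update,
    init_population,
    producer_update,
    watcher_update,
)

CFG = SSAConfig(pop_size=6, max_iter=10, n_bands=2, seed=0)


class ToyEvaluator:
    """Deterministic toy fitness: closeness of the bank to a target bank."""

    def __init__(self, target):
        self.target = np.asarray(target, dtype=float)
        self.n_evaluations = 0

    def __call__(self, position):
        self.n_evaluations += 1
        return float(np.exp(-np.linalg.norm(position - self.target) / 50.0))


class TestRepair:
    def test_swap_rule(self):
        out = repair([10.0, 7.0, 20.0, 25.0], CFG)
        assert bank_from_position(out).edges() == [[7.0, 10.0], [20.0, 25.0]]

    def test_clip_rule(self):
        out = repair([2.0, 45.0, 10.0, 12.0], CFG)
        assert [4.0, 40.0] in bank_from_position(out).edges()

    def test_min_width_at_upper_boundary(self):
        out = repair([40.0, 40.0, 10.0, 12.0], CFG)
        assert [39.5, 40.0] in bank_from_position(out).edges()

    def test_pairs_sorted_by_low_edge(self):
        out = repair([30.0, 35.0, 5.0, 9.0], CFG)
        edges = bank_from_position(out).edges()
        assert edges == sorted(edges)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(min_value=-100, max_value=200,
                              allow_nan=False), min_size=4, max_size=4))
    def test_total_on_arbitrary_vectors(self, values):
        out = repair(values, CFG)
        bank = bank_from_position(out)  # must not raise
        for band in bank:
            assert CFG.f_min <= band.low < band.high <= CFG.f_max
            assert band.width >= CFG.w_min - 1e-9


class TestRoleUpdates:
    x = np.array([10.0, 14.0, 20.0, 28.0])

    def test_producer_zero_jump_is_identity(self, rng):
        out = producer_update(self.x, 3, CFG, rng, r2=0.95, q=0.0)
        np.testing.assert_array_equal(out, self.x)

    def test_producer_shrink_closed_form(self, rng):
        out = producer_update(self.x, CFG.max_iter, CFG, rng, r2=0.1, alpha=1.0)
        np.testing.assert_allclose(out, self.x * math.exp(-1.0), rtol=1e-12)

    def test_producer_reproducible(self):
        a = producer_update(self.x, 2, CFG, np.random.default_rng(5))
        b = producer_update(self.x, 2, CFG, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_follower_fixed_point_at_best(self, rng):
        out = follower_update(self.x, 3, CFG, rng, x_best=self.x, q=0.0)
        np.testing.assert_allclose(out, self.x)

    def test_follower_unit_step_reaches_best(self, rng):
        best = np.array([8.0, 12.0, 16.0, 24.0])
        out = follower_update(self.x, 3, CFG, rng, x_best=best, q=0.0, step=1.0)
        np.testing.assert_allclose(out, best)

    def test_follower_step_decay_vanishes_at_final_iteration(self, rng):
        """At t = T the adaptive term is zero: step is the dimension decay."""
        best = np.zeros(4)
        r = 0.7
        out = follower_update(self.x, CFG.max_iter, CFG, rng, x_best=best,
                              r=r, q=0.0)
        j = np.arange(1, 5)
        step = r * np.exp(-j / 4.0)
        np.testing.assert_allclose(out, self.x + step * (best - self.x),
                                   rtol=1e-12)

    def test_watcher_noise_vanishes_at_final_iteration(self, rng):
        best = np.array([8.0, 12.0, 16.0, 24.0])
        out = watcher_update(self.x, 0.5, CFG.max_iter, CFG, rng,
                             x_best=best, f_best=0.9, f_worst=0.1, beta=0.25)
        np.testing.assert_allclose(out, best + 0.25 * np.abs(self.x - best),
                                   rtol=1e-12)

    def test_watcher_degenerate_draws_reach_best(self, rng):
        best = np.array([8.0, 12.0, 16.0, 24.0])
        out = watcher_update(self.x, 0.5, 2, CFG, rng, x_best=best,
                             f_best=0.9, f_worst=0.1, beta=0.0, noise=0.0)
        np.testing.assert_allclose(out, best)

    def test_watcher_sigma_is_search_range_width(self):
        assert CFG.sigma == 36.0

    def test_watcher_best_branch_inverse_fitness_gap(self, rng):
        best = np.array([8.0, 12.0, 16.0, 24.0])
        f_b, f_w, k = 0.9, 0.4, 0.3
        out = watcher_update(self.x, f_b, 2, CFG, rng, x_best=best,
                             f_best=f_b, f_worst=f_w, k=k)
        expected = best + k * (self.x - best) / (abs(f_b - f_w) + CFG.epsilon)
        np.testing.assert_allclose(out, expected, rtol=1e-12)

    def test_classic_and_improved_watchers_coincide_when_degenerate(self, rng):
        classic_cfg = SSAConfig(pop_size=6, max_iter=10, n_bands=2, seed=0,
                                use_classic_watcher=True)
        best = np.array([8.0, 12.0, 16.0, 24.0])
        improved = watcher_update(self.x, 0.5, 2, CFG, rng, x_best=best,
                                  f_best=0.9, f_worst=0.1, beta=0.4, noise=0.0)
        classic = watcher_update(self.x, 0.5, 2, classic_cfg, rng, x_best=best,
                                 f_best=0.9, f_worst=0.1, beta=0.4)
        np.testing.assert_allclose(improved, classic)

    def test_classic_follower_better_half_fixed_point(self, rng):
        classic_cfg = SSAConfig(pop_size=6, max_iter=10, n_bands=2, seed=0,
                                use_classic_follower=True)
        out = follower_update(self.x, 2, classic_cfg, rng, x_best=self.x,
                              rank=5, n_followers=6, x_worst=self.x * 0.5)
        np.testing.assert_allclose(out, self.x)


class TestInitPopulation:
    def test_warm_start_is_uniform_bank(self, rng):
        cfg = SSAConfig(pop_size=15, max_iter=5, n_bands=10, seed=1)
        positions = init_population(cfg, rng)
        assert positions.shape == (15, 20)
        expected = position_from_bank(make_uniform_bank(10, cfg.f_min, cfg.f_max))
        np.testing.assert_allclose(positions[0], expected)
        for p in positions:
            bank_from_position(p)  # all decode to valid banks

    def test_deterministic(self):
        cfg = SSAConfig(pop_size=8, max_iter=5, n_bands=3, seed=2)
        a = init_population(cfg, np.random.default_rng(3))
        b = init_population(cfg, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)


class TestFitnessEvaluator:
    def test_separable_data_high_fitness(self, separable_epochs):
        cfg = SSAConfig(pop_size=4, max_iter=2, n_bands=4, seed=0)
        evaluator = FitnessEvaluator(separable_epochs, cfg)
        bank_pos = np.array([8.0, 16.0, 16.0, 24.0, 24.0, 32.0, 4.0, 8.0])
        assert evaluator(repair(bank_pos, cfg)) >= 0.9

    def test_permuted_labels_give_chance_fitness(self, separable_epochs):
        from ssafbcsp import EpochSet

        perm = np.random.default_rng(21).permutation(separable_epochs.n_trials)
        shuffled = EpochSet(
            data=separable_epochs.data,
            labels=separable_epochs.labels[perm],
            fs=separable_epochs.fs,
        )
        cfg = SSAConfig(pop_size=4, max_iter=2, n_bands=4, seed=0)
        fitness = FitnessEvaluator(shuffled, cfg)(
            position_from_bank(make_uniform_bank(4))
        )
        n = separable_epochs.n_trials
        half_width = 2.576 * np.sqrt(0.25 / n)
        assert 0.5 - half_width <= fitness <= 0.5 + half_width

    def test_deterministic_and_cached(self, mi_epochs_small):
        cfg = SSAConfig(pop_size=4, max_iter=2, n_bands=2, cv_folds=3, seed=4)
        pos = position_from_bank(make_uniform_bank(2, 4.0, 30.0))
        ev1 = FitnessEvaluator(mi_epochs_small, cfg)
        ev2 = FitnessEvaluator(mi_epochs_small, cfg)
        v1, v2 = ev1(pos), ev2(pos)
        assert v1 == v2
        assert ev1(pos) == v1
        assert ev1.n_evaluations == 1  # second call served from cache

    def test_too_few_trials_per_class_rejected(self, mi_epochs_small):
        cfg = SSAConfig(pop_size=4, max_iter=2, n_bands=2, cv_folds=20, seed=0)
        with pytest.raises(ValueError, match="fold"):
            FitnessEvaluator(mi_epochs_small, cfg)


class TestOptimize:
    target = position_from_bank(bank_from_position([10.0, 14.0, 20.0, 28.0]))

    def test_elitism_history_nondecreasing_across_seeds(self):
        for seed in range(10):
            cfg = SSAConfig(pop_size=6, max_iter=8, n_bands=2, seed=seed)
            res = optimize(None, cfg, evaluator=ToyEvaluator(self.target))
            assert all(a <= b for a, b in zip(res.history, res.history[1:]))
            assert res.best_fitness == res.history[-1]

    def test_zero_iterations_returns_initial_best(self):
        cfg = SSAConfig(pop_size=6, max_iter=0, n_bands=2, seed=3)
        res = optimize(None, cfg, evaluator=ToyEvaluator(self.target))
        assert len(res.history) == 1
        assert res.evaluations == cfg.pop_size

    def test_empty_role_mask_only_evaluates_initial_population(self):
        cfg = SSAConfig(pop_size=6, max_iter=5, n_bands=2, seed=3)
        res = optimize(None, cfg, role_mask=(), evaluator=ToyEvaluator(self.target))
        init_best = optimize(
            None, SSAConfig(pop_size=6, max_iter=0, n_bands=2, seed=3),
            evaluator=ToyEvaluator(self.target),
        )
        assert res.best_fitness == init_best.best_fitness
        assert res.evaluations == cfg.pop_size

    def test_every_evaluated_position_is_feasible(self):
        class RecordingEvaluator(ToyEvaluator):
            def __init__(self, target):
                super().__init__(target)
                self.seen = []

            def __call__(self, position):
                self.seen.append(np.array(position))
                return super().__call__(position)

        cfg = SSAConfig(pop_size=6, max_iter=6, n_bands=2, seed=1)
        ev = RecordingEvaluator(self.target)
        optimize(None, cfg, evaluator=ev)
        assert len(ev.seen) > cfg.pop_size
        for pos in ev.seen:
            bank_from_position(pos)  # must not raise

    def test_unknown_role_rejected(self):
        cfg = SSAConfig(pop_size=4, max_iter=2, n_bands=2, seed=0)
        with pytest.raises(ConfigurationError):
            optimize(None, cfg, role_mask={"sentries"},
                     evaluator=ToyEvaluator(self.target))

    def test_warm_start_beats_uniform_bank_on_training_fitness(
        self, separable_epochs
    ):
        cfg = SSAConfig(pop_size=5, max_iter=3, n_bands=4, seed=2)
        evaluator = FitnessEvaluator(separable_epochs, cfg)
        uniform_fitness = evaluator(position_from_bank(make_uniform_bank(4)))
        res = optimize(separable_epochs, cfg, evaluator=evaluator)
        assert res.best_fitness >= uniform_fitness
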
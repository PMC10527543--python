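"""Unit and property tests for the Artificial Rabbits Algorithm core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from leafara.ara import (
    ARAConfig,
    StepRandoms,
    ara_optimize,
    detour_foraging_step,
    dimension_selector,
    energy_factor,
    random_burrow,
    random_hiding_step,
    running_length,
)


def sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


class TestRunningLength:
    @pytest.mark.parametrize(
        "t,T,R2,expected",
        [
            (1, 10, 0.25, math.e - 1.0),  # exponent 0, sin(pi/2)=1
            (1, 3, 0.5, 0.0),  # sin(pi)=0
            (7, 9, 0.5, 0.0),
            (10, 10, 0.25, (math.e - math.exp(0.81)) * 1.0),
        ],
    )
    def test_closed_form(self, t, T, R2, expected):
        assert running_length(t, T, R2) == pytest.approx(expected, abs=1e-9)

    def test_envelope_bound(self):
        for t, T, R2 in [(1, 5, 0.1), (3, 5, 0.9), (5, 5, 0.77)]:
            assert abs(running_length(t, T, R2)) <= math.e - 1 + 1e-12

    def test_iteration_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            running_length(0, 10, 0.5)
        with pytest.raises(ValueError):
            running_length(11, 10, 0.5)


class TestDimensionSelector:
    def test_single_dimension_always_selected(self):
        assert dimension_selector(1, 0.0, np.array([0])).tolist() == [1.0]

    def test_full_selection(self):
        c = dimension_selector(3, 1.0, np.array([2, 0, 1]))
        assert c.tolist() == [1.0, 1.0, 1.0]

    def test_partial_selection_follows_permutation(self):
        # ceil(0.4*4)=2: dims 3 and 1 (1-based) -> indices 2 and 0
        c = dimension_selector(4, 0.4, np.array([2, 0, 3, 1]))
        assert c.tolist() == [1.0, 0.0, 1.0, 0.0]

    @settings(deadline=None, derandomize=True)
    @given(st.integers(1, 12), st.floats(0, 1), st.randoms(use_true_random=False))
    def test_count_property(self, D, R, rnd):
        g = np.array(rnd.sample(range(D), D))
        c = dimension_selector(D, R, g)
        assert c.sum() == max(1, math.ceil(R * D))
        assert set(np.unique(c)) <= {0.0, 1.0}


class TestDetourForaging:
    def test_zero_movement_returns_peer(self):
        out = detour_foraging_step([3.0, 4.0], [1.0, 2.0], [0.0, 0.0], 0.3, [1.0, 1.0])
        assert out.tolist() == [1.0, 2.0]

    def test_identity_when_positions_coincide(self):
        out = detour_foraging_step([2.0, 2.0], [2.0, 2.0], [0.5, 0.5], 0.9, [1.0, 1.0])
        assert out.tolist() == [2.0, 2.0]

    def test_hand_example(self):
        out = detour_foraging_step([3.0, 4.0], [1.0, 2.0], [0.5, 0.5], 0.9, [1.0, 1.0])
        assert out == pytest.approx([2.0, 3.0])

    def test_round_offset_modes(self):
        # printed mode: offset 0 for R1 < 1; aro_compat fires at R1 >= 0.95
        a = detour_foraging_step([1.0], [0.0], [1.0], 0.96, [1.0], "printed")
        b = detour_foraging_step([1.0], [0.0], [1.0], 0.96, [1.0], "aro_compat")
        assert a.item() == pytest.approx(1.0)
        assert b.item() == pytest.approx(2.0)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            detour_foraging_step([1.0], [1.0, 2.0], [1.0], 0.5, [1.0])


class TestEnergyFactor:
    @pytest.mark.parametrize(
        "t,T,R4,expected",
        [
            (10, 10, 0.3, 0.0),
            (3, 7, 1.0, 0.0),
            (5, 10, math.exp(-1), 2.0),
        ],
    )
    def test_closed_form(self, t, T, R4, expected):
        assert energy_factor(t, T, R4) == pytest.approx(expected, abs=1e-9)

    def test_zero_r4_rejected(self):
        with pytest.raises(ValueError):
            energy_factor(1, 10, 0.0)


class TestRandomHiding:
    def test_hiding_parameter_at_final_iteration(self):
        _, _, H = random_burrow(np.array([1.0, 1.0]), 10, 10, 1.0, 0.3)
        assert H == pytest.approx(0.1, abs=1e-9)

    def test_one_hot_selector_index(self):
        _, g_r, _ = random_burrow(np.zeros(4), 1, 10, 0.5, 0.4)
        assert g_r.tolist() == [0.0, 1.0, 0.0, 0.0]  # ceil(0.4*4)=2 -> 2nd dim

    def test_burrow_perturbs_single_dimension(self):
        b, g_r, H = random_burrow(np.array([2.0, 4.0]), 1, 2, 1.0, 0.9)
        assert H == pytest.approx(1.0)
        assert b.tolist() == [2.0, 8.0]  # 4*(1+1) at the selected dim
        assert int(g_r.sum()) == 1

    def test_burrow_value_hand_example(self):
        # H = 0.5 requires (T-t+1)/T * n2 = 0.5: t=T=2, n2=1
        b, _, H = random_burrow(np.array([2.0, 4.0]), 2, 2, 1.0, 0.9)
        assert H == pytest.approx(0.5)
        assert b.tolist() == [2.0, 6.0]

    def test_step_closed_forms(self):
        X = np.array([2.0, 4.0])
        assert random_hiding_step(X, [0.0, 0.0], 0.7, [9.0, 9.0]).tolist() == [2.0, 4.0]
        assert random_hiding_step(X, [1.0, 1.0], 1.0, [2.0, 6.0]).tolist() == [2.0, 6.0]
        assert random_hiding_step(X, [1.0, 1.0], 0.0, [5.0, 5.0]).tolist() == [0.0, 0.0]


def _config(**kw):
    base = dict(population_size=10, max_iterations=50, dimensions=2,
                lower_bounds=[-5, -5], upper_bounds=[5, 5], seed=0)
    base.update(kw)
    return ARAConfig(**base)


class TestOptimizer:
    def test_constant_objective(self):
        _, best, trace = ara_optimize(lambda x: 7.5, _config(max_iterations=5))
        assert best == 7.5
        assert trace.best_fitness == [7.5] * 5

    def test_trace_monotone_and_bounds(self):
        seen = []
        cfg = _config(seed=3)
        _, _, trace = ara_optimize(lambda x: seen.append(x.copy()) or sphere(x), cfg)
        bf = trace.best_fitness
        assert all(a >= b for a, b in zip(bf, bf[1:]))
        assert len(bf) == cfg.max_iterations
        pos = np.array(seen[cfg.population_size :])  # post-init candidates are clipped
        assert (pos >= -5 - 1e-12).all() and (pos <= 5 + 1e-12).all()

    def test_reproducible_given_seed(self):
        r1 = ara_optimize(sphere, _config(seed=11))
        r2 = ara_optimize(sphere, _config(seed=11))
        assert np.array_equal(r1[0], r2[0])
        assert r1[2].best_fitness == r2[2].best_fitness
        assert r1[2].n_explore == r2[2].n_explore

    def test_sphere_improvement_rate(self):
        wins = 0
        for seed in range(20):
            cfg = _config(seed=seed)
            rng = np.random.default_rng(seed)
            init = rng.uniform(-5, 5, size=(10, 2))  # not the same draw; compare to trace
            _, best, trace = ara_optimize(sphere, cfg)
            if best < trace.best_fitness[0] or best < 1e-3:
                wins += 1
        assert wins >= 19

    def test_quadratic_recovery_rate(self):
        hits = 0
        for seed in range(20):
            cfg = ARAConfig(15, 100, 1, [-5.0], [5.0], seed=seed)
            best_x, _, _ = ara_optimize(lambda x: (x[0] - 1.0) ** 2, cfg)
            hits += abs(best_x[0] - 1.0) < 0.1
        assert hits >= 18

    def test_minimal_population_runs(self):
        _, best, trace = ara_optimize(sphere, _config(population_size=2, max_iterations=10))
        assert len(trace.best_fitness) == 10
        assert math.isfinite(best)

    def test_exploration_fraction_decays_over_iterations(self):
        """E shrinks linearly in t, so exploration counts trend downward."""
        T = 30
        counts = np.zeros(T)
        for seed in range(30):
            _, _, trace = ara_optimize(sphere, _config(seed=seed, max_iterations=T, population_size=8))
            counts += np.array(trace.n_explore)
        slope = np.polyfit(np.arange(1, T + 1), counts / 30, 1)[0]
        assert slope < 0

    def test_non_finite_objective_reported_with_position(self):
        with pytest.raises(ValueError, match="position"):
            ara_optimize(lambda x: float("nan"), _config(max_iterations=2))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            _config(population_size=1)
        with pytest.raises(ValueError):
            _config(lower_bounds=[5, 5], upper_bounds=[-5, -5])
        with pytest.raises(ValueError):
            _config(round_mode="nearest")


def test_step_randoms_draw_shapes():
    sr = StepRandoms.draw(np.random.default_rng(0), 5)
    assert sorted(sr.g.tolist()) == [0, 1, 2, 3, 4]
    assert sr.n1.shape == (5,)
    for v in (sr.R1, sr.R2, sr.R4, sr.R5, sr.R6):
        assert 0.0 <= v <= 1.0
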
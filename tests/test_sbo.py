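import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sbocad import sbo


def box_config(dim=2, lo=0.0, hi=1.0, **kw):
    defaults = dict(population_size=8, max_iterations=5)
    defaults.update(kw)
    return sbo.SBOConfig(lower_bounds=np.full(dim, lo),
                         upper_bounds=np.full(dim, hi), **defaults)


class TestFitnessMapping:
    @pytest.mark.parametrize("f,expected", [(0.0, 1.0), (1.0, 0.5), (-1.0, 2.0),
                                            (3.0, 0.25), (-0.5, 1.5)])
    def test_closed_forms(self, f, expected):
        assert sbo.fitness_of(f) == pytest.approx(expected)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            sbo.fitness_of(float("nan"))

    @given(st.floats(-1e6, 1e6))
    def test_always_positive(self, f):
        assert sbo.fitness_of(f) > 0

    @given(st.floats(0, 1e6), st.floats(0, 1e6))
    def test_order_reversing_for_nonneg(self, a, b):
        lo, hi = sorted((a, b))
        assert sbo.fitness_of(lo) >= sbo.fitness_of(hi)


class TestSelectionProbs:
    def test_uniform_for_equal_fitness(self):
        p = sbo.selection_probs(np.ones(5))
        assert np.allclose(p, 0.2)

    def test_direct_ratio(self):
        assert np.allclose(sbo.selection_probs(np.array([1.0, 3.0])),
                           [0.25, 0.75])

    @given(st.lists(st.floats(1e-6, 1e6), min_size=1, max_size=30))
    def test_is_distribution(self, fits):
        p = sbo.selection_probs(np.array(fits))
        assert abs(p.sum() - 1.0) < 1e-12
        assert np.all(p >= 0) and np.all(p <= 1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sbo.selection_probs(np.array([]))


class TestStepSize:
    @pytest.mark.parametrize("alpha,prob,expected",
                             [(1.0, 0.0, 1.0), (1.0, 1.0, 0.5),
                              (2.0, 0.5, 4.0 / 3.0)])
    def test_closed_forms(self, alpha, prob, expected):
        assert sbo.step_size(alpha, prob) == pytest.approx(expected)

    def test_bounded_in_half_alpha_alpha(self):
        for p in np.linspace(0, 1, 11):
            lam = sbo.step_size(0.94, p)
            assert 0.47 <= lam <= 0.94

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            sbo.step_size(-1.0, 0.5)


class TestInitPopulation:
    def test_within_bounds_and_sized(self, rng):
        cfg = box_config(dim=5, lo=-2.0, hi=3.0, population_size=200)
        pop = sbo.init_population(cfg, rng)
        assert pop.shape == (200, 5)
        assert np.all(pop >= -2.0) and np.all(pop <= 3.0)

    def test_degenerate_thin_box(self, rng):
        eps = 1e-9
        cfg = sbo.SBOConfig(population_size=10, max_iterations=1,
                            lower_bounds=np.array([0.5]),
                            upper_bounds=np.array([0.5 + eps]))
        pop = sbo.init_population(cfg, rng)
        assert np.all(np.abs(pop - 0.5) <= eps)

    def test_seed_determinism(self):
        cfg = box_config(dim=3)
        a = sbo.init_population(cfg, np.random.default_rng(5))
        b = sbo.init_population(cfg, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            box_config(lo=1.0, hi=0.0)


class TestUpdatePositions:
    def test_fixed_point_when_all_equal(self, rng):
        cfg = box_config(dim=3, lo=-1.0, hi=1.0, population_size=4)
        pos = np.full((4, 3), 0.25)
        probs = np.full(4, 0.25)
        out = sbo.update_positions(pos, probs, pos[0], cfg, rng)
        assert np.allclose(out, 0.25)

    def test_midpoint_hand_example(self, rng):
        # lambda = alpha/(1+prob(target)) = 2/(1+1) = 1 when the target has
        # probability 1; new = 0 + 1*((2+4)/2 - 0) = 3
        cfg = box_config(dim=1, lo=-10.0, hi=10.0, population_size=2,
                         alpha_max=2.0)
        pos = np.array([[0.0], [2.0]])
        probs = np.array([0.0, 1.0])  # roulette always picks bower 1
        out = sbo.update_positions(pos, probs, np.array([4.0]), cfg, rng)
        assert out[0, 0] == pytest.approx(3.0)

    def test_clipped_to_box(self, rng):
        cfg = box_config(dim=4, lo=0.0, hi=1.0, population_size=12,
                         alpha_max=5.0)
        pos = sbo.init_population(cfg, rng)
        probs = sbo.selection_probs(np.ones(12))
        out = sbo.update_positions(pos, probs, np.ones(4), cfg, rng)
        assert np.all(out >= 0.0) and np.all(out <= 1.0)


class TestMutate:
    def test_zero_probability_is_noop(self, rng):
        cfg = box_config(dim=3, mutation_prob=0.0)
        pos = sbo.init_population(cfg, rng)
        assert np.array_equal(sbo.mutate(pos, cfg, rng), pos)

    def test_zero_variance_ratio_is_noop(self, rng):
        cfg = box_config(dim=3, mutation_prob=1.0, variance_ratio=0.0)
        pos = sbo.init_population(cfg, rng)
        assert np.array_equal(sbo.mutate(pos, cfg, rng), pos)

    def test_perturbation_scale_monte_carlo(self, rng):
        # std of the kick should match variance_ratio * box width within 5%
        cfg = sbo.SBOConfig(population_size=10_000, max_iterations=1,
                            mutation_prob=1.0, variance_ratio=0.02,
                            lower_bounds=np.array([0.0]),
                            upper_bounds=np.array([1.0]))
        pos = np.full((10_000, 1), 0.5)
        delta = sbo.mutate(pos, cfg, rng) - pos
        assert delta.std() == pytest.approx(0.02, rel=0.05)


class TestOptimize:
    def test_1d_quadratic_reaches_optimum(self):
        cfg = sbo.SBOConfig(population_size=20, max_iterations=60, seed=3,
                            lower_bounds=np.array([-2.0]),
                            upper_bounds=np.array([2.0]))
        res = sbo.optimize(lambda x: float((x[0] - 0.3) ** 2), cfg)
        assert abs(res.best_position[0] - 0.3) < 0.01

    def test_constant_objective_flat_history(self):
        cfg = box_config(dim=2, max_iterations=10, seed=0)
        res = sbo.optimize(lambda x: 7.0, cfg)
        assert res.history == [7.0] * 10

    def test_history_monotone_non_increasing(self):
        cfg = sbo.SBOConfig(population_size=15, max_iterations=40, seed=11,
                            lower_bounds=np.full(3, -5.0),
                            upper_bounds=np.full(3, 5.0))
        res = sbo.optimize(lambda x: float(x @ x), cfg)
        assert all(a >= b for a, b in zip(res.history, res.history[1:]))

    def test_bit_reproducible(self):
        cfg = box_config(dim=2, max_iterations=15, seed=42)
        obj = lambda x: float(np.sin(x[0]) + x[1] ** 2)
        a = sbo.optimize(obj, cfg)
        b = sbo.optimize(obj, cfg)
        assert np.array_equal(a.best_position, b.best_position)
        assert a.history == b.history

    def test_non_finite_objective_treated_as_worst(self):
        cfg = box_config(dim=1, lo=-1.0, hi=1.0, max_iterations=10, seed=2)
        def obj(x):
            return float("nan") if x[0] > 0 else float(x[0] ** 2)
        res = sbo.optimize(obj, cfg)
        assert np.isfinite(res.best_objective)
        assert res.best_position[0] <= 0

    def test_initial_seeding_never_worse(self):
        cfg = box_config(dim=2, lo=-1.0, hi=1.0, max_iterations=0, seed=9)
        start = np.array([0.1, -0.1])
        res = sbo.optimize(lambda x: float(x @ x), cfg, initial=start)
        assert res.best_objective <= float(start @ start)

    def test_result_serializable(self):
        import json
        cfg = box_config(dim=1, max_iterations=3, seed=1)
        res = sbo.optimize(lambda x: float(x[0] ** 2), cfg)
        payload = json.loads(json.dumps(res.to_dict()))
        assert payload["seed"] == 1
        assert len(payload["history"]) == 3


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 1000))
def test_all_positions_stay_in_box_property(seed):
    rng = np.random.default_rng(seed)
    cfg = sbo.SBOConfig(population_size=6, max_iterations=1, seed=seed,
                        alpha_max=3.0, mutation_prob=0.5,
                        lower_bounds=np.array([-1.0, 0.0]),
                        upper_bounds=np.array([1.0, 2.0]))
    pos = sbo.init_population(cfg, rng)
    probs = sbo.selection_probs(np.ones(6))
    pos = sbo.update_positions(pos, probs, pos[0], cfg, rng)
    pos = sbo.mutate(pos, cfg, rng)
    assert np.all(pos >= cfg.lower_bounds) and np.all(pos <= cfg.upper_bounds)
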
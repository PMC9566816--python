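import numpy as np
import pytest

from sparrowkelm.benchmarks import make_benchmark
from sparrowkelm.ssa import (
    SwarmConfig,
    init_population,
    optimize_ssa,
    producer_update_ssa,
    save_curve,
    scout_update,
    scrounger_update,
)


def sphere(x):
    return float(np.sum(x**2))


def make_state(positions, fitnesses, config, rng, best=None, worst=None):
    from sparrowkelm.ssa import SwarmState

    positions = np.asarray(positions, dtype=float)
    fitnesses = np.asarray(fitnesses, dtype=float)
    i_best = int(np.argmin(fitnesses))
    i_worst = int(np.argmax(fitnesses))
    return SwarmState(
        positions=positions,
        fitnesses=fitnesses,
        best_position=positions[i_best].copy() if best is None else np.asarray(best, float),
        best_fitness=float(fitnesses[i_best]),
        worst_position=positions[i_worst].copy() if worst is None else np.asarray(worst, float),
        worst_fitness=float(fitnesses[i_worst]),
        rng=rng,
    )


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SwarmConfig(pop_size=1, dim=2, lower=0, upper=1, iter_max=10)
        with pytest.raises(ValueError):
            SwarmConfig(pop_size=5, dim=2, lower=0, upper=1, iter_max=10, ST=0.4)
        with pytest.raises(ValueError):
            SwarmConfig(pop_size=5, dim=2, lower=1, upper=0, iter_max=10)

    def test_counts(self):
        cfg = SwarmConfig(pop_size=30, dim=2, lower=0, upper=1, iter_max=10)
        assert cfg.n_producers == 6
        assert cfg.n_scouts == 3


class TestInitPopulation:
    def test_shape_and_bounds(self):
        cfg = SwarmConfig(pop_size=5, dim=2, lower=0, upper=1, iter_max=10, seed=1)
        st = init_population(cfg, sphere)
        assert st.positions.shape == (5, 2)
        assert np.all((st.positions >= 0) & (st.positions <= 1))
        assert st.convergence_curve == []

    def test_same_seed_identical(self):
        cfg = SwarmConfig(pop_size=5, dim=2, lower=0, upper=1, iter_max=10, seed=7)
        a = init_population(cfg, sphere)
        b = init_population(cfg, sphere)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.fitnesses, b.fitnesses)

    def test_degenerate_bounds(self):
        cfg = SwarmConfig(pop_size=4, dim=3, lower=2.0, upper=2.0, iter_max=5, seed=0)
        st = init_population(cfg, sphere)
        assert np.all(st.positions == 2.0)


class TestProducerUpdate(object):
    def test_safe_branch_multiplier(self, scripted_rng):
        # R2 = 0.5 < ST; rank 1, alpha = 0.5, iter_max = 100 -> exp(-1/50)
        cfg = SwarmConfig(pop_size=5, dim=2, lower=-10, upper=10, iter_max=100)
        rng = scripted_rng(uniform=[0.5], random=[np.array([0.5])])
        st = make_state([[2.0, -3.0]] * 5, [1, 2, 3, 4, 5], cfg, rng)
        producer_update_ssa(st, cfg, np.array([0]))
        assert st.positions[0] == pytest.approx(
            np.array([2.0, -3.0]) * np.exp(-1 / 50.0)
        )

    def test_alarm_branch_zero_step(self, scripted_rng):
        cfg = SwarmConfig(pop_size=5, dim=2, lower=-10, upper=10, iter_max=100)
        rng = scripted_rng(uniform=[0.9], standard_normal=[np.array([0.0])])
        st = make_state([[2.0, -3.0]] * 5, [1, 2, 3, 4, 5], cfg, rng)
        producer_update_ssa(st, cfg, np.array([0]))
        assert st.positions[0] == pytest.approx([2.0, -3.0])

    def test_safe_branch_never_grows_magnitude(self, scripted_rng):
        # exp(-i / (alpha iter_max)) lies in (0, 1], so any safe-branch
        # update can only shrink coordinate magnitudes
        cfg = SwarmConfig(pop_size=10, dim=3, lower=-10, upper=10, iter_max=50)
        for alpha in (0.01, 0.5, 0.999):
            rng = scripted_rng(uniform=[0.1], random=[np.array([1 - alpha, 1 - alpha])])
            st = make_state(
                np.tile([[4.0, -6.0, 0.5]], (10, 1)), np.arange(10), cfg, rng
            )
            before = np.abs(st.positions[:2].copy())
            producer_update_ssa(st, cfg, np.array([0, 1]))
            assert np.all(np.abs(st.positions[:2]) <= before)

    def test_empty_producers_raises(self):
        cfg = SwarmConfig(pop_size=5, dim=2, lower=-1, upper=1, iter_max=10, seed=0)
        st = init_population(cfg, sphere)
        with pytest.raises(ValueError, match="empty producer"):
            producer_update_ssa(st, cfg, np.array([], dtype=int))


class TestScroungerUpdate:
    def test_worse_half_at_worst_position(self, scripted_rng):
        # rank > n/2 and position == worst -> new position is Q everywhere
        cfg = SwarmConfig(pop_size=4, dim=2, lower=-10, upper=10, iter_max=10)
        rng = scripted_rng(standard_normal=[np.array([1.7])], integers=[[[1, 1]]])
        st = make_state(
            [[0, 0], [1, 1], [2, 2], [5, 5]], [1, 2, 3, 4], cfg, rng, worst=[5.0, 5.0]
        )
        st.best_producer_position = st.positions[0].copy()
        scrounger_update(st, cfg, np.array([3]))
        assert st.positions[3] == pytest.approx([1.7, 1.7])

    def test_better_half_at_producer_unchanged(self, scripted_rng):
        cfg = SwarmConfig(pop_size=10, dim=2, lower=-10, upper=10, iter_max=10)
        rng = scripted_rng(
            standard_normal=[np.array([0.3])], integers=[[[1, -1]]]
        )
        positions = np.tile(np.array([2.0, 2.0]), (10, 1))
        st = make_state(positions, np.arange(10), cfg, rng)
        st.best_producer_position = np.array([2.0, 2.0])
        scrounger_update(st, cfg, np.array([2]))  # rank 3 <= 5
        assert st.positions[2] == pytest.approx([2.0, 2.0])

    def test_pseudo_inverse_step_matches_brute_force(self, scripted_rng):
        # gap (2, -4), A = (+1, -1): A+ = A^T (A A^T)^-1 and |gap|.A+.L
        # must equal our scalar step on every coordinate
        cfg = SwarmConfig(pop_size=10, dim=2, lower=-10, upper=10, iter_max=10)
        A = np.array([1.0, -1.0])
        posi_a = np.array([1.0, 1.0])
        pos = posi_a + np.array([2.0, -4.0])
        # raw 0/1 draw [1, 0] maps to signs (+1, -1)
        rng = scripted_rng(standard_normal=[np.array([0.0])], integers=[[[1, 0]]])
        positions = np.tile(posi_a, (10, 1))
        positions[2] = pos
        st = make_state(positions, np.arange(10), cfg, rng)
        st.best_producer_position = posi_a.copy()
        scrounger_update(st, cfg, np.array([2]))

        A_pinv = A[:, None] @ np.linalg.inv(A[None, :] @ A[:, None])  # d x 1
        step = (np.abs(pos - posi_a)[None, :] @ A_pinv) @ np.ones((1, 2))
        expected = posi_a + step.ravel()
        assert st.positions[2] == pytest.approx(expected)
        assert st.positions[2] == pytest.approx(posi_a + (2 - 4) / 2.0)


class TestScoutUpdate:
    def test_beta_zero_jumps_to_best(self, scripted_rng):
        cfg = SwarmConfig(pop_size=4, dim=2, lower=-10, upper=10, iter_max=10)
        rng = scripted_rng(standard_normal=[np.array([0.0])], uniform=[np.array([0.4])])
        st = make_state([[0, 0], [3, 3], [4, 4], [5, 5]], [1, 2, 3, 4], cfg, rng)
        scout_update(st, cfg, np.array([2]))
        assert st.positions[2] == pytest.approx(st.best_position)

    def test_at_incumbent_and_worst_position_unchanged(self, scripted_rng):
        cfg = SwarmConfig(pop_size=4, dim=2, lower=-10, upper=10, iter_max=10)
        rng = scripted_rng(standard_normal=[np.array([0.5])], uniform=[np.array([0.9])])
        st = make_state([[5, 5], [3, 3], [4, 4], [5, 5]], [1, 2, 3, 4], cfg, rng, worst=[5.0, 5.0])
        st.fitnesses[0] = st.best_fitness  # scout 0 sits at incumbent fitness
        scout_update(st, cfg, np.array([0]))
        assert st.positions[0] == pytest.approx([5.0, 5.0])

    def test_equality_branch_displacement(self, scripted_rng):
        # K = 0.5, |gap| = 2, fitness_i - fitness_w = -1 -> displacement -1
        cfg = SwarmConfig(
            pop_size=4, dim=2, lower=-10, upper=10, iter_max=10, epsilon=1e-50
        )
        rng = scripted_rng(standard_normal=[np.array([0.7])], uniform=[np.array([0.5])])
        st = make_state([[2, 2], [3, 3], [4, 4], [0, 0]], [1, 2, 3, 4], cfg, rng)
        st.worst_position = np.array([0.0, 0.0])
        st.worst_fitness = 2.0  # so fitness_0 - worst = -1
        st.fitnesses[0] = 1.0
        st.best_fitness = 1.0
        scout_update(st, cfg, np.array([0]))
        assert st.positions[0] == pytest.approx([1.0, 1.0])


class TestOptimize:
    def test_f1_converges_deep(self):
        # tabulated baseline mean is ~1e-49; runs are heavy-tailed, so assert
        # a loose bound a few orders above typical single-run depth
        b = make_benchmark("F1")
        vals = []
        for seed in range(3):
            cfg = SwarmConfig(
                pop_size=30, dim=30, lower=-100, upper=100, iter_max=500, seed=seed
            )
            _, best, curve = optimize_ssa(b.evaluate, cfg)
            vals.append(best)
            assert np.all(np.diff(curve) <= 0)
        assert np.mean(vals) <= 1e-15

    def test_seed_determinism(self):
        cfg = SwarmConfig(pop_size=10, dim=5, lower=-5, upper=5, iter_max=30, seed=123)
        p1, f1, c1 = optimize_ssa(sphere, cfg)
        p2, f2, c2 = optimize_ssa(sphere, cfg)
        assert np.array_equal(p1, p2)
        assert f1 == f2
        assert np.array_equal(c1, c2)

    def test_positions_within_bounds(self):
        cfg = SwarmConfig(pop_size=8, dim=3, lower=-2, upper=2, iter_max=25, seed=5)
        pos, _, _ = optimize_ssa(sphere, cfg)
        assert np.all(pos >= -2) and np.all(pos <= 2)

    def test_non_finite_objective_aborts(self):
        cfg = SwarmConfig(pop_size=5, dim=2, lower=-1, upper=1, iter_max=5, seed=0)
        with pytest.raises(RuntimeError, match="non-finite"):
            optimize_ssa(lambda x: float("nan"), cfg)


def test_save_curve(tmp_path):
    path = tmp_path / "curve.tsv"
    save_curve(path, [3.0, 2.0, 1.0])
    arr = np.loadtxt(path, skiprows=1)
    assert arr.shape == (3, 2)
    assert arr[:, 1].tolist() == [3.0, 2.0, 1.0]
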
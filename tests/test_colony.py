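"""The binary multi-neighbor bee colony optimizer."""

import numpy as np
import pytest

from bmnabc import ColonyConfig, run
from bmnabc.colony import (
    _Colony,
    binary_update,
    compute_apb,
    hamming_distance,
    partition_neighbors,
    transfer_probability,
)


@pytest.mark.parametrize(
    "a, b, d",
    [([1, 0, 1], [1, 1, 0], 2), ([0] * 5, [1] * 5, 5), ([1, 1], [1, 1], 0)],
)
def test_hamming_distance(a, b, d):
    assert hamming_distance(np.array(a), np.array(b)) == d


def test_hamming_length_mismatch():
    with pytest.raises(ValueError, match="mismatch"):
        hamming_distance(np.zeros(3), np.zeros(4))


def test_partition_splits_at_mean():
    # bee 0 with neighbors at distances 1 and 9: mean 5 separates them
    x = np.zeros((3, 10), dtype=np.int8)
    x[1, :1] = 1
    x[2, :9] = 1
    near, far = partition_neighbors(x, 0)
    assert list(near) == [1] and list(far) == [2]


def test_partition_degenerate_identical_bees():
    x = np.zeros((5, 8), dtype=np.int8)
    near, far = partition_neighbors(x, 2)
    assert far.size == 1 and near.size == 3
    assert not set(near) & set(far)


def test_partition_two_bees_lone_neighbor_serves_both_roles():
    x = np.zeros((2, 4), dtype=np.int8)
    near, far = partition_neighbors(x, 0)
    assert list(near) == [1] and list(far) == [1]


def test_apb_bounds_and_expectation(rng):
    pbests = np.ones((6, 50))
    far = np.arange(1, 6)
    vals = np.concatenate([compute_apb(pbests, far, rng) for _ in range(200)])
    assert np.all((vals >= 0) & (vals <= 1))
    assert vals.mean() == pytest.approx(0.5, abs=0.02)
    assert np.all(compute_apb(np.zeros((4, 3)), np.array([1, 2]), rng) == 0)


@pytest.mark.parametrize(
    "a, ac, t, expected",
    [
        (0.0, 0, 0.05, 0.0),
        (50.0, 0, 0.05, 1.0),  # tanh saturates
        (0.0, 10, 0.05, 1.0 - np.exp(-0.5)),  # ~0.3935, the AC floor
    ],
)
def test_transfer_probability_closed_forms(a, ac, t, expected):
    assert transfer_probability(a, ac, t) == pytest.approx(expected, abs=1e-9)


def test_binary_update_extremes(rng):
    x = np.array([1, 0, 1, 0], dtype=np.int8)
    np.testing.assert_array_equal(binary_update(x, np.zeros(4), 0, 0.05, rng), x)
    flipped = binary_update(x, np.full(4, 100.0), 0, 0.05, rng)
    np.testing.assert_array_equal(flipped, 1 - x)


def test_binary_update_flip_fraction(rng):
    """Empirical flip rate matches S(a) = 1 - exp(-0.5) ~ 0.3935."""
    x = np.zeros(100_000, dtype=np.int8)
    out = binary_update(x, np.zeros(x.size), 10, 0.05, rng)
    assert out.mean() == pytest.approx(1.0 - np.exp(-0.5), abs=0.005)


def test_constant_fitness_increments_all_counters(rng):
    cfg = ColonyConfig(d=12, n=6, seed=0)
    col = _Colony(lambda x: 0.5, cfg, rng)
    ac_before = col.ac.copy()
    col.employed_phase()
    np.testing.assert_array_equal(col.ac, ac_before + 1)


def test_employed_phase_is_monotone_per_bee(rng):
    cfg = ColonyConfig(d=10, n=8, seed=3)
    col = _Colony(lambda x: float(x.mean()), cfg, rng)
    before = col.fitness.copy()
    col.employed_phase()
    assert np.all(col.fitness >= before)


def test_scout_reinitializes_only_exhausted_bees(rng):
    cfg = ColonyConfig(d=10, n=4, limit=3, seed=0)
    col = _Colony(lambda x: float(x.mean()), cfg, rng)
    col.ac[:] = [0, 3, 4, 10]
    x_before = col.x.copy()
    pbest_before = col.pbest.copy()
    col.scout_phase()
    assert col.ac[2] == 0 and col.ac[3] == 0
    assert col.ac[1] == 3  # at the limit, not beyond it
    np.testing.assert_array_equal(col.x[0], x_before[0])
    np.testing.assert_array_equal(col.pbest[1], pbest_before[1])  # memory kept


def test_stagnating_colony_rescouts_within_limit_plus_two(rng):
    """With constant fitness nothing ever improves, so every bee's counter
    crosses the limit and forces a re-scout within limit + 2 iterations."""
    cfg = ColonyConfig(d=15, n=5, limit=4, max_iter=1, seed=1)
    col = _Colony(lambda x: 0.25, cfg, rng)
    initial = col.x.copy()
    rescouted = np.zeros(cfg.n, dtype=bool)
    for _ in range(cfg.limit + 2):
        col.employed_phase()
        col.onlooker_phase()
        ac_before = col.ac.copy()
        col.scout_phase()
        rescouted |= (ac_before > cfg.limit)
    assert rescouted.all()


def test_onlooker_roulette_degenerates_to_single_winner(rng):
    """When one bee holds all the fitness mass it receives every draw."""
    cfg = ColonyConfig(d=6, n=5, seed=0)
    col = _Colony(lambda x: 0.0, cfg, rng)
    col.fitness[:] = [0.0, 0.0, 0.7, 0.0, 0.0]
    probs = col.fitness / col.fitness.sum()
    draws = rng.choice(cfg.n, size=1000, p=probs)
    assert np.all(draws == 2)


def test_run_determinism_and_history():
    cfg = ColonyConfig(d=15, n=6, max_iter=20, seed=7)
    f = lambda x: float(x.mean())
    a, b = run(f, cfg), run(f, cfg)
    np.testing.assert_array_equal(a.best_x, b.best_x)
    np.testing.assert_array_equal(a.history, b.history)
    assert a.evaluations == b.evaluations
    assert np.all(np.diff(a.history) >= 0)
    assert a.best_fitness == a.history[-1]


def test_one_dimensional_space_solved_immediately():
    res = run(lambda x: float(x[0]), ColonyConfig(d=1, n=4, max_iter=2, seed=0))
    assert res.best_fitness == 1.0
    assert res.history[0] == 1.0


def test_evaluation_budget():
    cfg = ColonyConfig(d=10, n=6, max_iter=15, seed=2)
    res = run(lambda x: float(x.mean()), cfg)
    assert res.evaluations <= cfg.n + cfg.max_iter * 3 * cfg.n


def test_pbest_dominates_current_fitness():
    res = run(lambda x: float(x.mean()), ColonyConfig(d=12, n=6, max_iter=10, seed=5))
    for bee in res.colony:
        assert bee.pbest_fitness >= bee.fitness


def test_empty_mask_sentinel_skips_fitness_fn():
    seen = []

    def f(x):
        seen.append(x.copy())
        return float(x.mean())

    run(f, ColonyConfig(d=4, n=4, max_iter=5, seed=0))
    assert all(x.any() for x in seen)


def test_non_finite_fitness_raises():
    with pytest.raises(RuntimeError, match="non-finite"):
        run(lambda x: float("nan"), ColonyConfig(d=5, n=4, max_iter=2, seed=0))


def test_config_validation():
    with pytest.raises(ValueError):
        ColonyConfig(d=0)
    with pytest.raises(ValueError):
        ColonyConfig(d=5, n=1)
    with pytest.raises(ValueError):
        ColonyConfig(d=5, t_temp=0.0)
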
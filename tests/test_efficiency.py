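import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gravistoch.efficiency import (
    ClassifierTrace,
    all_stage_features,
    efficiency_score,
    extract_features,
    response_time,
    run_efficiency_experiment,
    stagewise_accuracy,
    variance_vs_repetitions,
)
from gravistoch.physics import GravityDirection, SimConfig, simulate
from gravistoch.stability import StabilityParams
from gravistoch.stacks import Block

from conftest import make_stack
from test_stability import synthetic_traj


def test_features_zero_at_stage_zero(crossing_tower, fast_sim):
    traj = simulate(crossing_tower, GravityDirection(0, 0), fast_sim)
    f = extract_features(traj, 0)
    assert f.shape == (3 * 24,)
    assert np.all(f == 0)
    with pytest.raises(IndexError):
        extract_features(traj, traj.n_stages)


def test_features_encode_rigid_translation():
    centers = np.zeros((5, 2, 3))
    centers[3:, 1, 2] = -1.0  # block 1 translates down one unit
    traj = synthetic_traj(centers)
    f = extract_features(traj, 4).reshape(2, 8, 3)
    assert np.all(f[0] == 0)
    assert np.allclose(f[1, :, 2], -1.0)
    assert np.allclose(f[1, :, :2], 0.0)


def test_stable_stack_features_stay_near_zero(stable_tower, fast_sim):
    traj = simulate(stable_tower, GravityDirection(0, 0), fast_sim)
    assert np.abs(all_stage_features(traj)).max() < 1e-6


def test_response_time_and_efficiency_arithmetic():
    curve = np.full(500, 0.5)
    curve[99:] = 0.9  # max first reached at stage 100 (1-based)
    t_hat, time = response_time(curve)
    assert (t_hat, time) == (100, pytest.approx(0.2))
    assert efficiency_score(0.9, time) == pytest.approx(4.5)

    increasing = np.linspace(0.5, 1.0, 500)
    assert response_time(increasing) == (500, pytest.approx(1.0))

    constant = np.full(500, 0.8)
    t_hat, time = response_time(constant)
    assert (t_hat, time) == (1, pytest.approx(1 / 500))

    with pytest.raises(ValueError):
        efficiency_score(0.9, 0.0)


@given(st.lists(st.floats(0.3, 1.0), min_size=2, max_size=40))
def test_efficiency_identity(accs):
    trace = ClassifierTrace(np.array(accs))
    assert trace.efficiency * trace.time == pytest.approx(trace.plateau_accuracy)
    assert 0 < trace.time <= 1


def test_stagewise_accuracy_on_separable_features(rng):
    n, T, F = 40, 6, 8
    y = np.array([0, 1] * (n // 2))
    X = np.zeros((n, T, F), dtype=np.float32)
    # from stage 2 on, class 1 drifts in feature space
    X[y == 1, 2:, 0] = 1.0
    acc = stagewise_accuracy(X, y, X, y)
    assert np.allclose(acc[:2], 0.5)  # all-zero features: chance on balanced sets
    assert np.allclose(acc[2:], 1.0)
    with pytest.raises(ValueError):
        stagewise_accuracy(X, np.zeros(n, dtype=int), X, y)


def test_small_efficiency_experiment_end_to_end():
    params = StabilityParams()
    sim = SimConfig(n_stages=100)
    results = {}
    for kind in ("ngs", "mgs"):
        rng = np.random.default_rng(31)
        results[kind] = run_efficiency_experiment([3], 8, 8, kind, params, rng, sim)
    for res in results.values():
        trace = res.traces[3]
        assert np.all((0 <= trace.accuracy_by_stage) & (trace.accuracy_by_stage <= 1))
        assert trace.accuracy_by_stage[0] == pytest.approx(0.5)  # chance at stage 0
        assert trace.efficiency * trace.time == pytest.approx(trace.plateau_accuracy)
    # natural gravity trajectories directly expose the label
    assert results["ngs"].traces[3].plateau_accuracy >= 0.7
    summary = results["ngs"].summary()
    assert list(summary["n_blocks"]) == [3, "pooled"]


def test_variance_vs_repetitions_decreases(fast_sim):
    rng = np.random.default_rng(9)
    stack = make_stack(
        [Block("long-x", [0.0, 0.0, 0.2]), Block("long-x", [0.55, 0.0, 0.6])]
    )
    table = variance_vs_repetitions([stack], [1, 4], rng=rng, sim_config=fast_sim, n_reps=40)
    v1 = table.loc[table.n_sims == 1, "variance"].item()
    v4 = table.loc[table.n_sims == 4, "variance"].item()
    assert v1 > v4 > 0
    # i.i.d. mean: var(n) ~ var(1)/n, up to variance-of-variance noise
    assert v1 / 12 < v4 < 3 * v1 / 4
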
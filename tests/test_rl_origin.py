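import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gravistoch.physics import GravityDirection, SimConfig, simulate
from gravistoch.psychophysics import FitError
from gravistoch.rl_origin import (
    DirectionGrid,
    RLConfig,
    fit_grid_sigma,
    q_value,
    td_update,
    train,
)
from gravistoch.stacks import StackGenConfig, generate_stack


def test_td_update_examples():
    assert td_update(0.5, 0.5, 0.15) == 0.5  # fixed point
    assert td_update(0.0, 1.0, 0.15) == pytest.approx(0.15)


@given(
    st.floats(0, 1),
    st.floats(0, 1),
    st.floats(0.01, 1.0),
    st.integers(1, 60),
)
def test_td_update_closed_form(w0, q, gamma, k):
    """k constant-target updates follow w_k = q + (w0 - q)(1 - gamma)^k."""
    w = w0
    for _ in range(k):
        w = td_update(w, q, gamma)
    assert w == pytest.approx(q + (w0 - q) * (1 - gamma) ** k, abs=1e-9)
    assert 0.0 <= w <= 1.0  # convex combination stays in range


def test_direction_grid_shape_and_dedup():
    grid = DirectionGrid()
    assert grid.theta_axis.shape == (61,)
    assert grid.theta_axis[0] == 0.0 and grid.theta_axis[-1] == 180.0
    # phi = 360 names the same direction as 0 and is dropped
    assert grid.phi_axis.shape == (60,)
    assert grid.phi_axis.max() < 360.0
    assert np.all(grid.W == 0.5)


def test_grid_sampling_follows_weights(rng):
    grid = DirectionGrid()
    grid.W[:] = 1e-12
    grid.W[3, 7] = 1.0
    cells = grid.sample_cells(1, rng)
    assert cells == [(3, 7)]


def test_q_value_is_one_under_natural_gravity(fast_sim):
    stack = generate_stack(StackGenConfig(n_blocks=5, seed=4))
    ngs = simulate(stack, GravityDirection(0, 0), fast_sim)
    assert q_value(stack, GravityDirection(0, 0), ngs, sim_config=fast_sim) == 1.0


def test_q_value_bounded_and_low_for_sideways_gravity(fast_sim):
    stack = generate_stack(StackGenConfig(n_blocks=8, area_x=0.5, area_y=0.5, seed=10))
    ngs = simulate(stack, GravityDirection(0, 0), fast_sim)
    q = q_value(stack, GravityDirection(90, 30), ngs, sim_config=fast_sim)
    assert 0.0 <= q < 1.0


def test_q_value_stack_mismatch(fast_sim):
    a = generate_stack(StackGenConfig(n_blocks=4, seed=1))
    b = generate_stack(StackGenConfig(n_blocks=5, seed=1))
    ngs_b = simulate(b, GravityDirection(0, 0), fast_sim)
    with pytest.raises(ValueError):
        q_value(a, GravityDirection(0, 0), ngs_b, sim_config=fast_sim)


def test_zero_iterations_leave_grid_uniform():
    grid, trace = train(RLConfig(n_configs=0, seed=1))
    assert np.all(grid.W == 0.5)
    assert trace.snapshots == []
    with pytest.raises(FitError):
        fit_grid_sigma(grid)


def test_training_keeps_weights_in_unit_interval():
    cfg = RLConfig(n_configs=40, n_stages=80, block_range=(2, 4), seed=5)
    grid, trace = train(cfg, sim_config=SimConfig(n_stages=80))
    assert grid.W.min() >= 0.0 and grid.W.max() <= 1.0
    assert not np.all(grid.W == 0.5)
    assert trace.iterations[-1] == 40


def test_training_deterministic_given_seed():
    cfg = RLConfig(n_configs=10, n_stages=60, block_range=(2, 3), seed=6)
    a, _ = train(cfg)
    b, _ = train(cfg)
    assert np.array_equal(a.W, b.W)


def test_fit_grid_sigma_noiseless():
    grid = DirectionGrid()
    grid.W = np.exp(-(grid.theta_axis[:, None] ** 2) / (2 * 20.0**2)) * np.ones(
        (1, len(grid.phi_axis))
    )
    fit = fit_grid_sigma(grid)
    assert fit.sigma == pytest.approx(20.0, abs=1e-3)
    assert fit.baseline == pytest.approx(0.0, abs=1e-6)
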
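import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gravistoch.physics import (
    GravityDirection,
    SimConfig,
    SimulationError,
    gravity_vector,
    quick_stable,
    simulate,
)
from gravistoch.stability import is_stable
from gravistoch.stacks import Block, StackGenConfig, generate_stack

from conftest import make_stack


def test_gravity_vector_reference_directions():
    assert gravity_vector(GravityDirection(0, 0, 9.8)) == pytest.approx([0, 0, -9.8])
    assert gravity_vector(GravityDirection(90, 0, 9.8)) == pytest.approx([9.8, 0, 0], abs=1e-12)
    assert gravity_vector(GravityDirection(90, 90, 9.8)) == pytest.approx([0, 9.8, 0], abs=1e-12)
    # inverted world: gravity points straight up
    assert gravity_vector(GravityDirection(180, 123, 9.8)) == pytest.approx([0, 0, 9.8], abs=1e-12)


@given(st.floats(0, 180), st.floats(0, 360))
def test_gravity_vector_norm_identity(theta, phi):
    v = gravity_vector(GravityDirection(theta, phi))
    assert np.linalg.norm(v) == pytest.approx(9.8, abs=1e-9)


def test_resting_block_is_static(single_block_stack, fast_sim):
    traj = simulate(single_block_stack, GravityDirection(0, 0), fast_sim)
    assert traj.displacements().max() < 0.01
    assert traj.centers.shape == (fast_sim.n_stages, 1, 3)
    assert np.array_equal(traj.centers[0, 0], [0.0, 0.0, 0.2])


def test_free_fall_matches_closed_form():
    stack = make_stack([Block("long-x", [0.0, 0.0, 5.0])])
    traj = simulate(stack, GravityDirection(0, 0), SimConfig(n_stages=500))
    g, dt = 9.8, 1.0 / 240.0
    # semi-implicit Euler: z_k = z0 - g dt^2 k(k+1)/2 while airborne
    for k in (5, 20, 60):
        assert traj.centers[k, 0, 2] == pytest.approx(5.0 - g * dt**2 * k * (k + 1) / 2, abs=1e-9)
    # ends resting on the ground at its half height
    assert traj.centers[-1, 0, 2] == pytest.approx(0.2, abs=5e-3)
    assert traj.displacements()[-1, 0] > 0.01


def test_simulation_deterministic(overhang_tower, fast_sim):
    a = simulate(overhang_tower, GravityDirection(25, 130), fast_sim)
    b = simulate(overhang_tower, GravityDirection(25, 130), fast_sim)
    assert np.array_equal(a.centers, b.centers)
    assert np.array_equal(a.quats, b.quats)


def test_phi_irrelevant_at_zero_tilt(overhang_tower, fast_sim):
    a = simulate(overhang_tower, GravityDirection(0, 0), fast_sim)
    b = simulate(overhang_tower, GravityDirection(0, 271.3), fast_sim)
    assert np.array_equal(a.centers, b.centers)


def test_collapse_rotates_with_phi(fast_sim):
    """Tilting along y on a y-mirrored stack mirrors the x-tilt collapse."""
    sx = make_stack([Block("long-x", [0.0, 0.0, 0.2]), Block("long-x", [0.3, 0.0, 0.6])])
    sy = make_stack([Block("long-y", [0.0, 0.0, 0.2]), Block("long-y", [0.0, 0.3, 0.6])])
    ta = simulate(sx, GravityDirection(40, 0), fast_sim)
    tb = simulate(sy, GravityDirection(40, 90), fast_sim)
    swapped = tb.centers[:, :, [1, 0, 2]]  # (y, x, z) of the rotated run
    assert np.allclose(ta.centers, swapped, atol=1e-6)


def test_blocks_stay_above_ground(fast_sim):
    stack = generate_stack(StackGenConfig(n_blocks=10, area_x=0.6, area_y=0.6, seed=8))
    traj = simulate(stack, GravityDirection(30, 45), fast_sim)
    assert traj.vertices[..., 2].min() > -0.02


def test_vertices_shape_and_stage0(crossing_tower, fast_sim):
    traj = simulate(crossing_tower, GravityDirection(0, 0), fast_sim)
    T, M = traj.n_stages, traj.n_blocks
    assert traj.vertices.shape == (T, M, 8, 3)
    expected_top = crossing_tower.blocks[2].top
    assert traj.vertices[0, 2, :, 2].max() == pytest.approx(expected_top)


def test_empty_stack_raises(fast_sim):
    empty = make_stack([Block("long-x", [0, 0, 0.2])])
    empty.blocks = []
    with pytest.raises(SimulationError):
        simulate(empty, GravityDirection(0, 0), fast_sim)


@pytest.mark.parametrize("seed", [3, 21])
def test_quick_label_agrees_with_full_run(seed, fast_sim):
    stack = generate_stack(StackGenConfig(n_blocks=6, seed=seed))
    full = is_stable(simulate(stack, GravityDirection(0, 0), fast_sim))
    assert quick_stable(stack, GravityDirection(0, 0), fast_sim) == full
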
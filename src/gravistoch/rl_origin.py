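"""How a Gaussian gravity prior can emerge from prediction-error learning.

An agent holds sampling weights W(theta, phi) over a spherical grid of
candidate gravity directions (61 tilts covering 0-180 deg x 60 distinct
orientations).  For every stack it encounters it samples a few directions
in proportion to W, mentally simulates the collapse under each, and compares
the predicted final block positions with what natural gravity actually did.
The match fraction

    Q = (1/M) * sum_m 1[ |P_m(theta, phi) - P_m(NGS)| < epsilon ]

drives a temporal-difference update W <- W + gamma (Q - W) on each sampled
cell, so directions whose predictions keep matching reality gain weight.
Trained on enough random stacks, the theta-marginal of W peaks at straight
down and falls off as a Gaussian -- a stochastic prior nobody put in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .physics import GravityDirection, SimConfig, Trajectory, simulate
from .psychophysics import FitError, GaussianFit, fit_gaussian_sensitivity
from .stacks import Stack, StackGenConfig, generate_stack

N_ANGLES = 61  # sampling angles per spherical axis


@dataclass
class DirectionGrid:
    """Sampling weights over the (theta, phi) direction grid.

    phi = 0 and 360 name the same direction, so the phi axis keeps 60
    distinct values; theta spans [0, 180] inclusive with all 61.
    """

    theta_axis: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 180.0, N_ANGLES)
    )
    phi_axis: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 360.0, N_ANGLES)[:-1]
    )
    W: np.ndarray | None = None

    def __post_init__(self):
        if self.W is None:
            # any identical initial value works; 0.5 is the midpoint of Q's range
            self.W = np.full((len(self.theta_axis), len(self.phi_axis)), 0.5)

    def sample_cells(self, n: int, rng: np.random.Generator) -> list[tuple[int, int]]:
        """Draw n distinct cells with probability proportional to W."""
        p = self.W.ravel()
        total = p.sum()
        if total <= 0:
            raise ValueError("all grid weights are zero")
        flat = rng.choice(p.size, size=n, replace=False, p=p / total)
        return [tuple(np.unravel_index(k, self.W.shape)) for k in flat]

    def direction(self, i: int, j: int, g: float = 9.8) -> GravityDirection:
        return GravityDirection(float(self.theta_axis[i]), float(self.phi_axis[j]), g)

    def theta_marginal(self) -> np.ndarray:
        return self.W.mean(axis=1)


@dataclass(frozen=True)
class RLConfig:
    gamma: float = 0.15
    samples_per_stack: int = 3
    n_configs: int = 100_000
    block_range: tuple[int, int] = (2, 15)
    epsilon: float = 0.01
    n_stages: int = 500
    seed: int | None = None
    snapshot_every: int | None = None  # default: n_configs // 20

    def __post_init__(self):
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError("gamma must be in (0, 1]")
        if self.samples_per_stack < 1:
            raise ValueError("samples_per_stack must be >= 1")


def q_value(
    stack: Stack,
    direction: GravityDirection,
    ngs_traj: Trajectory,
    epsilon: float = 0.01,
    sim_config: SimConfig | None = None,
) -> float:
    """Expectation-observation match: fraction of blocks whose final position
    under ``direction`` lies within epsilon of the natural-gravity final
    position.  1 = the sampled direction predicts reality perfectly."""
    if ngs_traj.n_blocks != stack.n_blocks:
        raise ValueError("ngs_traj does not belong to this stack")
    traj = simulate(stack, direction, sim_config)
    d = np.linalg.norm(traj.centers[-1] - ngs_traj.centers[-1], axis=1)
    return float((d < epsilon).mean())


def td_update(w: float, q: float, gamma: float = 0.15) -> float:
    """Exponential-moving-average update toward the observed match Q."""
    return w + gamma * (q - w)


@dataclass
class TrainingTrace:
    iterations: list[int]
    snapshots: list[np.ndarray]
    n_skipped: int = 0


def train(
    config: RLConfig,
    sim_config: SimConfig | None = None,
    gen_config: StackGenConfig | None = None,
    grid: DirectionGrid | None = None,
    progress: bool = False,
) -> tuple[DirectionGrid, TrainingTrace]:
    """Run the TD loop over freshly generated stacks.

    Per stack: block count uniform over ``block_range``, one natural-gravity
    simulation for the observation, ``samples_per_stack`` weighted direction
    draws for the expectations, one td_update per draw.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    grid = grid or DirectionGrid()
    if sim_config is None:
        # coarser solver settings: training only needs final positions at the
        # 0.01 match threshold, where moved-vs-unmoved dominates the Q value
        from .engine import EngineParams

        sim_config = SimConfig(
            n_stages=config.n_stages,
            engine=EngineParams(vel_iters=6, pos_iters=1, sleep_steps=5),
        )
    every = config.snapshot_every or max(config.n_configs // 20, 1)
    trace = TrainingTrace(iterations=[], snapshots=[])
    lo, hi = config.block_range
    iterator = range(config.n_configs)
    if progress:
        iterator = _progress(iterator)
    area_kwargs = {}
    if gen_config is not None:
        area_kwargs = dict(
            area_x=gen_config.area_x,
            area_y=gen_config.area_y,
            area_bounds=gen_config.area_bounds,
            overlap_range=gen_config.overlap_range,
        )
    for it in iterator:
        n_blocks = int(rng.integers(lo, hi + 1))
        cfg = StackGenConfig(n_blocks=n_blocks, seed=int(rng.integers(2**31)), **area_kwargs)
        stack = generate_stack(cfg)
        try:
            ngs_traj = simulate(stack, GravityDirection(0.0, 0.0), sim_config)
            cells = grid.sample_cells(config.samples_per_stack, rng)
            for i, j in cells:
                q = q_value(stack, grid.direction(i, j), ngs_traj, config.epsilon, sim_config)
                grid.W[i, j] = td_update(grid.W[i, j], q, config.gamma)
        except Exception:
            trace.n_skipped += 1
            continue
        if (it + 1) % every == 0 or it + 1 == config.n_configs:
            trace.iterations.append(it + 1)
            trace.snapshots.append(grid.W.copy())
    return grid, trace


def fit_grid_sigma(grid: DirectionGrid, with_baseline: bool = True) -> GaussianFit:
    """Gaussian width of the trained grid's theta-marginal.

    The marginal is rescaled to peak 1 before fitting, so the width is
    independent of the overall weight level.  By default the fit includes a
    non-negative baseline: cells a finite training pass has rarely sampled
    still sit near their initial weight, which floors the marginal; the
    baseline absorbs that floor (and tends to zero as training lengthens) so
    the width measures the learned structure.  A uniform (untrained) grid is
    degenerate and raises FitError.
    """
    marginal = grid.theta_marginal()
    peak = marginal.max()
    if peak <= 0 or np.allclose(marginal, marginal[0]):
        raise FitError("degenerate theta-marginal (uniform or empty grid)")
    return fit_gaussian_sensitivity(
        grid.theta_axis, marginal / peak, with_baseline=with_baseline
    )


def _progress(it):
    try:
        from tqdm import tqdm

        return tqdm(it)
    except ImportError:  # pragma: no cover
        return it
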
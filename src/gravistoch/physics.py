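"""Forward simulation of a block stack under an arbitrary gravity direction.

The gravity direction is an angle pair (theta, phi) on the sphere: theta is
the tilt away from straight down (theta = 0 reproduces natural gravity,
theta = 180 points upward), phi the horizontal orientation of the tilt.  The
decomposition is

    G = g * (sin(theta) cos(phi), sin(theta) sin(phi), -cos(theta))

so that ||G|| = g always.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .engine import EngineParams, World
from .stacks import Stack


@dataclass(frozen=True)
class GravityDirection:
    """Gravity as a spherical angle pair, in degrees, with magnitude g."""

    theta: float = 0.0
    phi: float = 0.0
    g: float = 9.8

    @property
    def vector(self) -> np.ndarray:
        return gravity_vector(self)


def gravity_vector(direction: GravityDirection) -> np.ndarray:
    """3-vector of the gravity acceleration; theta = 0 gives (0, 0, -g)."""
    th = np.deg2rad(direction.theta)
    ph = np.deg2rad(direction.phi)
    return direction.g * np.array(
        [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), -np.cos(th)]
    )


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings: stage count and backend parameters.

    One integration step of ``dt`` seconds is taken per recorded stage, so the
    default 500 stages cover a little over two seconds of motion -- ample for
    a collapse to play out at these block sizes.
    """

    n_stages: int = 500
    dt: float = 1.0 / 240.0
    friction: float = 1.0
    restitution: float = 0.0
    engine: EngineParams = field(default_factory=EngineParams)

    def __post_init__(self):
        if self.n_stages < 1:
            raise ValueError("n_stages must be >= 1")
        object.__setattr__(
            self,
            "engine",
            replace(
                self.engine,
                dt=self.dt,
                friction=self.friction,
                restitution=self.restitution,
            ),
        )


@dataclass
class Trajectory:
    """Per-stage rigid-body states of one simulation.

    ``centers`` has shape (T, M, 3) with stage 0 equal to the initial
    configuration.  Vertices (T, M, 8, 3) are derived lazily from the stored
    orientations since most consumers only need centers.
    """

    centers: np.ndarray
    quats: np.ndarray
    half_extents: np.ndarray
    gravity: GravityDirection
    stack: Stack | None = None
    _vertices: np.ndarray | None = None

    @property
    def n_stages(self) -> int:
        return self.centers.shape[0]

    @property
    def n_blocks(self) -> int:
        return self.centers.shape[1]

    @property
    def vertices(self) -> np.ndarray:
        if self._vertices is None:
            from .engine import kernels as _k

            T, M = self.centers.shape[:2]
            out = np.empty((T, M, 8, 3))
            for t in range(T):
                _k.vertices_snapshot(self.centers[t], self.quats[t], self.half_extents, out[t])
            self._vertices = out
        return self._vertices

    def displacements(self) -> np.ndarray:
        """Euclidean center displacement from stage 0, shape (T, M)."""
        return np.linalg.norm(self.centers - self.centers[0], axis=2)


class SimulationError(RuntimeError):
    pass


def simulate(
    stack: Stack,
    direction: GravityDirection | None = None,
    config: SimConfig | None = None,
) -> Trajectory:
    """Rigid-body forward simulation of ``stack`` under uniform gravity.

    Gravity is the only external force; block-block and block-ground contacts
    use the stack's friction/restitution settings.  Deterministic for fixed
    inputs.
    """
    direction = direction or GravityDirection()
    config = config or SimConfig()
    if len(stack.blocks) == 0:
        raise SimulationError("empty stack")
    centers = np.array([b.center for b in stack.blocks])
    halves = np.array([b.half_extents for b in stack.blocks])
    masses = np.array([b.mass for b in stack.blocks])
    try:
        world = World(centers, halves, masses, gravity_vector(direction), config.engine)
        pos_hist, quat_hist = world.run(config.n_stages)
    except Exception as exc:  # pragma: no cover - backend failures are rare
        raise SimulationError(
            f"simulation failed for stack of {len(stack.blocks)} blocks "
            f"at theta={direction.theta}, phi={direction.phi}: {exc}"
        ) from exc
    return Trajectory(
        centers=pos_hist,
        quats=quat_hist,
        half_extents=halves,
        gravity=direction,
        stack=stack,
    )


def quick_stable(
    stack: Stack,
    direction: GravityDirection | None = None,
    config: SimConfig | None = None,
    eps: float = 0.01,
) -> bool:
    """Early-exit stability check: same verdict as simulating the full
    horizon and testing every stage's displacement against ``eps``, but
    without recording a trajectory."""
    direction = direction or GravityDirection()
    config = config or SimConfig()
    centers = np.array([b.center for b in stack.blocks])
    halves = np.array([b.half_extents for b in stack.blocks])
    masses = np.array([b.mass for b in stack.blocks])
    world = World(centers, halves, masses, gravity_vector(direction), config.engine)
    return world.settles_unmoved(eps, config.n_stages)
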
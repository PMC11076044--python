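"""Parametric observer that stands in for human participants.

Responses are Bernoulli draws whose acceptance probability follows the same
Gaussian tuning model the analysis fits:

    p(normal | theta) = amplitude * exp(-theta^2 / (2 sigma_true^2))

The run design mirrors the psychophysics task: per run, each of the 16 theta
values and each of the (up to) 96 phi draws appears six times, randomly
paired, giving 96 trials per run and 4 runs by default.  The peak acceptance
probability defaults to 0.91 (the reported accuracy at theta = 0).  An
inverted-world observer uses an identical tuning model -- gravity's encoded
direction is cognitively impenetrable -- so the flag only tags metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .psychophysics import PHI_GRID, THETA_GRID, TrialRecord


@dataclass(frozen=True)
class ObserverSpec:
    sigma_true: float = 19.9
    amplitude: float = 0.91
    n_runs: int = 4
    pairs_per_run: int = 96
    inverted_world: bool = False
    seed: int | None = None

    def __post_init__(self):
        if not (0.0 < self.amplitude <= 1.0):
            raise ValueError("amplitude must be in (0, 1]")
        if self.sigma_true <= 0:
            raise ValueError("sigma_true must be positive")


def run_design(
    pairs_per_run: int,
    rng: np.random.Generator,
    theta_grid: np.ndarray = THETA_GRID,
    phi_grid: np.ndarray = PHI_GRID,
) -> list[tuple[float, float]]:
    """Random pairing of theta and phi values with balanced repetition.

    Each grid value is tiled to the run length (six repeats of 16 thetas for
    the default 96) and the phi column is shuffled against the theta column.
    """
    reps_t = int(np.ceil(pairs_per_run / len(theta_grid)))
    thetas = np.tile(theta_grid, reps_t)[:pairs_per_run]
    reps_p = int(np.ceil(pairs_per_run / len(phi_grid)))
    phis = np.tile(phi_grid, reps_p)[:pairs_per_run]
    rng.shuffle(phis)
    return list(zip(thetas.tolist(), phis.tolist()))


def simulate_observer(spec: ObserverSpec, rng: np.random.Generator | None = None) -> list[TrialRecord]:
    """Generate trial-level binary judgments under the Gaussian tuning model."""
    rng = rng or np.random.default_rng(spec.seed)
    trials: list[TrialRecord] = []
    for run in range(spec.n_runs):
        for theta, phi in run_design(spec.pairs_per_run, rng):
            p = spec.amplitude * np.exp(-(theta**2) / (2.0 * spec.sigma_true**2))
            trials.append(TrialRecord(theta, phi, bool(rng.random() < p), run_id=run))
    return trials


def simulate_participants(
    n: int,
    sigma_range: tuple[float, float] = (11.1, 37.1),
    amplitude: float = 0.91,
    rng: np.random.Generator | None = None,
) -> list[tuple[float, list[TrialRecord], list[TrialRecord]]]:
    """Heterogeneous observers: sigma_true ~ U(sigma_range), one upright and
    one inverted-world session each; returns (sigma_true, upright, inverted).
    """
    rng = rng or np.random.default_rng()
    out = []
    for _ in range(n):
        sigma = float(rng.uniform(*sigma_range))
        up = simulate_observer(ObserverSpec(sigma_true=sigma, amplitude=amplitude), rng)
        inv = simulate_observer(
            ObserverSpec(sigma_true=sigma, amplitude=amplitude, inverted_world=True), rng
        )
        out.append((sigma, up, inv))
    return out
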
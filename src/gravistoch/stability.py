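"""Stability scoring and the natural/mental gravity simulators.

NGS (natural gravity simulator): one deterministic simulation with gravity
straight down defines ground truth.  A stack is *stable* when no block's
center ever moves epsilon = 0.01 units from its start; the graded *stability
score* is the fraction of blocks whose final-stage displacement stays below
epsilon.

MGS (mental gravity simulator): the same simulation repeated under gravity
directions whose tilt theta is drawn from a Gaussian around vertical
(sigma defaults to 18.6 deg, the mean of the psychophysically measured
widths in the upright and inverted worlds, truncated at the 45 deg design
limit) with uniform horizontal orientation phi; the stability estimate is
the mean score across draws.  The *inference bias* MGS - NGS quantifies how
much the stochastic model under-rates stability, which grows with stack
height (the "taller looks more precarious" illusion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .physics import GravityDirection, SimConfig, Trajectory, simulate
from .stacks import Stack, StackGenConfig, generate_labeled_set

#: displacement just-noticeable-difference (length units)
EPSILON = 0.01

#: default MGS tilt width: mean of the tuning widths measured upright (19.9)
#: and inverted (17.2)
SIGMA_MGS = 18.6


@dataclass(frozen=True)
class StabilityParams:
    epsilon: float = EPSILON
    n_mgs_samples: int = 100
    sigma_mgs: float = SIGMA_MGS
    theta_max: float = 45.0

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.n_mgs_samples < 1:
            raise ValueError("n_mgs_samples must be >= 1")


@dataclass(frozen=True)
class StabilityResult:
    score: float
    is_stable: bool
    per_direction_scores: tuple[float, ...] | None = None


def is_stable(traj: Trajectory, eps: float = EPSILON) -> bool:
    """True iff every block stays within eps of its start at *every* stage."""
    return bool((traj.displacements() < eps).all())


def stability_score(traj: Trajectory, eps: float = EPSILON) -> float:
    """Fraction of blocks whose *final-stage* displacement is below eps."""
    return float((traj.displacements()[-1] < eps).mean())


def ngs_stability(
    stack: Stack,
    params: StabilityParams | None = None,
    sim_config: SimConfig | None = None,
) -> StabilityResult:
    """Ground-truth stability from a single natural-gravity simulation."""
    params = params or StabilityParams()
    traj = simulate(stack, GravityDirection(0.0, 0.0), sim_config)
    return StabilityResult(
        score=stability_score(traj, params.epsilon),
        is_stable=is_stable(traj, params.epsilon),
    )


def sample_mgs_directions(
    n: int,
    sigma: float = SIGMA_MGS,
    theta_max: float = 45.0,
    rng: np.random.Generator | None = None,
    g: float = 9.8,
) -> list[GravityDirection]:
    """Draw gravity directions for the mental simulator.

    theta follows the half-Gaussian density ~ exp(-theta^2 / 2 sigma^2)
    truncated to [0, theta_max]; phi is uniform on [0, 360).  sigma = 0
    degenerates to natural gravity.
    """
    rng = rng or np.random.default_rng()
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0.0:
        thetas = np.zeros(n)
    else:
        thetas = stats.truncnorm.rvs(
            0.0, theta_max / sigma, scale=sigma, size=n, random_state=rng
        )
    phis = rng.uniform(0.0, 360.0, size=n)
    return [GravityDirection(float(t), float(p), g) for t, p in zip(thetas, phis)]


def mgs_stability(
    stack: Stack,
    params: StabilityParams | None = None,
    rng: np.random.Generator | None = None,
    sim_config: SimConfig | None = None,
) -> StabilityResult:
    """Mean stability score over Gaussian-tilted gravity simulations."""
    params = params or StabilityParams()
    rng = rng or np.random.default_rng()
    directions = sample_mgs_directions(
        params.n_mgs_samples, params.sigma_mgs, params.theta_max, rng
    )
    scores = tuple(
        stability_score(simulate(stack, d, sim_config), params.epsilon) for d in directions
    )
    mean = float(np.mean(scores))
    return StabilityResult(score=mean, is_stable=mean == 1.0, per_direction_scores=scores)


def inference_bias(est_scores, ref_scores) -> float:
    """Mean difference estimator - reference; negative means the estimator
    judges stacks less stable than the reference does."""
    est = np.asarray(est_scores, dtype=float)
    ref = np.asarray(ref_scores, dtype=float)
    if est.shape != ref.shape:
        raise ValueError(f"length mismatch: {est.shape} vs {ref.shape}")
    return float(np.mean(est - ref))


@dataclass
class HeightIllusionResult:
    """Per-stack scores and per-height-bin inference-bias summary.

    ``spearman_rho`` correlates height with bias across individual stacks
    (diluted by NGS-unstable stacks, whose bias is bounded near zero);
    ``bin_spearman_rho`` correlates the binned curve -- bin height against
    mean bias -- which is the monotone-trend statistic.
    """

    stacks: pd.DataFrame
    bins: pd.DataFrame
    spearman_rho: float
    spearman_p: float
    bin_spearman_rho: float = np.nan
    bin_spearman_p: float = np.nan


def height_illusion_experiment(
    side_lengths,
    n_stable: int,
    n_unstable: int,
    params: StabilityParams | None = None,
    rng: np.random.Generator | None = None,
    sim_config: SimConfig | None = None,
    n_blocks: int = 10,
    n_bins: int = 10,
) -> HeightIllusionResult:
    """Does the stochastic simulator under-rate taller stacks more?

    For each square designated area (placement half-range ``side``), generate
    ``n_stable`` + ``n_unstable`` labeled stacks of ``n_blocks`` blocks, score
    each with NGS and MGS, and aggregate the per-stack inference bias
    IB = MGS - NGS by stack-height bins (quantile bins over all stacks).
    Reports a one-sided t test (mean IB < 0) per bin and the Spearman
    correlation between height and IB.
    """
    side_lengths = list(side_lengths)
    if not side_lengths:
        raise ValueError("side_lengths must be non-empty")
    params = params or StabilityParams()
    rng = rng or np.random.default_rng()

    rows = []
    for side in side_lengths:
        config = StackGenConfig(
            n_blocks=n_blocks,
            area_x=float(side),
            area_y=float(side),
            seed=int(rng.integers(2**31)),
        )
        stacks = generate_labeled_set(n_stable, n_unstable, config, sim_config=sim_config)
        for k, stack in enumerate(stacks):
            ngs = ngs_stability(stack, params, sim_config)
            mgs = mgs_stability(stack, params, rng, sim_config)
            rows.append(
                {
                    "stack_id": f"s{side:g}_{k}",
                    "side": side,
                    "n_blocks": n_blocks,
                    "height": stack.height,
                    "ngs_score": ngs.score,
                    "mgs_score": mgs.score,
                    "ib": mgs.score - ngs.score,
                }
            )
    df = pd.DataFrame(rows)

    df["height_bin"] = pd.qcut(df["height"], q=n_bins, duplicates="drop")
    summaries = []
    for interval, grp in df.groupby("height_bin", observed=True):
        ib = grp["ib"].to_numpy()
        mean = float(ib.mean())
        sem = float(stats.sem(ib)) if len(ib) > 1 else np.nan
        if len(ib) > 1 and np.std(ib) > 0:
            t = stats.ttest_1samp(ib, 0.0, alternative="less")
            p = float(t.pvalue)
        else:
            p = np.nan
        ci = 1.96 * sem if np.isfinite(sem) else np.nan
        summaries.append(
            {
                "height_mid": float(interval.mid),
                "n": len(ib),
                "mean_ib": mean,
                "ci_lo": mean - ci,
                "ci_hi": mean + ci,
                "p_less": p,
            }
        )
    bins = pd.DataFrame(summaries).sort_values("height_mid").reset_index(drop=True)
    rho, rho_p = stats.spearmanr(df["height"], df["ib"])
    brho, brho_p = stats.spearmanr(bins["height_mid"], bins["mean_ib"])
    return HeightIllusionResult(
        stacks=df,
        bins=bins,
        spearman_rho=float(rho),
        spearman_p=float(rho_p),
        bin_spearman_rho=float(brho),
        bin_spearman_p=float(brho_p),
    )
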
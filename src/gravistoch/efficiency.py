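"""Speed-accuracy-efficiency analysis of the two simulators.

A decision maker watching a mental simulation unfold can commit as soon as
the evidence suffices.  We model that with one logistic-regression classifier
per simulation stage: its input is the flattened difference between every
block vertex's position at that stage and at stage 0 (24 features per block),
its target the ground-truth (natural gravity) stability label.  From the
test-accuracy-by-stage curve we read off

    plateau accuracy  = max_t accuracy_t
    response time     = t_hat / T,  t_hat = first stage attaining the max
    efficiency        = plateau accuracy / response time.

The deterministic simulator is more accurate but slow to reveal instability;
the stochastically tilted one collapses sooner, trading accuracy for speed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .physics import GravityDirection, SimConfig, Trajectory, simulate
from .stability import StabilityParams, mgs_stability, sample_mgs_directions
from .stacks import Stack, StackGenConfig, generate_labeled_set


def extract_features(traj: Trajectory, stage: int) -> np.ndarray:
    """Flattened vertex displacements at ``stage`` relative to stage 0.

    Fixed ordering: block-major, then the 8 vertices in lexicographic corner
    order, then x/y/z -- 24 features per block.
    """
    if not (0 <= stage < traj.n_stages):
        raise IndexError(f"stage {stage} out of range [0, {traj.n_stages})")
    v = traj.vertices
    return (v[stage] - v[0]).ravel()


def all_stage_features(traj: Trajectory) -> np.ndarray:
    """(T, 24*M) feature matrix for every stage of one trajectory."""
    v = traj.vertices
    return (v - v[0]).reshape(traj.n_stages, -1).astype(np.float32)


def response_time(accuracy_by_stage) -> tuple[int, float]:
    """(t_hat, time): first 1-based stage attaining the maximum, and t_hat/T."""
    acc = np.asarray(accuracy_by_stage, dtype=float)
    if acc.size == 0:
        raise ValueError("empty accuracy curve")
    t_hat = int(np.argmax(acc)) + 1
    return t_hat, t_hat / acc.size


def efficiency_score(accuracy: float, time: float) -> float:
    if time <= 0:
        raise ValueError("time must be positive")
    return accuracy / time


@dataclass
class ClassifierTrace:
    """Per-stage accuracies of one simulator at one block number."""

    accuracy_by_stage: np.ndarray
    n_blocks: int | None = None
    simulator: str = ""

    @property
    def plateau_accuracy(self) -> float:
        return float(np.max(self.accuracy_by_stage))

    @property
    def t_hat(self) -> int:
        return response_time(self.accuracy_by_stage)[0]

    @property
    def time(self) -> float:
        return response_time(self.accuracy_by_stage)[1]

    @property
    def efficiency(self) -> float:
        return efficiency_score(self.plateau_accuracy, self.time)


@dataclass
class EfficiencyResult:
    traces: dict[int, ClassifierTrace]
    simulator: str

    @property
    def pooled_plateau(self) -> float:
        return float(np.mean([t.plateau_accuracy for t in self.traces.values()]))

    @property
    def pooled_time(self) -> float:
        return float(np.mean([t.time for t in self.traces.values()]))

    @property
    def pooled_efficiency(self) -> float:
        return float(np.mean([t.efficiency for t in self.traces.values()]))

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "simulator": self.simulator,
                "n_blocks": m,
                "plateau_accuracy": t.plateau_accuracy,
                "t_hat": t.t_hat,
                "time": t.time,
                "efficiency": t.efficiency,
            }
            for m, t in sorted(self.traces.items())
        ]
        rows.append(
            {
                "simulator": self.simulator,
                "n_blocks": "pooled",
                "plateau_accuracy": self.pooled_plateau,
                "t_hat": np.nan,
                "time": self.pooled_time,
                "efficiency": self.pooled_efficiency,
            }
        )
        return pd.DataFrame(rows)


def _simulate_features(
    stacks: list[Stack],
    simulator: str,
    params: StabilityParams,
    rng: np.random.Generator,
    sim_config: SimConfig,
) -> np.ndarray:
    """Stack trajectories -> per-stage features, shape (n_stacks, T, F)."""
    feats = []
    for stack in stacks:
        if simulator == "ngs":
            direction = GravityDirection(0.0, 0.0)
        elif simulator == "mgs":
            # one mental simulation pass: a single sampled direction
            direction = sample_mgs_directions(1, params.sigma_mgs, params.theta_max, rng)[0]
        else:
            raise ValueError(f"unknown simulator {simulator!r}")
        feats.append(all_stage_features(simulate(stack, direction, sim_config)))
    return np.stack(feats)


def stagewise_accuracy(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    C: float = 1.0,
) -> np.ndarray:
    """Train/test one logistic classifier per stage.

    X_* have shape (n_stacks, T, F).  Consecutive stages with identical
    features (the scene has gone static) reuse the previous accuracy.
    """
    if len(np.unique(y_train)) < 2:
        raise ValueError("degenerate class balance in training labels")
    T = X_train.shape[1]
    acc = np.empty(T)
    prev_tr = prev_te = None
    for t in range(T):
        Xt, Xe = X_train[:, t, :], X_test[:, t, :]
        if (
            prev_tr is not None
            and np.array_equal(Xt, prev_tr)
            and np.array_equal(Xe, prev_te)
        ):
            acc[t] = acc[t - 1]
            continue
        clf = LogisticRegression(C=C, max_iter=1000)
        clf.fit(Xt, y_train)
        acc[t] = clf.score(Xe, y_test)
        prev_tr, prev_te = Xt, Xe
    return acc


def run_efficiency_experiment(
    block_numbers,
    n_train: int,
    n_test: int,
    simulator: str,
    params: StabilityParams | None = None,
    rng: np.random.Generator | None = None,
    sim_config: SimConfig | None = None,
) -> EfficiencyResult:
    """Per-stage classification of stability from simulated trajectories.

    For each block number, ``n_train`` stable + ``n_train`` unstable training
    stacks and the same test split are generated and labeled by natural
    gravity; trajectories come from the chosen simulator (``mgs`` draws one
    gravity direction per stack); labels are always the NGS ground truth.
    """
    params = params or StabilityParams()
    rng = rng or np.random.default_rng()
    sim_config = sim_config or SimConfig()
    traces: dict[int, ClassifierTrace] = {}
    for m in block_numbers:
        cfg = StackGenConfig(n_blocks=int(m), seed=int(rng.integers(2**31)))
        train_set = generate_labeled_set(n_train, n_train, cfg, sim_config=sim_config)
        cfg2 = StackGenConfig(n_blocks=int(m), seed=int(rng.integers(2**31)))
        test_set = generate_labeled_set(n_test, n_test, cfg2, sim_config=sim_config)
        y_train = np.array([s.label_stable for s in train_set], dtype=int)
        y_test = np.array([s.label_stable for s in test_set], dtype=int)
        X_train = _simulate_features(train_set, simulator, params, rng, sim_config)
        X_test = _simulate_features(test_set, simulator, params, rng, sim_config)
        acc = stagewise_accuracy(X_train, y_train, X_test, y_test)
        traces[int(m)] = ClassifierTrace(acc, n_blocks=int(m), simulator=simulator)
    return EfficiencyResult(traces=traces, simulator=simulator)


def variance_vs_repetitions(
    stacks: list[Stack],
    n_sim_list,
    params: StabilityParams | None = None,
    rng: np.random.Generator | None = None,
    sim_config: SimConfig | None = None,
    n_reps: int = 30,
) -> pd.DataFrame:
    """Variance of the MGS stability estimate vs number of simulations.

    For each n in ``n_sim_list`` the MGS estimate (mean of n sampled-direction
    scores) is recomputed ``n_reps`` times per stack; reported is the
    across-repetition variance averaged over stacks.  Being a mean of i.i.d.
    draws, the variance shrinks like 1/n.
    """
    params = params or StabilityParams()
    rng = rng or np.random.default_rng()
    rows = []
    for n in n_sim_list:
        p = StabilityParams(
            epsilon=params.epsilon,
            n_mgs_samples=int(n),
            sigma_mgs=params.sigma_mgs,
            theta_max=params.theta_max,
        )
        variances = []
        for stack in stacks:
            est = [mgs_stability(stack, p, rng, sim_config).score for _ in range(n_reps)]
            variances.append(np.var(est, ddof=1))
        rows.append({"n_sims": int(n), "variance": float(np.mean(variances))})
    return pd.DataFrame(rows)
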
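"""Config-driven orchestration of the analysis stages.

A run config (TOML via the CLI, or a plain dict) names the stages to execute
and their parameters; stages run in dependency order and deposit artifacts in
``out_dir``.  Every stochastic operation receives a seed derived from the
single top-level seed, so a config reruns to byte-identical results.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import __version__

STAGE_ORDER = ("generate", "simulate", "stability", "synth_observer", "psychfit", "rl_train", "efficiency")
_TOP_KEYS = {"seed", "out_dir", "stages"} | set(STAGE_ORDER)


class ConfigError(ValueError):
    pass


class MissingArtifactError(RuntimeError):
    pass


def _require(artifacts: dict, key: str, needed_by: str, produced_by: str) -> str:
    if key not in artifacts:
        raise MissingArtifactError(
            f"stage '{needed_by}' needs '{key}' which stage '{produced_by}' produces; "
            f"add '{produced_by}' to the config or provide the path explicitly"
        )
    return artifacts[key]


def run_pipeline(config: dict) -> dict:
    """Execute the configured stages; returns the artifact manifest."""
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    seed = int(config.get("seed", 0))
    out_dir = Path(config.get("out_dir", "gravistoch_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages") or [s for s in STAGE_ORDER if s in config]
    bad = [s for s in stages if s not in STAGE_ORDER]
    if bad:
        raise ConfigError(f"unknown stages: {bad}")

    rng = np.random.default_rng(seed)
    stage_seeds = {s: int(rng.integers(2**31)) for s in STAGE_ORDER}
    artifacts: dict[str, str] = {}
    manifest = {"version": __version__, "seed": seed, "stages": {}, "artifacts": artifacts}

    for stage in STAGE_ORDER:
        if stage not in stages:
            continue
        opts = dict(config.get(stage, {}))
        runner = globals()[f"_stage_{stage}"]
        produced = runner(opts, out_dir, stage_seeds[stage], artifacts)
        manifest["stages"][stage] = {"seed": stage_seeds[stage], "options": opts, "outputs": produced}

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _stage_generate(opts, out_dir, seed, artifacts):
    from .physics import SimConfig
    from .stacks import StackGenConfig, generate_labeled_set, generate_stack, save_stacks

    rng = np.random.default_rng(seed)
    cfg = StackGenConfig(
        n_blocks=int(opts.get("n_blocks", 10)),
        area_x=opts.get("area_x"),
        area_y=opts.get("area_y"),
        seed=seed,
    )
    sim_config = SimConfig(n_stages=int(opts.get("n_stages", 500)))
    stacks = []
    n_stable = int(opts.get("n_stable", 0))
    n_unstable = int(opts.get("n_unstable", 0))
    if n_stable or n_unstable:
        stacks += generate_labeled_set(n_stable, n_unstable, cfg, sim_config=sim_config, rng=rng)
    for _ in range(int(opts.get("n_any", 0))):
        stacks.append(
            generate_stack(
                StackGenConfig(
                    n_blocks=cfg.n_blocks,
                    area_x=cfg.area_x,
                    area_y=cfg.area_y,
                    seed=int(rng.integers(2**31)),
                )
            )
        )
    path = str(out_dir / "stacks.json")
    save_stacks(stacks, path)
    artifacts["stacks"] = path
    return {"stacks": path}


def _stage_simulate(opts, out_dir, seed, artifacts):
    from .physics import GravityDirection, SimConfig, simulate
    from .stacks import load_stacks

    path = opts.get("stacks") or _require(artifacts, "stacks", "simulate", "generate")
    stacks = load_stacks(path)
    direction = GravityDirection(float(opts.get("theta", 0.0)), float(opts.get("phi", 0.0)))
    cfg = SimConfig(n_stages=int(opts.get("n_stages", 500)))
    arrays = {}
    for k, stack in enumerate(stacks):
        traj = simulate(stack, direction, cfg)
        arrays[f"centers_{k}"] = traj.centers
        arrays[f"vertices_{k}"] = traj.vertices
    out = str(out_dir / "trajectories.npz")
    np.savez_compressed(out, **arrays)
    artifacts["trajectories"] = out
    return {"trajectories": out}


def _stage_stability(opts, out_dir, seed, artifacts):
    import pandas as pd

    from .physics import SimConfig
    from .stability import StabilityParams, mgs_stability, ngs_stability
    from .stacks import load_stacks

    path = opts.get("stacks") or _require(artifacts, "stacks", "stability", "generate")
    stacks = load_stacks(path)
    params = StabilityParams(
        n_mgs_samples=int(opts.get("n_samples", 100)),
        sigma_mgs=float(opts.get("sigma", 18.6)),
    )
    sim_config = SimConfig(n_stages=int(opts.get("n_stages", 500)))
    mode = opts.get("mode", "ngs")
    rng = np.random.default_rng(seed)
    rows = []
    for k, stack in enumerate(stacks):
        ngs = ngs_stability(stack, params, sim_config)
        row = {"stack_id": k, "n_blocks": stack.n_blocks, "height": stack.height, "ngs_score": ngs.score}
        if mode == "mgs":
            mgs = mgs_stability(stack, params, rng, sim_config)
            row["mgs_score"] = mgs.score
            row["ib"] = mgs.score - ngs.score
        rows.append(row)
    out = str(out_dir / "stability.csv")
    pd.DataFrame(rows).to_csv(out, index=False)
    artifacts["stability"] = out
    return {"stability": out}


def _stage_synth_observer(opts, out_dir, seed, artifacts):
    from .psychophysics import trials_to_frame
    from .synthetic_observer import ObserverSpec, simulate_observer

    spec = ObserverSpec(
        sigma_true=float(opts.get("sigma_true", 19.9)),
        amplitude=float(opts.get("amplitude", 0.91)),
        n_runs=int(opts.get("n_runs", 4)),
        seed=seed,
    )
    trials = simulate_observer(spec)
    out = str(out_dir / "trials.csv")
    trials_to_frame(trials).to_csv(out, index=False)
    artifacts["trials"] = out
    return {"trials": out}


def _stage_psychfit(opts, out_dir, seed, artifacts):
    import pandas as pd

    from .psychophysics import confidence_ratios, fit_gaussian_sensitivity, marginalize_theta, trials_from_frame

    path = opts.get("trials") or _require(artifacts, "trials", "psychfit", "synth_observer")
    trials = trials_from_frame(pd.read_csv(path))
    thetas, means = marginalize_theta(confidence_ratios(trials))
    fit = fit_gaussian_sensitivity(thetas, means)
    out = str(out_dir / "psychfit.json")
    Path(out).write_text(json.dumps({"A": fit.A, "sigma": fit.sigma, "rss": fit.rss}, indent=1))
    artifacts["psychfit"] = out
    return {"psychfit": out}


def _stage_rl_train(opts, out_dir, seed, artifacts):
    from .rl_origin import RLConfig, fit_grid_sigma, train

    blocks = opts.get("blocks", "2-15")
    lo, hi = (int(v) for v in str(blocks).split("-"))
    cfg = RLConfig(
        gamma=float(opts.get("gamma", 0.15)),
        n_configs=int(opts.get("n_configs", 100_000)),
        block_range=(lo, hi),
        n_stages=int(opts.get("n_stages", 500)),
        seed=seed,
    )
    grid, trace = train(cfg)
    out = str(out_dir / "rl_grid.npz")
    np.savez_compressed(out, W=grid.W, theta_axis=grid.theta_axis, phi_axis=grid.phi_axis)
    fit = fit_grid_sigma(grid)
    meta = str(out_dir / "rl_grid.json")
    Path(meta).write_text(
        json.dumps({"sigma": fit.sigma, "A": fit.A, "baseline": fit.baseline, "n_skipped": trace.n_skipped}, indent=1)
    )
    artifacts["rl_grid"] = out
    return {"rl_grid": out, "rl_fit": meta}


def _stage_efficiency(opts, out_dir, seed, artifacts):
    import pandas as pd

    from .efficiency import run_efficiency_experiment
    from .physics import SimConfig
    from .stability import StabilityParams

    blocks = opts.get("blocks", "2-10")
    lo, hi = (int(v) for v in str(blocks).split("-"))
    params = StabilityParams(sigma_mgs=float(opts.get("sigma", 18.6)))
    sim_config = SimConfig(n_stages=int(opts.get("n_stages", 500)))
    frames = []
    for kind in ("ngs", "mgs"):
        rng = np.random.default_rng(seed)
        res = run_efficiency_experiment(
            range(lo, hi + 1),
            int(opts.get("n_train", 100)),
            int(opts.get("n_test", 100)),
            kind,
            params,
            rng,
            sim_config,
        )
        frames.append(res.summary())
    out = str(out_dir / "efficiency.csv")
    pd.concat(frames).to_csv(out, index=False)
    artifacts["efficiency"] = out
    return {"efficiency": out}
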
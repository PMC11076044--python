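"""Static plot helpers (matplotlib optional; import on demand)."""

from __future__ import annotations

import numpy as np


def _plt():
    try:
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("plotting requires matplotlib (pip install gravistoch[plot])") from exc
    return plt


def plot_stack_snapshot(traj, stage: int = 0, ax=None):
    """Top-and-side outline of every block at one trajectory stage."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    verts = traj.vertices[stage]
    for m in range(verts.shape[0]):
        v = verts[m]
        xs, zs = v[:, 0], v[:, 2]
        ax.scatter(xs, zs, s=6)
        ax.plot([xs.min(), xs.max(), xs.max(), xs.min(), xs.min()],
                [zs.min(), zs.min(), zs.max(), zs.max(), zs.min()], lw=0.8)
    ax.axhline(0.0, color="k", lw=1)
    ax.set_xlabel("x")
    ax.set_ylabel("z")
    ax.set_title(f"stage {stage}")
    return ax


def plot_tuning_curve(thetas, ratios, fit=None, ax=None):
    """Phi-marginal acceptance ratios and (optionally) the Gaussian fit."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.plot(thetas, ratios, "o", ms=4, label="confidence ratio")
    if fit is not None:
        grid = np.linspace(min(thetas), max(thetas), 200)
        ax.plot(
            grid,
            fit.baseline + fit.A * np.exp(-(grid**2) / (2 * fit.sigma**2)),
            label=f"Gaussian fit (sigma={fit.sigma:.1f})",
        )
    ax.set_xlabel("theta (deg)")
    ax.set_ylabel("p(judged normal)")
    ax.legend(frameon=False)
    return ax


def plot_direction_grid(grid, ax=None):
    """Heatmap of the sampling weights over (theta, phi)."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    im = ax.imshow(
        grid.W,
        origin="lower",
        aspect="auto",
        extent=[grid.phi_axis[0], grid.phi_axis[-1], grid.theta_axis[0], grid.theta_axis[-1]],
    )
    ax.set_xlabel("phi (deg)")
    ax.set_ylabel("theta (deg)")
    plt.colorbar(im, ax=ax, label="sampling weight")
    return ax
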
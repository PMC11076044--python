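"""Tuning curves over gravity directions and the Gaussian sensitivity fit.

An observer watches collapse trajectories simulated under gravity tilted by
(theta, phi) and reports whether each looked "normal".  The per-angle-pair
acceptance ratio n/N forms a tuning curve on the design grid
theta in {0, 3, ..., 45} deg x phi in {0, 24, ..., 336} deg; pairs never
sampled inherit the mean ratio over phi at the same theta.  Sensitivity is
the width sigma of the least-squares fit

    Ratio(theta) = A * exp(-theta^2 / (2 sigma^2))

to the phi-marginalized curve: a small sigma means abnormal tilts are
detected quickly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

THETA_GRID = np.arange(0.0, 46.0, 3.0)  # 16 values
PHI_GRID = np.arange(0.0, 360.0, 24.0)  # 15 distinct directions


@dataclass(frozen=True)
class TrialRecord:
    """One binary normal/abnormal judgment of a collapse trajectory."""

    theta: float
    phi: float
    response: bool
    run_id: int = 0


@dataclass
class TuningCurve:
    """Acceptance ratios on the (theta, phi) design grid.

    ``ratios[i, j]`` is the ratio at (theta_grid[i], phi_grid[j]);
    ``sampled[i, j]`` marks pairs that had actual trials (the rest are
    phi-averages at the same theta).
    """

    ratios: np.ndarray
    sampled: np.ndarray
    theta_grid: np.ndarray
    phi_grid: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        th, ph = np.meshgrid(self.theta_grid, self.phi_grid, indexing="ij")
        return pd.DataFrame(
            {
                "theta": th.ravel(),
                "phi": ph.ravel(),
                "ratio": self.ratios.ravel(),
                "sampled": self.sampled.ravel(),
            }
        )


@dataclass(frozen=True)
class GaussianFit:
    A: float
    sigma: float
    rss: float
    baseline: float = 0.0


class FitError(RuntimeError):
    pass


def trials_to_frame(trials) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "theta": [t.theta for t in trials],
            "phi": [t.phi for t in trials],
            "response": [bool(t.response) for t in trials],
            "run_id": [t.run_id for t in trials],
        }
    )


def trials_from_frame(df: pd.DataFrame) -> list[TrialRecord]:
    return [
        TrialRecord(float(r.theta), float(r.phi), bool(r.response), int(r.run_id))
        for r in df.itertuples()
    ]


def confidence_ratios(
    trials,
    theta_grid: np.ndarray = THETA_GRID,
    phi_grid: np.ndarray = PHI_GRID,
) -> TuningCurve:
    """Per-pair acceptance ratio n/N; unsampled pairs get the phi-average.

    Every theta on the grid must have at least one sampled phi, otherwise its
    unsampled cells cannot be interpolated.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("no trials")
    nt, npj = len(theta_grid), len(phi_grid)
    acc = np.zeros((nt, npj))
    cnt = np.zeros((nt, npj))
    t_index = {round(float(t), 6): i for i, t in enumerate(theta_grid)}
    p_index = {round(float(p), 6): j for j, p in enumerate(phi_grid)}
    for tr in trials:
        i = t_index.get(round(float(tr.theta), 6))
        j = p_index.get(round(float(tr.phi) % 360.0, 6))
        if i is None or j is None:
            raise ValueError(f"trial at ({tr.theta}, {tr.phi}) off the design grid")
        cnt[i, j] += 1
        acc[i, j] += bool(tr.response)
    sampled = cnt > 0
    ratios = np.zeros((nt, npj))
    ratios[sampled] = acc[sampled] / cnt[sampled]
    for i in range(nt):
        if not sampled[i].any():
            raise ValueError(f"theta={theta_grid[i]} has no sampled phi; cannot interpolate")
        fill = ratios[i, sampled[i]].mean()
        ratios[i, ~sampled[i]] = fill
    return TuningCurve(ratios, sampled, np.asarray(theta_grid, float), np.asarray(phi_grid, float))


def marginalize_theta(curve: TuningCurve) -> tuple[np.ndarray, np.ndarray]:
    """Mean ratio over phi for each theta; returns (thetas, means) in theta order."""
    order = np.argsort(curve.theta_grid)
    return curve.theta_grid[order], curve.ratios[order].mean(axis=1)


def _gauss(theta, A, sigma):
    return A * np.exp(-(theta**2) / (2.0 * sigma**2))


def _gauss_b(theta, A, sigma, b):
    return b + A * np.exp(-(theta**2) / (2.0 * sigma**2))


def fit_gaussian_sensitivity(
    thetas,
    ratios,
    p0: tuple[float, float] | None = None,
    with_baseline: bool = False,
) -> GaussianFit:
    """Least-squares fit of A*exp(-theta^2/2 sigma^2) to marginal ratios.

    Bounds A in (0, 1.5], sigma in (0, 90] deg; initialized at the maximum
    ratio and sigma = 20.  With ``with_baseline`` a constant offset b >= 0 is
    added to the model (used for partially converged weight grids, where
    weight mass left over from initialization floors the curve).  Degenerate
    (constant) data raises FitError.
    """
    thetas = np.asarray(thetas, dtype=float)
    ratios = np.asarray(ratios, dtype=float)
    if thetas.size < 3 or np.unique(thetas).size < 3:
        raise FitError("need at least 3 distinct theta values")
    if np.allclose(ratios, ratios[0]):
        raise FitError("degenerate (constant) tuning data")
    if p0 is None:
        p0 = (max(float(ratios.max()), 1e-3), 20.0)
    try:
        if with_baseline:
            popt, _ = curve_fit(
                _gauss_b,
                thetas,
                ratios,
                p0=(p0[0], p0[1], float(ratios.min())),
                bounds=([1e-6, 1e-3, 0.0], [1.5, 90.0, 1.0]),
                maxfev=10_000,
            )
            A, sigma, b = (float(v) for v in popt)
        else:
            popt, _ = curve_fit(
                _gauss,
                thetas,
                ratios,
                p0=p0,
                bounds=([1e-6, 1e-3], [1.5, 90.0]),
                maxfev=10_000,
            )
            A, sigma = float(popt[0]), float(popt[1])
            b = 0.0
    except RuntimeError as exc:
        raise FitError(f"Gaussian fit did not converge: {exc}") from exc
    rss = float(np.sum((_gauss_b(thetas, A, sigma, b) - ratios) ** 2))
    return GaussianFit(A=A, sigma=sigma, rss=rss, baseline=b)


def fit_trials(trials) -> GaussianFit:
    """Convenience: trials -> tuning curve -> phi-marginal -> Gaussian fit."""
    thetas, means = marginalize_theta(confidence_ratios(trials))
    return fit_gaussian_sensitivity(thetas, means)
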
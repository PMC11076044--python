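"""Parameter recovery: synthetic observer -> Gaussian tuning fit.

A synthetic observer accepts collapse trajectories with probability
0.91 * exp(-theta^2 / (2 * 19.9^2)); fitting the acceptance ratios on the
design grid recovers the generating width.
"""

from gravistoch.psychophysics import confidence_ratios, fit_gaussian_sensitivity, marginalize_theta
from gravistoch.synthetic_observer import ObserverSpec, simulate_observer

spec = ObserverSpec(sigma_true=19.9, amplitude=0.91, n_runs=4, seed=21)
trials = simulate_observer(spec)
print(f"{len(trials)} trials over 4 runs (96 angle pairs each)")

curve = confidence_ratios(trials)
thetas, means = marginalize_theta(curve)
fit = fit_gaussian_sensitivity(thetas, means)
print(f"generating sigma = {spec.sigma_true}")
print(f"recovered  sigma = {fit.sigma:.1f}  (A = {fit.A:.2f}, rss = {fit.rss:.4f})")
# the fitted sigma is the observer's sensitivity to gravity's direction:
# at theta = sigma the acceptance probability has dropped to ~61% of its peak
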
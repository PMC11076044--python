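"""Speed-accuracy trade-off: per-stage classifiers on NGS vs MGS trajectories.

Small run (3-block stacks, 20+20 train / 20+20 test, 200 stages).  The
deterministic simulator reaches higher plateau accuracy; the stochastic one
reaches its (lower) plateau much earlier, so its accuracy/time efficiency is
higher -- quick, slightly sloppy decisions beat slow perfect ones.
"""

import numpy as np

from gravistoch.efficiency import run_efficiency_experiment
from gravistoch.physics import SimConfig
from gravistoch.stability import StabilityParams

params = StabilityParams()  # MGS tilt width sigma = 18.6 deg
sim = SimConfig(n_stages=200)

for kind in ("ngs", "mgs"):
    rng = np.random.default_rng(42)
    res = run_efficiency_experiment([3], 20, 20, kind, params, rng, sim)
    trace = res.traces[3]
    print(
        f"{kind}: plateau accuracy={trace.plateau_accuracy:.2f}  "
        f"first reached at stage {trace.t_hat}/200 (time={trace.time:.2f})  "
        f"efficiency={trace.efficiency:.2f}"
    )
# plateau = best achievable accuracy from the simulated evidence;
# time = fraction of the simulation needed to reach it; efficiency = ratio
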
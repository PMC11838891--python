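"""Hierarchical regime structure of a surrogate connectome network.

Simulates a 12-population network on a random symmetric connectivity
matrix, fits TVART at increasing prediction delays, and counts
temporal-mode clusters as a function of the dendrogram distance cutoff
(Manhattan metric).  Longer delays unfold more distinct regimes.
"""

import numpy as np

import tvartlab as tl
from tvartlab.tvart import TVARTConfig, build_windows, fit_tvart

C = tl.surrogate_connectivity(12, density=0.3, seed=0)
params = tl.highdim_parameters(C, G=0.08, sigma=0.5)
attractors = tl.find_fixed_points(params, n_seeds=120, seed=1)
print(f"surrogate network: N = 12, stable fixed points: {attractors.n_stable}")

settings = tl.SimulationSettings(duration=130.0, burn_in=10.0,
                                 downsample_period=5e-3, seed=2)
traj = tl.simulate_heun(params, settings)

cutoffs = [0.25, 0.5, 1.0]
print("\n delay   clusters at cutoff " + str(cutoffs))
for delay in (1, 11, 31):
    data = build_windows(traj, 100, delay)
    fit = fit_tvart(data, TVARTConfig(window_M=100, rank_R=6, delay_steps=delay,
                                      eta=10.0, beta=0.1, max_iter=30, seed=0))
    U3 = fit.U3 / np.abs(fit.U3).max()
    curve = tl.hierarchical_cluster_curve(U3, cutoffs)
    print(f"  {delay:>4}   {curve.counts.tolist()}")

print("\nEach row counts flat clusters of the per-window temporal modes; "
      "growth with delay shows the regimes becoming separable once the "
      "dynamics have time to unfold.")
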
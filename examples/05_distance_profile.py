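"""Distance-resolved order parameter: local versus global synchrony.

Simulates the data-like and power-law-only networks at moderate coupling
and prints r(d), the universal order parameter restricted to node pairs
within distance d. Both networks are coherent at short range; only the
residual-bearing network extends coherence to the whole-brain scale.
"""

import numpy as np

from connsync import (SimConfig, SynthConfig, build_power_law_network,
                      compute_residuals, default_distance_grid,
                      fit_distance_model, generate_connectome,
                      order_parameter_profile, pairwise_coherence,
                      predict_baseline, simulate)

conn, _ = generate_connectome(SynthConfig(seed=0))
fit = fit_distance_model(conn)
K = build_power_law_network(predict_baseline(fit, conn.distances))
d = conn.distances

grid = default_distance_grid(d, n_points=8)
print(f"{'d (um)':>10s} {'r(d) data-like':>15s} {'r(d) power-law':>15s}")
rows = {}
for name, A in (("data", conn.weights), ("plaw", K)):
    cfg = SimConfig(k=45.0, sigma_n=1.0, n_steps=20_000, seed=3,
                    delays_enabled=False)
    traj = simulate(A, None, cfg)
    C = pairwise_coherence(traj)
    _, rows[name] = order_parameter_profile(C, A, d, grid)
for g, dv in enumerate(grid):
    print(f"{dv:10.0f} {rows['data'][g]:15.3f} {rows['plaw'][g]:15.3f}")
print("\n-> r(d) decreases with spatial scale in both networks, but the"
      "\n   drop from local to whole-network coherence is much larger for"
      "\n   the strictly distance-ruled network")
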
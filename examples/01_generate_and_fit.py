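"""Generate a synthetic spatially embedded connectome and fit its distance rule.

Builds the package's default 100-region network — power-law weight decay
with heavy log-scale scatter plus 60 injected strong residual edges — then
fits the power-law and exponential distance laws and extracts the residual
field. The printed numbers show that the power law wins the model
comparison and that a sparse positive residual tail survives above it.
"""

import numpy as np

from connsync import (SynthConfig, compute_residuals, fit_distance_model,
                      generate_connectome)

conn, info = generate_connectome(SynthConfig(seed=0))
print(f"connectome: {conn.n_regions} regions, "
      f"{int((conn.weights > 0).sum())} weighted edges, "
      f"total strength {conn.weights.sum():.2f}")

power = fit_distance_model(conn, model="power_law")
expo = fit_distance_model(conn, model="exponential")
print(f"power law:   alpha={power.alpha:.3g}  beta={power.beta:.3f}  "
      f"r^2={power.r_square:.3f}  rmse={power.rmse:.3f} (log10 scale)")
print(f"exponential: alpha={expo.alpha:.3g}  rate={expo.beta:.3g}  "
      f"r^2={expo.r_square:.3f}  rmse={expo.rmse:.3f}")
print("-> the power law explains the weight-distance relation better,"
      " as on the mouse mesoscale connectome")

res = compute_residuals(conn, power)
vals = res.positive_values()
print(f"residual field: {res.stats['n_positive']} positive edges carrying "
      f"mass {res.positive_mass():.2f}, skewness {res.stats['skew']:.1f}")
top60_share = np.sort(vals)[-60:].sum() / vals.sum()
print(f"strongest positive residual {vals.max():.3f}; the top 60 edges carry "
      f"{100 * top60_share:.0f}% of the tail mass"
      " -> a sparse set of strong connections above the distance rule")
covered = sum(res.positive_mask[i, j] for i, j in info["injected_edges"])
print(f"ground truth: {covered}/{len(info['injected_edges'])} injected edges "
      "recovered as positive residuals")
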
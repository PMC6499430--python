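# connsync

Synchronization analysis of spatially embedded, weighted, directed brain
networks: fit the distance rule of a mesoscale connectome, extract the
residual connections the rule cannot explain, rebuild the network with
those residuals restored, shuffled or relocated, run delayed noisy phase
oscillators on every variant, and quantify how sharply — and how locally —
each network synchronizes.

## The problem

Region-level connectomes are strongly spatially organized: connection
strength decays with interregional Euclidean distance roughly as a power
law, `W_ij ≈ α d_ij^(−β)`. But a sparse set of connections is far
*stronger* than the distance rule predicts — a long positive tail of
residuals `ε_ij = W_ij − α d_ij^(−β)` spread over many edge lengths. Do
these residual connections matter for network dynamics, or is the distance
rule alone a sufficient description?

`connsync` answers this with Kuramoto-type phase oscillators on the
network,

    dθ_i/dt = ω_i + k Σ_j A_ij sin(θ_j(t − τ_ij) − θ_i(t)) + η_i(t),

with distance-dependent conduction delays `τ_ij = d_ij / v` and white
noise of variance `σ_n²/T`, and with coherence measured by the *universal*
order parameter for weighted directed graphs,

    r = (Σ_ij A_ij ⟨cos(θ_i − θ_j)⟩_t) / Σ_i k_i,   k_i = Σ_j A_ij,

its distance-resolved version `r(d)` (pairs within distance `d`), and two
summary statistics: `Γ_k = max Δr/Δk`, the maximum sensitivity of
coherence to the global coupling coefficient, and
`Γ_d = ⟨r(d_short) − r(d_long)⟩_k`, the gap between local and global
coherence. Networks whose strong connections span many spatial scales
switch coherence states sharply (high `Γ_k`, low `Γ_d`); strictly
distance-ruled networks stay locally coherent (low `Γ_k`, high `Γ_d`).

The package ships a seeded synthetic-connectome generator with the
statistical structure this analysis assumes (power-law decay, heavy
log-scale scatter, injected strong residual edges with ground truth), so
the whole pipeline is testable end to end without any data download. It is
intended for computational neuroscientists and network scientists studying
spatial constraints on synchronization.

## Worked example

```python
import numpy as np
from connsync import (SynthConfig, generate_connectome, fit_distance_model,
                      compute_residuals, predict_baseline,
                      build_power_law_network, SimConfig, simulate,
                      pairwise_coherence, universal_order_parameter)

conn, info = generate_connectome(SynthConfig(seed=0))   # 100 regions
fit = fit_distance_model(conn)                          # log10-scale OLS
print(fit.beta, fit.r_square)                           # 2.827 0.196

res = compute_residuals(conn, fit)
print(res.positive_mass())                              # 9.98

K = build_power_law_network(predict_baseline(fit, conn.distances))
for name, A in (("data", conn.weights), ("power law", K)):
    cfg = SimConfig(k=45.0, sigma_n=1.0, n_steps=20_000,
                    delays_enabled=False, seed=3)
    traj = simulate(A, None, cfg)
    r = universal_order_parameter(pairwise_coherence(traj), A)
    print(f"{name}: r = {r:.3f}")
# data: r = 0.561
# power law: r = 0.214
```

The fitted exponent (2.827) sits near the decay of the generating rule;
the low `r²` says most log-weight variance is scatter around the trend, as
on real mesoscale data. At the same coupling, the residual-bearing network
is globally coherent (r ≈ 0.56) while the strictly distance-ruled network
with the same spatial embedding is not (r ≈ 0.21): the sparse strong
connections above the distance rule carry the global synchrony.

The `examples/` directory holds one short script per capability
(generation + fitting, the closed-form two-oscillator check, variant
construction and strength conservation, a coupling sweep with Γ
statistics, and the distance-resolved profile); each prints the numbers it
computes and what they mean. A thin CLI mirrors the pipeline stages:

```bash
connsync synth --n 100 --seed 1 --out bundle/
connsync fit bundle/
connsync sweep --config experiment.yaml --out sweep_out/
connsync report sweep_out/
```

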
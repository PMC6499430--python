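"""Coupling sweep comparing residual-bearing and distance-ruled dynamics.

Runs a scaled-down sweep of the global coupling coefficient k for the
data-like network (distance rule + residuals) and the power-law-only
network, computing the universal order parameter and the Γ statistics.
The data-like network shows the larger maximum sensitivity Γ_k (it can
switch coherence states sharply), while the power-law-only network shows
the larger spatial coherence gap Γ_d (its synchrony stays local).

Takes about a minute on one core; pass a smaller grid to go faster.
"""

from connsync import (ExperimentConfig, SimConfig, SynthConfig, VariantSpec,
                      run_sweep)

config = ExperimentConfig(
    connectome=SynthConfig(seed=0),
    variants=(
        VariantSpec("top_residual_fraction", fraction_or_percentile=1.0,
                    name="data_like"),
        VariantSpec("power_law_only"),
    ),
    sweep_grid=(10.0, 20.0, 45.0, 100.0),
    repeats=3,
    base_sim=SimConfig(sigma_n=1.0, n_steps=20_000, delays_enabled=False),
    master_seed=0,
)
result = run_sweep(config)

print("order parameter vs coupling (mean over repeats):")
print(result.curves.to_string(index=False))
print("\nsensitivity statistics:")
print(result.gamma[["variant", "gamma_k", "gamma_d"]].to_string(index=False))
print("\n-> Γ_k(data-like) > Γ_k(power-law): residuals across spatial scales"
      "\n   let the network switch coherence states sharply; Γ_d orders the"
      "\n   other way: without residuals, coherence stays local")
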
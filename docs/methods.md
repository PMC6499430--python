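# Methods

`connsync` studies how the spatial embedding of a weighted, directed
region-level brain network shapes its synchronization dynamics. This note
documents the models, the synthetic study conditions, the numerical
choices, and the known limitations.

## The connectome and its distance rule

A connectome is a set of `n` region labels, 3-D centroid coordinates in
micrometres, and an `n × n` non-negative weight matrix with the convention
**rows = targets**: `W[i, j]` is the strength of the projection from source
region `j` to target region `i`, so the input strength of node `i` is
`k_i = Σ_j W[i, j]`. Weights are normalized to `[0, 1]` by their global
maximum after zeroing the diagonal; interregional distances are always
recomputed from the centroids so the distance matrix is guaranteed metric.
Two-hemisphere networks are assembled from an ipsilateral and a
contralateral block under mirror symmetry, `[[ipsi, contra], [contra,
ipsi]]`, with the second hemisphere's centroids reflected across a midline
plane.

Mesoscale connectomes show a strong decay of connection strength with
Euclidean centroid distance. The package fits

    W_ij = α · d_ij^(−β) + ε_ij          (power law)
    W_ij = α · exp(−β d_ij) + ε_ij       (exponential alternative)

by ordinary least squares on the log10 scale over strictly positive
off-diagonal weights (the default, under which the power law wins the
model comparison on mouse data), or by Levenberg–Marquardt nonlinear least
squares on the linear scale. Zero-weight edges are excluded from log-scale
fits because their logarithm is undefined; `n_edges_used` reports the
count that entered the fit. `r²` and rmse are computed on the fit scale.
Ipsilateral and contralateral blocks of bilateral networks can be fitted
separately (`fit_bilateral`) and the baseline assembled blockwise.

The **residual field** `ε_ij = W_ij − α d_ij^(−β)` is computed on the
linear weight scale, because all network restructurings manipulate residual
*strengths*; its sparse, strong positive tail — connections stronger than
the distance rule predicts, spread over many edge lengths — is the object
of the whole analysis.

## Restructured network variants

All variants start from the fitted baseline `K` (the strictly
distance-ruled network) and manipulate only the positive residuals;
negative residuals are never restored or moved:

- **top-residual restoration**: the strongest fraction `p` of positive
  residuals added back at their original edges (ties at the threshold all
  included); `p = 1` restores the data network on every positive-residual
  edge;
- **shuffle**: the multiset of positive residual values is placed on
  uniformly random distinct off-diagonal edges (stacking onto an edge that
  already carries a residual is allowed; values add);
- **window relocation**: the *total* positive residual mass is split
  equally over all edges whose length falls in `[d_min, d_max)` —
  proximal or distal windows concentrate the extra strength at one
  spatial scale;
- **longest-fraction relocation**: the window `(cutoff, ∞)`, with the
  whole-brain cutoff list for the longest 1–90 % of edges exposed as
  `LONGEST_EDGE_CUTOFFS_UM`.

Every relocation variant conserves total network strength (baseline plus
positive residual mass) to machine precision, so dynamical differences
between variants isolate the effect of residual *location*, not total
coupling.

## Phase dynamics

Each region is a Kuramoto-type phase oscillator:

    dθ_i/dt = ω_i + k Σ_j A_ij sin(θ_j(t − τ_ij) − θ_i(t)) + η_i(t)

- natural frequencies `ω_i = 2π f_i` with `f_i ~ Normal(f0, σ_d²)` in Hz
  (default `f0 = 40` Hz, in the gamma band; `σ_d = 0` makes them
  identical). Angular units are used inside the sine; the paper-style
  frequency parameters are quoted in Hz.
- conduction delays `τ_ij = d_ij / v` with a fixed speed `v = 3.5` m/s,
  rounded to whole Euler steps (error ≤ 0.05 ms at the default step);
- Gaussian white noise with autocorrelation `δ(t−t′) σ_n² / T`, `T = 1` s;
  the Euler noise increment is `sqrt(Δt σ_n²/T) ξ`, `ξ ~ N(0,1)`, applied
  from step 0 (including burn-in);
- forward-Euler integration with `Δt = 1e−4` s for `n_steps = 40 000`
  (4 s) by default, the first half discarded before any averaging.

The step size is checked against the heuristic stability bound
`Δt ≤ 0.01 / max(max(k A_ij), 0.05 μ, σ_n²/2T, 1)` with `μ` read as the
mean angular frequency `2π f0` (the most conservative reading);
`validate_timestep` reports which term binds, and the sweep driver refuses
configurations whose largest swept coupling violates the bound.

Implementation: phases are kept unwrapped during integration and wrapped
only at output. The delay term uses ring buffers of the sine and cosine of
the phase history, updated one row per step, so the per-step cost is
`O(n²)` multiply–adds but only `O(n)` trigonometric evaluations; the
delay history before `t = 0` is the initial condition held constant. The
kernel is JIT-compiled with numba when available; a vectorized numpy
implementation of the identical recurrence is the fallback and agrees with
the numba path to ~1e−13. Zero-delay runs use a matrix-product fast path.
Trajectories are thinned (default every 10th retained step) before the
coherence average; the thinning is a documented deviation knob with a
convergence test, and all pre-generated noise for a run is held in memory
(`n_steps × n` doubles).

## Coherence measures

All metrics derive from the phase coherence matrix
`C_ij = ⟨cos(θ_i − θ_j)⟩_t` over the retained window:

- the **universal order parameter** `r = Σ_ij A_ij C_ij / Σ_i k_i`,
  which weights pairwise coherence by connection strength and so compares
  fairly across networks of different topology and total strength;
- **Kuramoto's order parameter**: both `r²_K = ⟨|N⁻¹ Σ e^{iθ}|²⟩_t`
  (identically the unweighted mean of `C`, including the diagonal) and its
  square root are returned; on an unweighted all-to-all network with
  self-loops `r_universal = r²_K` exactly, which is verified to 1e−12;
- the **distance-resolved profile** `r(d)`: the same strength-weighted
  average restricted to pairs with `d_ij ≤ d` (closed ball), with input
  strengths recomputed inside the restriction; at the maximal distance it
  equals the whole-network `r` exactly. The default grid is 40 log-spaced
  distances; grid points with no coupled pair are NaN, never interpolated;
- **Γ_k**, the maximum forward-difference slope of `r` against a control
  parameter (capacity for sharp state switching), and **Γ_d**, the mean
  over the sweep of `r(d_shortest) − r(d_longest)` (how local coherence
  stays), where `r(d_shortest)` is the best sub-threshold profile value.
  The short-range threshold defaults to 570 μm (the resolution-limited
  local scale of the mouse data); on synthetic networks the pipeline uses
  the 5th percentile of edge lengths instead, since the absolute scale is
  geometry-dependent. Γ may be computed on the repeat-averaged curve (the
  pipeline's `gamma_k` column) or per repeat and averaged
  (`gamma_k_repeat_mean`); both are reported because either convention is
  defensible.

## The synthetic connectome generator

The generator is the package's study system: region centroids uniform in a
10 mm cube (two mirrored half-domains when bilateral), baseline weights
`α d^(−β) · 10^z` with `z ~ N(0, log_noise_sd²)`, diagonal zeroed, matrix
normalized to max 1; then `n_residuals` distinct edges receive additive
lognormal increments (median `residual_scale`, log-SD `residual_log_sd`)
and the matrix is re-normalized. The injected-edge list is returned as
ground truth. Placement is unrestricted by default (`across_scales`) or
confined to the shortest/longest 0.2 % of edge lengths.

Defaults and why:

| parameter | default | rationale |
| --- | --- | --- |
| `n_regions` | 100 | two-digit scale that keeps a full sweep on one core in minutes |
| `box_extent` | 10 000 μm | mouse-brain spatial scale (longest edges ~12 mm) |
| `alpha`, `beta` | 6.92e6, 2.886 | the ipsilateral power-law fit of the mouse mesoscale connectome |
| `log_noise_sd` | 1.1 | reproduces the observed goodness of fit (log-scale rmse ≈ 1.09, r² ≈ 0.2–0.26): on the real network the scatter, not the distance trend, dominates log-weight variance |
| `n_residuals` | 60 | ~0.6 % of directed edges: sparse, several strong inputs per involved node |
| `residual_scale`, `residual_log_sd` | 0.05, 0.5 | individually strong edges (above the locking threshold in the study's coupling range) with a positive-tail mass of the order of the network's total strength |

The scatter law around the trend is not identified by the data; the
lognormal choice is a two-parameter stand-in for "multiplicative, positive,
heavy-tailed" and is flagged as such.

What the generator does **not** emulate: anatomical region geometry and
volumes, the spatial clustering of real centroids (uniform placement gives
sparser short-range neighbourhoods than a brain), reciprocity and
community structure of residuals, and hemisphere-specific asymmetries.
Passing tests therefore show that the *methods* behave as specified on
networks with the assumed statistical structure — not that any particular
biological claim holds for a specific brain.

## Scaled-down study conditions

The headline comparison — data-like network versus power-law-only,
proximal- and distal-relocated variants — runs on one fixed default
connectome (generator seed 0) with five independent noise seeds, mirroring
the one-brain/many-runs design of connectome studies. Conditions:

- 100 regions, 20 000 Euler steps (2 s, second half retained), σ_d = 0;
- σ_n = 1 rad. The reduced network has ~10× smaller input strengths than
  a 488-node brain network, so with σ_n = 2 its coherence transition lies
  beyond the coupling range permitted by the stability bound at
  `Δt = 1e−4`; halving the noise keeps the transition inside the valid
  window. The full-scale pipeline defaults keep σ_n = 2;
- coupling grid (10, 15, 20, 30, 45, 60, 80, 100): it spans the data-like
  network's coherence transition; it starts at 10 because the concentrated
  relocation variants lock below k ≈ 2 and their order parameter
  thereafter grows only through slow phase-jitter tightening
  (`r ∝ exp(−c D/k)`), whose steep low-k segment is a property of grid
  placement rather than of any transition; the maximum is the largest
  coupling passing the stability bound for max-weight-1 networks;
- the variant comparison runs without conduction delays, as in the
  dispersion-sweep variant study; with only 20 relocated distal edges,
  delay-induced multistability of that small backbone otherwise produces
  abrupt stochastic locking events that dominate the Γ_k estimate. The
  delayed integrator is exercised and validated separately;
- relocation windows are the shortest/longest 0.2 % of edge lengths; the
  Γ_d short-range threshold is the 5th percentile of edge lengths.

Under these conditions, over fresh seeds, Γ_k of the data-like network
exceeds the power-law-only, proximal and distal variants by a factor of
~3–4 with non-overlapping mean ± SE, and Γ_d orders the other way
(power-law-only ≈ 0.6 versus data-like ≈ 0.36) — the qualitative
phenomenology of the full-scale analysis.

## Numerical choices and degenerate inputs

- Initial phases are uniform on `[0, 2π)`; a constant phase shift of the
  initial condition leaves every order parameter unchanged (tested).
- Seeding is counter-based throughout: generator stages and every
  (variant, sweep value, repeat) simulation derive independent
  `SeedSequence` children, so enlarging a sweep never perturbs existing
  cells.
- Euler consistency: halving the step changes the two-oscillator locking
  order parameter by < 1e−2 (tested at 1e−4 → 5e−5, and against a 10×
  finer step).
- Non-finite phases abort the run with the failing step number.
- Degenerate inputs are errors, not warnings: all-zero weight matrices,
  coincident centroids (named pair), empty relocation windows (named
  window), sweeps with non-increasing grids, residual requests exceeding
  the eligible edge set.

## Known limitations

- Max-normalization of heavy-tailed weights makes *across-generator-seed*
  variability large (the normalizing maximum is an extreme-value draw);
  the study design therefore fixes one connectome and varies the dynamics
  noise. Conclusions about generator-level ensembles would need a
  different normalization or many more seeds.
- Γ_k estimated from a coarse grid is a biased (downward) estimate of the
  true maximum slope and is sensitive to grid placement; comparisons are
  only made between variants on identical grids.
- The exponential fit shares the log-scale OLS machinery; no censored
  likelihood is offered for zero-weight edges.
- The forward-Euler/rounded-delay scheme is first order; it is validated
  against closed forms and step-halving, not against an exact DDE solver.
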
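# Methods

This note documents the models implemented in `dmfconn`, the numerical
and statistical choices behind them, what the synthetic-data generators
do and do not emulate, and the package's known limitations.

## Dynamic mean-field model

Each region reduces a network of interconnected excitatory and
inhibitory spiking populations to one excitatory (E) and one inhibitory
(I) pool described by synaptic gating variables `S_E` (NMDA, τ = 100 ms,
kinetic factor γ = 0.641) and `S_I` (GABA-A, τ = 10 ms). Input currents
(nA) are converted to population firing rates (Hz) by the sigmoidal
transfer function `H(x) = x / (1 − exp(−d·x))` with `x = a·I − b`,
evaluated as `−x / expm1(−d·x)` for numerical accuracy and as the limit
`1/d` at `x = 0`. Parameter defaults (`DMFParameters`): external input
`I_0 = 0.382 nA` weighted `W_E = 1` / `W_I = 0.7`, synaptic coupling
`J_NMDA = 0.15 nA`, local recurrence `w+ = 1.4`, gains
`a_E = 310 nC⁻¹`, `a_I = 615 nC⁻¹`, thresholds `b_E = 125 Hz`,
`b_I = 177 Hz`, curvatures `d_E = 0.16 s`, `d_I = 0.087 s`, noise
`σ = 0.01 nA`. These are the standard constants of this model family;
all are exposed as dataclass fields.

Integration is Euler–Maruyama with independent `N(0,1)` draws per region
and step scaled by `σ√dt`; the equations as printed do not fix a
discretization, and this is the standard choice. The default step is
1.2 ms, used both as the integration and the recording step (they can be
decoupled via `record_stride`). Gating is clamped to `[0, 1]` after each
step; a state leaving `[−0.1, 1.1]` *before* clamping aborts the run
with `SimulationError` — that margin distinguishes benign noise
excursions from genuine divergence.

### Feedback inhibition control

FIC tunes the per-region inhibitory weight `J_i` so that every region's
long-run excitatory rate sits near the 3 Hz operating point regardless
of how much long-range excitation it receives. Two implementation
choices matter:

1. **Initialization is analytic.** At the target rate the gating
   fixed points are closed-form: `S_E* = γrτ/(1+γrτ) ≈ 0.1613`, and
   `S_I*` solves a scalar fixed-point equation independent of `J` and
   `G` (`gating_fixed_points`). The deterministic `J` that places the
   excitatory current at the target then follows directly from the
   current-balance equation. For moderate coupling this initial guess is
   already within tolerance.
2. **Refinement controls on current, not rate.** The iterative update
   is `J_i ← J_i + clip(η · (Ī_E,i − I*), ±0.02 nA)` with
   `η = 15 nA/nA` and `I*` the current at which `H_E` outputs the
   target rate, estimated from a 10 s epoch after a 2 s burn-in. The
   firing-rate error is a poor control signal: it saturates at
   `−target` when a region falls silent and grows without bound when it
   saturates high, which produces relaxation oscillations between the
   bistable branches. The mean input current is monotone and nearly
   linear in `J` in both regimes (`dI/dJ = −S_I`), so a damped
   quasi-Newton step on it converges in a handful of epochs; the small
   step clip suppresses branch-hopping limit cycles near the stability
   edge.

Convergence is declared on the rates (max deviation ≤ 0.15 Hz by
default); exhausting `max_iter` returns `converged=False` rather than
raising, so a grid search can skip uncalibratable couplings. For
couplings beyond the network's stability edge the low-activity branch
does not exist as a stable state and FIC reports non-convergence — this
is a property of the dynamics, not a solver failure.

## Hemodynamic forward model

The Balloon–Windkessel model maps neural drive `z` to BOLD per region:
vasodilatory signal `ds/dt = z − κs − γ_h(f−1)`, inflow `df/dt = s`,
venous volume `τ_h dv/dt = f − v^{1/α}`, deoxyhemoglobin
`τ_h dq/dt = f·(1−(1−ρ)^{1/f})/ρ − v^{1/α} q/v`, and
`BOLD = V0(k1(1−q) + k2(1−q/v) + k3(1−v))`. Defaults: κ = 0.65 s⁻¹,
γ_h = 0.41 s⁻¹, τ_h = 0.98 s, α = 0.32, ρ = 0.34, V0 = 0.02, k1 = 7ρ,
k2 = 2, k3 = 2ρ − 0.2 — the canonical resting-state parameterization.
The balloon ODEs are integrated with explicit Euler at the neural step,
and the TR samples are the nearest-dt ticks.

Choices worth flagging:

- **Drive.** The default neural drive is the excitatory gating `S_E`
  (synaptic activity), with population rate `r_E` available via
  `drive="rate"`. Which quantity drives the transform is a genuine
  degree of freedom in this model family; it is a knob, not a claim.
- **Settling window.** The balloon state starts at its resting point
  (0, 1, 1, 1), and its relaxation toward the operating point under
  sustained drive takes ~15 s. Because that transient is identical in
  every region, it masquerades as near-perfect interregional
  correlation: with only a 2 s discard, uncoupled regions show mean FC
  ≈ 0.98. `simulate_bold` therefore discards `burn_s + hemo_settle_s`
  (2 + 20 s by default) before sampling.
- BOLD is a deterministic functional of the neural trace: replaying a
  stored gating trace through `integrate_balloon` reproduces the
  simulated BOLD bit-exactly (tested).

## Fitting the global coupling

`fit_G` grid-searches `G` (default grid 0–0.75 in steps of 0.005)
minimizing `|mean upper-triangular FC(sim) − mean upper-triangular
FC(empirical)|`, with FIC recalibrated at every grid value (J depends on
G) and the simulated summary averaged over `n_repeats` runs. Ties break
toward smaller G. The comparison uses raw correlations by default
(`scale="z"` switches to Fisher-z averages). Grid values where FIC does
not converge are excluded with a warning — fitting against an
uncalibrated model would compare incommensurable objects. Because the
simulated FC curve depends only on the connectome and settings, it can
be computed once (`simulate_reference_curve`) and shared across subjects
fitted against the same structural matrix. The mean-FC summary carries a
scan-length-dependent finite-sample bias, so simulated runs should match
the empirical scan length; mismatched lengths shift every fit by the
bias differential.

`compare_groups` tests fitted G values between groups with a two-sided
permutation t test: `p = (1 + #{|t_perm| ≥ |t_obs|}) / (n_perm + 1)`,
pooled-variance t, group labels permuted. Degenerate all-equal inputs
give p = 1.

## Connectivity statistics

- Correlations at ±1 are clipped to ±(1 − 1e-7) before `atanh`.
- Global connectivity is the mean Fisher-z correlation of a voxel with
  all other in-mask voxels; the long-range variant excludes partners at
  Euclidean center distance ≤ the exclusion radius (strictly-greater
  rule, 600 µm in the mouse application).
- Group maps: Cohen's d with degrees-of-freedom-pooled SD; Student
  (pooled-variance) t, not Welch; occurrence maps count site-level
  d maps exceeding a threshold (default 0.2, strict >).
- Cluster correction is a permutation max-extent test: clusters are
  connected components of same-sign suprathreshold voxels (default
  |t| > 2, 6-connectivity in 3-D via `grid_adjacency`); a cluster is
  significant when its extent exceeds the (1−α) quantile of the
  permutation null of maximum extents. This replaces parametric
  Gaussian-random-field correction; it is exact under exchangeability
  and makes no smoothness assumptions.
- Motion censoring drops frames with framewise displacement above
  0.2 mm and signals subject exclusion when fewer than `min_fraction`
  frames survive.
- Site/covariate harmonization is fixed-effect OLS residualization on
  an intercept, site indicator codes, and numeric covariates; the
  original mega-analytic mixed-model harmonization is approximated by
  these fixed effects, which is exact for site mean offsets and
  conservative otherwise. Rank-deficient designs are rejected naming
  the collinear columns.

## Gene decoding and enrichment

For each donor brain the expression of each gene across locations is
regressed on the (mean-centred) imaging map; the map is the predictor
and expression the response, untransformed by default (a per-donor
z-scoring knob exists since upstream decoding services do not document
their normalization). The donor-wise slopes go into a two-sided
one-sample t test against zero; Benjamini–Hochberg FDR is applied across
genes, and only genes with positive t surviving `q < 0.05` are retained.
Zero-variance slope vectors are excluded with a warning rather than
propagating undefined t values.

Enrichment of a decoded list A in a target set B within universe N uses
the 2×2 cross-product odds ratio `k(N−A−B+k) / ((A−k)(B−k))` with the
Haldane–Anscombe +0.5 correction applied to all four cells when any
cell is zero, and the inclusive upper-tail hypergeometric probability
`P(X ≥ k)`. `prune_interactome` intersects an interactome gene set with
a dysregulated set, preserving the universe.

## Subtyping

Subjects are clustered on vectorized connectivity maps: Euclidean
distances, agglomerative hierarchical clustering (complete linkage by
default — the common default for heatmap-style clustering of distance
matrices; Ward and average are options). The number of clusters is
chosen by majority vote over internal validity indices — silhouette,
Calinski–Harabasz, Davies–Bouldin, Dunn, C-index, and the gap statistic
(uniform reference draws, seeded) — each nominating its best k over
2–10, ties broken toward smaller k (parsimony). Six indices emulate the
behavior of larger index batteries without reproducing any specific
one. Per-subtype contrasts reuse the pooled-t machinery against the
control group (clusters of size 1 are rejected); per-subtype enrichment
runs the decode→enrich pipeline on each subtype's contrast map with BH
correction across subtypes.

## Synthetic data

Generators are pure functions of their arguments; all streams derive
from the master seed through counter-keyed `SeedSequence`s, so enlarging
one dimension never perturbs other draws. Defaults mirror the study
conditions: 74 regions, 20 subjects per group, 6 donor brains,
1000-gene universes over 200 locations.

- `make_connectome`: Bernoulli(density) edges with log-normal (µ=0, σ=1)
  weights, symmetrized, zero diagonal, rescaled to unit mean row
  strength. The row-strength normalization (rather than unit mean edge
  weight) keeps the model's low-activity branch stable across the whole
  G range of interest; see the stability remark under FIC.
- `make_group_bold` drives the full model + hemodynamics per subject at
  planted couplings, caching FIC per distinct G.
- `make_voxel_dataset`: regions are cubes of voxels on a regular 3-D
  grid (physical coordinates = index × voxel size, supporting the
  distance-exclusion rule); voxels share their region's latent signal
  plus i.i.d. noise; each latent mixes an independent and a global
  common component, and the group-2 common loading is raised by
  `group_effect`, planting diffuse hyperconnectivity.
- `make_expression_atlas`: coupled genes satisfy
  `expression = β·map + noise` in every donor; the rest are pure noise
  of the same scale. Note the systematic component is identical across
  donors, so any test map with nonzero sample correlation against the
  reference map will legitimately decode some planted genes — null
  checks should use maps orthogonalized against the reference.
- `make_gene_lists` plants an exact overlap; `make_subject_maps` places
  cluster prototypes on scaled unit basis vectors (exact pairwise
  separation) plus isotropic noise.

What the generators do **not** emulate: anatomy or atlas geometry,
scanner noise spectra and autocorrelation, motion artifacts, donor-level
expression heterogeneity, or realistic gene–gene covariance. Passing
tests demonstrate that each method recovers what it claims from data
matching its own assumptions — not robustness to real-data violations
of those assumptions.

## Problem sizes and determinism

Desk-scale defaults keep the full suite fast while preserving the
phenomena: 20-region connectomes, 10 simulation repeats per grid value,
400–600 TR runs at TR = 1 s and dt = 1.2 ms for coupling recovery;
1000-gene/200-location atlases over 6 donors for decoding; 60-subject,
4-cluster subtyping problems. The reference FC-vs-G curve is computed
once per connectome and shared across subject fits. All simulations are
seeded (kernel RNG included), making runs reproducible within an
environment; the integrators use compiled kernels whose vectorized
arithmetic may reorder floating-point operations across CPU
generations, so chaotic trajectories are bit-reproducible only on the
same hardware/compiler combination.

## Interfaces

The package is a library: the public functions are the interface, plus
`scripts/acceptance.py` for the from-scratch headline computation.
Serialization is plain text (TSV/JSON) with NIfTI supported for voxel
data through nibabel.

## Known limitations

- No regional heterogeneity in model parameters or hemodynamics; no
  plasticity; only G is fitted.
- The permutation cluster test assumes exchangeable subjects (no
  site-block permutation scheme).
- Fixed-effect site residualization, not a random-effects model, is the
  default harmonization (a `MixedLM` variant would be a natural
  extension).
- The gap statistic uses 10 uniform reference draws by default; its
  nominations are noisier than the closed-form indices.
- Paper-scale runs (74 regions, 151 grid values, 50 repeats of 3000
  timepoints per subject) are supported by the same code paths but are
  cluster-scale computations, not part of the test suite.
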
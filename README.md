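# dmfconn

Whole-brain dynamic mean-field modeling and resting-state fMRI
connectivity analysis, with imaging-transcriptomics enrichment and
connectivity-based subtyping.

`dmfconn` is aimed at researchers studying brain-wide functional
hyperconnectivity — for example in mTOR-pathway mouse mutants or in
autism cohorts — who want to (i) ask whether an increase in effective
synaptic coupling can explain an observed rsfMRI connectivity change,
(ii) quantify voxelwise connectivity alterations, (iii) decode which
genes' spatial expression tracks a connectivity-difference map and test
that list for enrichment in an interactome-derived gene set, and
(iv) partition a heterogeneous case group into connectivity-defined
subtypes. Every stage runs on synthetic data with known ground truth, so
the full pipeline is testable without any imaging downloads.

## The model

Each brain region *i* is a pair of coupled excitatory (E) and inhibitory
(I) neural-mass pools:

    I_E^i = W_E I_0 + w+ J_NMDA S_E^i + G J_NMDA Σ_j C_ij S_E^j − J_i S_I^i
    I_I^i = W_I I_0 + J_NMDA S_E^i − S_I^i
    r_p^i = H_p(I_p^i) = (a_p I_p^i − b_p) / (1 − exp(−d_p (a_p I_p^i − b_p)))
    dS_E^i/dt = −S_E^i/τ_NMDA + (1 − S_E^i) γ r_E^i + σ v_i(t)
    dS_I^i/dt = −S_I^i/τ_GABA + r_I^i + σ v_i(t)

where `C` is a structural connectome, `G` the global coupling — the
single fitted parameter — and `J_i` per-region inhibitory weights tuned
by *feedback inhibition control* (FIC) so that every region fires near
3 Hz. Simulated activity is converted to BOLD with the
Balloon–Windkessel hemodynamic model and compared to empirical data
through the mean upper-triangular functional-connectivity (FC) value;
`G` is fitted by grid search and groups are compared with a permutation
t test.

The analysis side implements weighted global (degree-centrality)
connectivity with a long-range distance exclusion, seed maps, Fisher
r-to-z, Cohen's d and pooled-t group maps, cross-site occurrence maps,
permutation cluster-extent correction, Dice overlap, motion censoring,
and covariate/site residualization; gene decoding via donor-specific
regression slopes + one-sample t + Benjamini–Hochberg FDR with a
positive-t filter; enrichment via the 2×2 odds ratio and the inclusive
hypergeometric tail; and agglomerative subtyping with cluster-count
selection by index majority vote.

## Worked example

```python
import numpy as np
import dmfconn as dc
from dmfconn.connectivity import fc_matrix
from dmfconn.fitting import GGrid, SimConfig, fc_summary, fit_G
from dmfconn.synthetic import make_connectome, make_group_bold

conn = make_connectome(n_regions=20, density=0.3, seed=1)
params = dc.DMFParameters()

# calibrate inhibition at G = 0.3 and check the operating point
fic = dc.calibrate_fic(params, conn, G=0.3)
print("converged:", fic.converged,
      "max rate deviation:", round(float(np.abs(fic.achieved_rates - 3).max()), 4))

# simulate a "subject" at a planted coupling and recover it by grid search
runs, truth = make_group_bold(conn, g_values=[0.3], duration_s=600.0,
                              tr_s=1.0, seed=3)
emp = fc_matrix(runs[0].Y)
print("empirical mean FC:", round(fc_summary(emp), 4))
fit = fit_G(emp, conn, GGrid(0.2, 0.5, 0.025), n_repeats=10,
            config=SimConfig(n_timepoints=400), seed=0)
print("planted G = 0.3, fitted G =", round(fit.optimal_G, 3))
```

prints (a few minutes of simulation):

```
converged: True max rate deviation: 0.0223
empirical mean FC: 0.0653
planted G = 0.3, fitted G = 0.35
```

The FIC step has pinned every region's firing rate within 0.15 Hz of the
3 Hz target. The subject's mean upper-triangular FC is a noisy draw from
a 600-sample scan, so the fitted coupling lands within two grid steps
(0.05) of the planted value — representative accuracy at this scan
length; the acceptance suite quantifies it over many subjects.

## Layout

- `dmfconn.synthetic` — ground-truth generators for every stage
- `dmfconn.dmf` — mean-field model, transfer function, FIC
- `dmfconn.hemodynamics` — Balloon–Windkessel BOLD forward model
- `dmfconn.connectivity` — voxel/region rsfMRI statistics
- `dmfconn.fitting` — G grid search and permutation group comparison
- `dmfconn.enrichment` — gene decoding, FDR, odds ratio, hypergeometric
- `dmfconn.subtyping` — distances, clustering, k selection, contrasts
- `dmfconn.io` — TSV/JSON/NIfTI serialization

See `docs/methods.md` for the modeling and statistical choices in detail.
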
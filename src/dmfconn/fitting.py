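"""Global coupling (G) fitting and group comparison.

The single free parameter of the whole-brain model is the global coupling
G scaling all long-range excitatory connections.  It is fitted per subject
by grid search: for each candidate G the inhibitory weights are
recalibrated (J depends on G), BOLD is simulated ``n_repeats`` times, and
the fitness is the absolute difference between the mean upper-triangular
functional connectivity of simulated and empirical data.  Groups of fitted
G values are compared with a permutation-based unpaired t test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .connectivity import FCMatrix
from .dmf import (DMFParameters, SimulationError, StructuralConnectome,
                  calibrate_fic)
from .hemodynamics import HemodynamicParameters, simulate_bold

__all__ = ["GGrid", "SimConfig", "FitResult", "GroupComparison",
           "fc_summary", "simulate_reference_curve", "fit_G",
           "compare_groups"]


@dataclass(frozen=True)
class GGrid:
    """Arithmetic grid of candidate global-coupling values."""

    g_min: float = 0.0
    g_max: float = 0.75
    step: float = 0.005

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.g_max < self.g_min:
            raise ValueError("g_max must be >= g_min")

    @property
    def values(self) -> np.ndarray:
        n = int(np.floor((self.g_max - self.g_min) / self.step + 1e-9)) + 1
        return self.g_min + self.step * np.arange(n)


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings shared by every grid evaluation."""

    n_timepoints: int = 300
    tr_s: float = 1.0
    dt_s: float = 0.0012
    burn_s: float = 2.0
    hemo_settle_s: float = 20.0
    dmf: DMFParameters = field(default_factory=DMFParameters)
    hemo: HemodynamicParameters = field(default_factory=HemodynamicParameters)
    fic_tol_hz: float = 0.15
    fic_max_iter: int = 100
    require_converged_fic: bool = True
    drive: str = "gating"


@dataclass
class FitResult:
    optimal_G: float
    fitness_curve: np.ndarray   # |sim mean FC - empirical mean FC| per grid value
    grid: np.ndarray
    n_repeats: int
    seed: int
    sim_curve: np.ndarray | None = None


@dataclass
class GroupComparison:
    g_diff: float               # mean(group B) - mean(group A)
    p_two_sided: float
    t_observed: float
    n_perm: int


def fc_summary(fc: FCMatrix | np.ndarray, scale: str = "r") -> float:
    """Mean of the strictly upper-triangular FC entries.

    ``scale='z'`` averages Fisher-z values instead of raw correlations.
    """
    R = fc.R if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)
    iu = np.triu_indices(R.shape[0], k=1)
    vals = R[iu]
    if scale == "z":
        from .connectivity import fisher_z
        vals = fisher_z(vals)
    elif scale != "r":
        raise ValueError("scale must be 'r' or 'z'")
    return float(np.nanmean(vals))


def _sim_summary(connectome: StructuralConnectome, g: float, J,
                 config: SimConfig, n_repeats: int, seed: int,
                 scale: str) -> float:
    from .connectivity import fc_matrix
    vals = np.empty(n_repeats)
    for r in range(n_repeats):
        bold = simulate_bold(config.dmf, config.hemo, connectome, g, J,
                             config.n_timepoints, config.tr_s,
                             seed=int(np.random.SeedSequence((seed, r)).generate_state(1)[0] % 2**31),
                             dt_s=config.dt_s, burn_s=config.burn_s,
                             hemo_settle_s=config.hemo_settle_s,
                             drive=config.drive)
        vals[r] = fc_summary(fc_matrix(bold.Y), scale=scale)
    return float(vals.mean())


def simulate_reference_curve(connectome: StructuralConnectome, grid: GGrid,
                             n_repeats: int, config: SimConfig, seed: int,
                             scale: str = "r",
                             fic_cache: dict | None = None) -> np.ndarray:
    """Mean simulated FC summary at each grid value (NaN where unstable).

    The curve depends only on the connectome and the simulation settings,
    so one curve can be shared when fitting many subjects against the same
    structural matrix.  ``fic_cache`` maps grid values to precomputed FIC
    solutions and is filled in place when provided.
    """
    gvals = grid.values
    curve = np.full(gvals.size, np.nan)
    for i, g in enumerate(gvals):
        try:
            key = round(float(g), 10)
            if fic_cache is not None and key in fic_cache:
                fic = fic_cache[key]
            else:
                fic = calibrate_fic(config.dmf, connectome, g,
                                    tol_hz=config.fic_tol_hz,
                                    max_iter=config.fic_max_iter,
                                    seed=seed, dt_s=config.dt_s)
                if fic_cache is not None:
                    fic_cache[key] = fic
            if config.require_converged_fic and not fic.converged:
                warnings.warn(f"grid value G = {g} skipped: FIC did not "
                              "converge (outside the stable range)")
                continue
            curve[i] = _sim_summary(connectome, g, fic, config, n_repeats,
                                    seed + i, scale)
        except SimulationError as exc:
            warnings.warn(f"grid value G = {g} skipped: {exc}")
    if np.all(np.isnan(curve)):
        raise SimulationError("simulation failed at every grid value")
    return curve


def fit_G(empirical_fc: FCMatrix, connectome: StructuralConnectome,
          grid: GGrid | None = None, n_repeats: int = 10,
          config: SimConfig | None = None, seed: int = 0,
          scale: str = "r", reference_curve: np.ndarray | None = None,
          fic_cache: dict | None = None) -> FitResult:
    """Grid-search the global coupling minimizing the FC-mean mismatch.

    fitness(g) = |mean simulated FC summary at g  -  empirical summary|;
    the optimum is the argmin, ties broken toward smaller g.  A
    ``reference_curve`` from :func:`simulate_reference_curve` (same grid
    and settings) skips re-simulation.
    """
    grid = grid or GGrid()
    config = config or SimConfig()
    if empirical_fc.R.shape[0] != connectome.n_regions:
        raise ValueError("empirical FC and connectome sizes differ")
    if reference_curve is None:
        reference_curve = simulate_reference_curve(
            connectome, grid, n_repeats, config, seed, scale, fic_cache)
    gvals = grid.values
    if reference_curve.shape != gvals.shape:
        raise ValueError("reference curve does not match the grid")
    emp = fc_summary(empirical_fc, scale=scale)
    fitness = np.abs(reference_curve - emp)
    best = int(np.nanargmin(fitness))  # first (= smallest g) on ties
    return FitResult(optimal_G=float(gvals[best]), fitness_curve=fitness,
                     grid=gvals, n_repeats=n_repeats, seed=seed,
                     sim_curve=reference_curve)


def _pooled_t(a_sum, a_sq, na, b_sum, b_sq, nb):
    ma, mb = a_sum / na, b_sum / nb
    va = (a_sq - na * ma**2) / (na - 1)
    vb = (b_sq - nb * mb**2) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (ma - mb) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))


def compare_groups(optG_A, optG_B, n_perm: int = 10000,
                   seed: int = 0) -> GroupComparison:
    """Permutation-based unpaired two-sided t test on fitted G values.

    p = (1 + #{|t_perm| >= |t_obs|}) / (n_perm + 1) under random relabeling
    of group membership; ``g_diff`` is mean(B) - mean(A).
    """
    a = np.asarray(optG_A, dtype=float)
    b = np.asarray(optG_B, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse p-value")
    pooled = np.concatenate([a, b])
    na, n = a.size, pooled.size
    g_diff = float(b.mean() - a.mean())
    if np.ptp(pooled) == 0:
        return GroupComparison(g_diff=0.0, p_two_sided=1.0, t_observed=0.0,
                               n_perm=n_perm)
    t_obs = _pooled_t(a.sum(), (a**2).sum(), na,
                      b.sum(), (b**2).sum(), b.size)
    rng = np.random.default_rng(seed)
    tot, tot_sq = pooled.sum(), (pooled**2).sum()
    # vectorized: each permutation only needs the group-A sums
    picks = np.empty((n_perm, na), dtype=int)
    for p in range(n_perm):
        picks[p] = rng.permutation(n)[:na]
    sel = pooled[picks]
    a_sum = sel.sum(axis=1)
    a_sq = (sel**2).sum(axis=1)
    t_perm = _pooled_t(a_sum, a_sq, na, tot - a_sum, tot_sq - a_sq, n - na)
    t_perm = np.nan_to_num(t_perm, nan=np.inf)  # zero-variance permutations
    exceed = np.sum(np.abs(t_perm) >= abs(t_obs) - 1e-12)
    p_val = (1 + exceed) / (n_perm + 1)
    if not np.isfinite(t_obs):
        p_val = 1.0 / (n_perm + 1)
        t_obs = float(np.sign(g_diff) * np.inf)
    return GroupComparison(g_diff=g_diff, p_two_sided=float(p_val),
                           t_observed=float(t_obs), n_perm=n_perm)
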
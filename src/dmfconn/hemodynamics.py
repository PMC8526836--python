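"""Balloon-Windkessel hemodynamic forward model.

Converts simulated neural activity into a fractional BOLD signal change.
Per region, a vasodilatory signal s drives blood inflow f, which inflates
venous volume v and dilutes deoxyhemoglobin q:

    ds/dt = z - kappa*s - gamma_h*(f - 1)
    df/dt = s
    tau_h dv/dt = f - v^(1/alpha)
    tau_h dq/dt = f*(1 - (1 - rho)^(1/f))/rho - v^(1/alpha) * q/v
    BOLD = V0 * (k1*(1 - q) + k2*(1 - q/v) + k3*(1 - v))

with the resting fixed point (s, f, v, q) = (0, 1, 1, 1) giving zero BOLD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .dmf import (DMFParameters, FICSolution, SimulationError,
                  StructuralConnectome, integrate)

__all__ = ["HemodynamicParameters", "BOLDTimeseries", "integrate_balloon",
           "simulate_bold"]

_RHO_DEFAULT = 0.34


@dataclass(frozen=True)
class HemodynamicParameters:
    """Balloon-Windkessel constants (canonical resting-state defaults)."""

    kappa: float = 0.65       # vasodilatory signal decay (1/s)
    gamma_h: float = 0.41     # flow-dependent elimination (1/s)
    tau_h: float = 0.98       # hemodynamic transit time (s)
    alpha: float = 0.32       # vessel stiffness (Grubb exponent)
    rho: float = _RHO_DEFAULT  # resting oxygen extraction fraction
    V0: float = 0.02          # resting venous volume fraction
    k1: float = 7.0 * _RHO_DEFAULT
    k2: float = 2.0
    k3: float = 2.0 * _RHO_DEFAULT - 0.2

    def __post_init__(self) -> None:
        for name in ("kappa", "gamma_h", "tau_h", "alpha", "rho", "V0", "k1"):
            if getattr(self, name) <= 0:
                raise ValueError(f"hemodynamic parameter {name} must be positive")
        for name in ("k2", "k3"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"hemodynamic parameter {name} must be finite")


@dataclass
class BOLDTimeseries:
    """Region x time BOLD matrix sampled at the scanner TR."""

    t: np.ndarray             # seconds
    Y: np.ndarray             # region x time, fractional signal change
    tr_s: float
    labels: list[str] | None = None

    @property
    def n_regions(self) -> int:
        return self.Y.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.Y.shape[1]


def integrate_balloon(drive: np.ndarray, dt_s: float,
                      params: HemodynamicParameters | None = None) -> np.ndarray:
    """Integrate the balloon model for a region x time neural drive.

    Explicit Euler at the drive's own time step; returns BOLD at the same
    resolution (region x time).  The state starts at rest, so a zero drive
    yields identically zero BOLD.
    """
    params = params or HemodynamicParameters()
    drive = np.asarray(drive, dtype=float)
    if drive.ndim != 2:
        raise ValueError("drive must be a region x time matrix")
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    if not np.all(np.isfinite(drive)):
        raise ValueError("drive must be finite")
    z = np.ascontiguousarray(drive.T)  # kernel wants time x region
    bold, fail = _kernels.integrate_balloon_kernel(
        z, float(dt_s), params.kappa, params.gamma_h, params.tau_h,
        params.alpha, params.rho, params.V0, params.k1, params.k2, params.k3)
    if fail >= 0:
        raise SimulationError(
            f"balloon state became non-positive at step {fail}")
    return bold.T


def simulate_bold(params: DMFParameters, hemo: HemodynamicParameters,
                  connectome: StructuralConnectome, G: float,
                  J: FICSolution | np.ndarray, n_timepoints: int,
                  tr_s: float, seed: int = 0, dt_s: float = 0.0012,
                  burn_s: float = 2.0, hemo_settle_s: float = 20.0,
                  drive: str = "gating") -> BOLDTimeseries:
    """Simulate neural activity and transform it into TR-sampled BOLD.

    Integrates the DMF model for ``burn_s + hemo_settle_s +
    n_timepoints * tr_s`` seconds, feeds the chosen neural drive
    (excitatory gating by default, firing rate with ``drive='rate'``)
    through the balloon model at the neural dt, then keeps the sample
    nearest each TR tick after the discarded window.  ``hemo_settle_s``
    covers the balloon model's relaxation from rest to its operating
    point; without it the shared onset transient masquerades as coherent
    signal across all regions.
    """
    if n_timepoints < 2:
        raise ValueError("n_timepoints must be >= 2")
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    if drive not in ("gating", "rate"):
        raise ValueError("drive must be 'gating' or 'rate'")
    discard = burn_s + hemo_settle_s
    duration = discard + n_timepoints * tr_s
    ts = integrate(params, connectome, G, J, duration, dt_s=dt_s, seed=seed,
                   record_rates=(drive == "rate"))
    z = ts.S_E_trace if drive == "gating" else ts.r_E
    bold_dt = _kernels.integrate_balloon_kernel(
        np.ascontiguousarray(z), float(dt_s), hemo.kappa, hemo.gamma_h,
        hemo.tau_h, hemo.alpha, hemo.rho, hemo.V0, hemo.k1, hemo.k2, hemo.k3)
    bold, fail = bold_dt
    if fail >= 0:
        raise SimulationError(
            f"balloon state became non-positive at step {fail} (G = {G})")
    ticks = discard + tr_s * np.arange(1, n_timepoints + 1)
    idx = np.clip(np.round(ticks / dt_s).astype(int) - 1, 0, bold.shape[0] - 1)
    return BOLDTimeseries(t=ticks, Y=bold[idx].T, tr_s=tr_s,
                          labels=list(connectome.labels))
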
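"""Dynamic mean-field (DMF) whole-brain model with feedback inhibition control.

Each brain region is a reciprocally coupled excitatory (E) / inhibitory (I)
pair of neural-mass pools.  Long-range coupling enters the excitatory input
current through a structural connectome ``C`` scaled by a single global
coupling constant ``G``.  Per-region inhibitory weights ``J_i`` are tuned by
feedback inhibition control (FIC) so every region fires near a low target
rate (~3 Hz) regardless of the excitation it receives from the network.

Model equations (per region i):

    I_E = W_E*I_0 + w+*J_NMDA*S_E + G*J_NMDA*sum_j C_ij S_E_j - J_i*S_I
    I_I = W_I*I_0 + J_NMDA*S_E - S_I
    r_p = H_p(I_p) = (a_p*I_p - b_p) / (1 - exp(-d_p*(a_p*I_p - b_p)))
    dS_E/dt = -S_E/tau_NMDA + (1 - S_E)*gamma*r_E + sigma*v(t)
    dS_I/dt = -S_I/tau_GABA + r_I + sigma*v(t)

integrated with Euler-Maruyama (noise increments sigma*sqrt(dt)*N(0,1)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels

__all__ = [
    "DMFParameters",
    "StructuralConnectome",
    "FICSolution",
    "NeuralTimeseries",
    "SimulationError",
    "transfer_function",
    "input_currents",
    "integrate",
    "calibrate_fic",
]


class SimulationError(RuntimeError):
    """Raised when a stochastic integration diverges."""


@dataclass(frozen=True)
class DMFParameters:
    """Constants of the mean-field equations (units in field names' docs).

    Defaults are the standard parameterization of this model family:
    currents in nA, rates in Hz, time constants in seconds.
    """

    W_E: float = 1.0          # scaling of external input to E pool
    W_I: float = 0.7          # scaling of external input to I pool
    I_0: float = 0.382        # effective external input current (nA)
    w_plus: float = 1.4       # local excitatory recurrence
    J_NMDA: float = 0.15      # excitatory synaptic coupling (nA)
    a_E: float = 310.0        # E gain (nC^-1)
    b_E: float = 125.0        # E threshold (Hz)
    d_E: float = 0.16         # E curvature (s)
    a_I: float = 615.0        # I gain (nC^-1)
    b_I: float = 177.0        # I threshold (Hz)
    d_I: float = 0.087        # I curvature (s)
    gamma: float = 0.641      # NMDA kinetic factor
    tau_NMDA: float = 0.1     # E gating time constant (s)
    tau_GABA: float = 0.01    # I gating time constant (s)
    sigma: float = 0.01       # noise amplitude (nA)

    def __post_init__(self) -> None:
        for name in ("W_E", "W_I", "I_0", "w_plus", "J_NMDA", "a_E", "b_E",
                     "d_E", "a_I", "b_I", "d_I", "gamma", "tau_NMDA",
                     "tau_GABA"):
            if getattr(self, name) <= 0:
                raise ValueError(f"DMF parameter {name} must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass
class StructuralConnectome:
    """Region labels plus the nonnegative coupling matrix C_ij."""

    labels: list[str]
    C: np.ndarray

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if self.C.ndim != 2 or self.C.shape[0] != self.C.shape[1]:
            raise ValueError("connectome matrix must be square")
        if self.C.shape[0] < 2:
            raise ValueError("connectome needs at least 2 regions")
        if len(self.labels) != self.C.shape[0]:
            raise ValueError("label count does not match matrix size")
        if np.any(self.C < 0):
            raise ValueError("connectome weights must be nonnegative")
        if np.any(np.diag(self.C) != 0):
            raise ValueError("connectome diagonal must be zero")

    @property
    def n_regions(self) -> int:
        return self.C.shape[0]

    @property
    def is_symmetric(self) -> bool:
        return bool(np.allclose(self.C, self.C.T))


@dataclass
class FICSolution:
    """Per-region inhibitory weights from feedback inhibition control."""

    J: np.ndarray             # inhibitory weight per region (nA)
    converged: bool
    achieved_rates: np.ndarray  # epoch-mean excitatory rates (Hz)
    n_iterations: int = 0


@dataclass
class NeuralTimeseries:
    t: np.ndarray             # seconds
    r_E: np.ndarray           # time x region (Hz)
    r_I: np.ndarray           # time x region (Hz)
    S_E_trace: np.ndarray     # time x region gating
    S_I_trace: np.ndarray     # time x region gating
    dt: float


def transfer_function(I, pool: str, params: DMFParameters | None = None):
    """Sigmoidal input-output function H(I) mapping current (nA) to rate (Hz).

    ``pool`` selects the excitatory ('E') or inhibitory ('I') constants.
    The removable singularity at a*I - b = 0 evaluates to the limit 1/d.
    """
    params = params or DMFParameters()
    if pool == "E":
        a, b, d = params.a_E, params.b_E, params.d_E
    elif pool == "I":
        a, b, d = params.a_I, params.b_I, params.d_I
    else:
        raise ValueError("pool must be 'E' or 'I'")
    I = np.asarray(I, dtype=float)
    if not np.all(np.isfinite(I)):
        raise ValueError("input current must be finite")
    x = a * I - b
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(x == 0.0, 1.0 / d, -x / np.expm1(-d * x))
    return h if h.ndim else float(h)


def input_currents(S_E, S_I, params: DMFParameters, G: float,
                   connectome: StructuralConnectome, J) -> tuple[np.ndarray, np.ndarray]:
    """Total input currents (I_E, I_I) in nA for the given gating state."""
    S_E = np.asarray(S_E, dtype=float)
    S_I = np.asarray(S_I, dtype=float)
    J = np.asarray(getattr(J, "J", J), dtype=float)
    n = connectome.n_regions
    if not (S_E.shape == S_I.shape == J.shape == (n,)):
        raise ValueError("state and J must match the connectome size")
    I_E = (params.W_E * params.I_0 + params.w_plus * params.J_NMDA * S_E
           + G * params.J_NMDA * (connectome.C @ S_E) - J * S_I)
    I_I = params.W_I * params.I_0 + params.J_NMDA * S_E - S_I
    return I_E, I_I


def _kernel_args(params: DMFParameters):
    return (params.W_E, params.W_I, params.I_0, params.w_plus, params.J_NMDA,
            params.a_E, params.b_E, params.d_E, params.a_I, params.b_I,
            params.d_I, params.gamma, params.tau_NMDA, params.tau_GABA)


# default initial gating: mid-range of the low-activity branch
_S_E0 = 0.1
_S_I0 = 0.05


def _child_seed(seed: int, *key: int) -> int:
    """Counter-based seed derivation; stable under stream insertion."""
    return int(np.random.SeedSequence((int(seed),) + key).generate_state(1)[0] % (2**31))


def integrate(params: DMFParameters, connectome: StructuralConnectome,
              G: float, J, duration_s: float, dt_s: float = 0.0012,
              seed: int = 0, sigma: float | None = None,
              record_stride: int = 1,
              pin_r_E: float | None = None,
              pin_r_I: float | None = None,
              record_rates: bool = True) -> NeuralTimeseries:
    """Integrate the gating equations and return sampled traces.

    ``sigma`` overrides the noise amplitude (0 gives the deterministic
    flow); ``pin_r_E``/``pin_r_I`` clamp the firing rates at fixed values,
    decoupling the gating dynamics from the transfer function (useful for
    checking the analytic gating fixed points).
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    if duration_s < dt_s:
        raise ValueError("duration_s must cover at least one step")
    J = np.asarray(getattr(J, "J", J), dtype=float)
    n = connectome.n_regions
    if J.shape != (n,):
        raise ValueError("J must have one weight per region")
    n_steps = int(round(duration_s / dt_s))
    sig = params.sigma if sigma is None else float(sigma)
    s_e0 = np.full(n, _S_E0)
    s_i0 = np.full(n, _S_I0)
    se, si, re, ri, fail = _kernels.integrate_gating(
        np.ascontiguousarray(connectome.C), float(G), J, float(dt_s),
        n_steps, int(record_stride), _child_seed(seed), sig,
        *_kernel_args(params), s_e0, s_i0,
        -1.0 if pin_r_E is None else float(pin_r_E),
        -1.0 if pin_r_I is None else float(pin_r_I), record_rates)
    if fail >= 0:
        raise SimulationError(f"gating diverged at step {fail} (t = {fail * dt_s:.4f} s)")
    t = dt_s * record_stride * np.arange(1, se.shape[0] + 1)
    return NeuralTimeseries(t=t, r_E=re, r_I=ri, S_E_trace=se, S_I_trace=si,
                            dt=dt_s * record_stride)


def _target_current(target_hz: float, params: DMFParameters) -> float:
    """Excitatory input current at which H_E equals the target rate."""
    from scipy.optimize import brentq
    f = lambda x: float(transfer_function((x + params.b_E) / params.a_E,
                                          "E", params)) - target_hz
    x = brentq(f, -params.b_E, 1e4)
    return (x + params.b_E) / params.a_E


def gating_fixed_points(params: DMFParameters,
                        target_hz: float = 3.0) -> tuple[float, float, float]:
    """(S_E*, S_I*, r_I*) at the target excitatory rate.

    S_E* is the closed-form gating fixed point gamma*r*tau/(1 + gamma*r*tau);
    S_I* solves its self-consistent fixed point S_I = tau_GABA * H_I(I_I)
    with I_I = W_I*I_0 + J_NMDA*S_E* - S_I (independent of J and G).
    """
    from scipy.optimize import brentq
    g_r_tau = params.gamma * target_hz * params.tau_NMDA
    s_e = g_r_tau / (1.0 + g_r_tau)
    base = params.W_I * params.I_0 + params.J_NMDA * s_e

    def f(s_i):
        return params.tau_GABA * float(
            transfer_function(base - s_i, "I", params)) - s_i

    s_i = brentq(f, 0.0, 1.0)
    r_i = s_i / params.tau_GABA
    return s_e, s_i, r_i


def _fic_analytic_init(params: DMFParameters, C: np.ndarray, G: float,
                       target_hz: float) -> np.ndarray:
    """Deterministic fixed-point solution for J at the target rate."""
    s_e, s_i, _ = gating_fixed_points(params, target_hz)
    i_star = _target_current(target_hz, params)
    excite = (params.W_E * params.I_0 + params.w_plus * params.J_NMDA * s_e
              + G * params.J_NMDA * C.sum(axis=1) * s_e)
    return np.maximum((excite - i_star) / s_i, 1e-6)


def calibrate_fic(params: DMFParameters, connectome: StructuralConnectome,
                  G: float, target_hz: float = 3.0, tol_hz: float = 0.15,
                  max_iter: int = 100, seed: int = 0, eta: float = 15.0,
                  max_step: float = 0.02, epoch_s: float = 10.0,
                  burn_s: float = 2.0, dt_s: float = 0.0012) -> FICSolution:
    """Feedback inhibition control: tune J_i until all regions fire ~target.

    J is initialized at the closed-form deterministic fixed-point solution
    (see :func:`gating_fixed_points`) and refined with a damped
    quasi-Newton iteration on the epoch-mean excitatory input current:
    after each epoch (``burn_s`` discarded),

        J_i <- J_i + clip(eta * (mean I_E,i - I*), +-max_step)

    where I* is the current at which the transfer function outputs the
    target rate.  The current is monotone in J even when a region
    saturates high or falls silent, unlike the firing rate, whose error
    signal vanishes in both regimes; eta ~ 0.6 / S_I* approximates the
    inverse current sensitivity dI/dJ = -S_I at the target state, and the
    small step clip suppresses limit cycles between the bistable branches.
    Convergence is declared on the rates: the loop stops when every
    region's epoch-mean excitatory rate is within ``tol_hz`` of the
    target; exhausting ``max_iter`` returns ``converged=False`` with the
    last rate estimates (no exception).
    """
    if target_hz <= 0:
        raise ValueError("target_hz must be positive")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    n = connectome.n_regions
    C = np.ascontiguousarray(connectome.C)
    J = _fic_analytic_init(params, C, G, target_hz)
    i_star = _target_current(target_hz, params)
    n_steps = int(round((burn_s + epoch_s) / dt_s))
    burn_steps = int(round(burn_s / dt_s))
    s_e0 = np.full(n, _S_E0)
    s_i0 = np.full(n, _S_I0)
    rates = np.full(n, np.nan)
    for it in range(max_iter):
        rates, currents, s_e0, s_i0, fail = _kernels.mean_excitatory_rate(
            C, float(G), J, float(dt_s), n_steps, burn_steps,
            _child_seed(seed, it), params.sigma, *_kernel_args(params),
            s_e0, s_i0)
        if fail >= 0:
            raise SimulationError(
                f"FIC epoch diverged at step {fail} (iteration {it}, G = {G})")
        if np.max(np.abs(rates - target_hz)) <= tol_hz:
            return FICSolution(J=J, converged=True, achieved_rates=rates,
                               n_iterations=it + 1)
        step = np.clip(eta * (currents - i_star), -max_step, max_step)
        J = np.maximum(J + step, 1e-6)
    return FICSolution(J=J, converged=False, achieved_rates=rates,
                       n_iterations=max_iter)
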
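"""Numba-compiled integration kernels.

These are private: the public entry points in :mod:`dmfconn.dmf` and
:mod:`dmfconn.hemodynamics` validate arguments and wrap the outputs in
typed containers.  Kernels avoid fastmath so that the balloon transform of
a stored gating trace is bit-identical to the fused simulation path.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _transfer(x, d):
    # x = a*I - b; removable singularity at x = 0 has limit 1/d
    if x == 0.0:
        return 1.0 / d
    return -x / math.expm1(-d * x)


@njit(cache=True, fastmath=True)
def integrate_gating(C, G, J, dt, n_steps, record_stride, seed, sigma,
                     w_e, w_i, i0, w_plus, j_nmda,
                     a_e, b_e, d_e, a_i, b_i, d_i,
                     gamma, tau_e, tau_i,
                     s_e0, s_i0, pin_r_e, pin_r_i, record_rates):
    """Euler-Maruyama integration of the coupled gating equations.

    Returns (S_E trace, S_I trace, r_E trace, r_I trace, fail_step).
    Traces are
    sampled every ``record_stride`` steps (state after the update, rates
    used for that update).  ``pin_r_e``/``pin_r_i`` < 0 mean "compute the
    rate from the input current"; >= 0 pins the rate at that value (used
    to probe the gating fixed points in isolation).  ``fail_step`` >= 0
    flags a divergence (gating left [-0.1, 1.1] before clamping).
    """
    n = C.shape[0]
    np.random.seed(seed)
    n_rec = n_steps // record_stride
    se_tr = np.empty((n_rec, n))
    si_tr = np.empty((n_rec, n))
    nr = n_rec if record_rates else 0
    re_tr = np.empty((nr, n))
    ri_tr = np.empty((nr, n))
    s_e = s_e0.copy()
    s_i = s_i0.copy()
    sq = sigma * math.sqrt(dt)
    rec = 0
    r_e = np.empty(n)
    r_i = np.empty(n)
    for step in range(n_steps):
        for i in range(n):
            coup = 0.0
            for j in range(n):
                coup += C[i, j] * s_e[j]
            i_e = w_e * i0 + w_plus * j_nmda * s_e[i] + G * j_nmda * coup - J[i] * s_i[i]
            i_i = w_i * i0 + j_nmda * s_e[i] - s_i[i]
            r_e[i] = pin_r_e if pin_r_e >= 0.0 else _transfer(a_e * i_e - b_e, d_e)
            r_i[i] = pin_r_i if pin_r_i >= 0.0 else _transfer(a_i * i_i - b_i, d_i)
        for i in range(n):
            ne = sq * np.random.normal() if sq > 0.0 else 0.0
            ni = sq * np.random.normal() if sq > 0.0 else 0.0
            s_e[i] += dt * (-s_e[i] / tau_e + (1.0 - s_e[i]) * gamma * r_e[i]) + ne
            s_i[i] += dt * (-s_i[i] / tau_i + r_i[i]) + ni
            if s_e[i] < -0.1 or s_e[i] > 1.1 or s_i[i] < -0.1 or s_i[i] > 1.1 \
                    or not math.isfinite(s_e[i]) or not math.isfinite(s_i[i]):
                return se_tr, si_tr, re_tr, ri_tr, step
            if s_e[i] < 0.0:
                s_e[i] = 0.0
            elif s_e[i] > 1.0:
                s_e[i] = 1.0
            if s_i[i] < 0.0:
                s_i[i] = 0.0
            elif s_i[i] > 1.0:
                s_i[i] = 1.0
        if (step + 1) % record_stride == 0:
            for i in range(n):
                se_tr[rec, i] = s_e[i]
                si_tr[rec, i] = s_i[i]
                if record_rates:
                    re_tr[rec, i] = r_e[i]
                    ri_tr[rec, i] = r_i[i]
            rec += 1
    return se_tr, si_tr, re_tr, ri_tr, -1


@njit(cache=True, fastmath=True)
def mean_excitatory_rate(C, G, J, dt, n_steps, burn_steps, seed, sigma,
                         w_e, w_i, i0, w_plus, j_nmda,
                         a_e, b_e, d_e, a_i, b_i, d_i,
                         gamma, tau_e, tau_i, s_e0, s_i0):
    """Time-averaged excitatory rate per region after a burn-in.

    Trace-free companion of :func:`integrate_gating` used by the FIC
    calibration loop, where only epoch means matter.  Returns
    (mean rates, mean excitatory currents, final S_E, final S_I, fail_step).
    """
    n = C.shape[0]
    np.random.seed(seed)
    s_e = s_e0.copy()
    s_i = s_i0.copy()
    acc = np.zeros(n)
    acc_i = np.zeros(n)
    count = 0
    sq = sigma * math.sqrt(dt)
    r_e = np.empty(n)
    r_i = np.empty(n)
    for step in range(n_steps):
        for i in range(n):
            coup = 0.0
            for j in range(n):
                coup += C[i, j] * s_e[j]
            i_e = w_e * i0 + w_plus * j_nmda * s_e[i] + G * j_nmda * coup - J[i] * s_i[i]
            i_i = w_i * i0 + j_nmda * s_e[i] - s_i[i]
            r_e[i] = _transfer(a_e * i_e - b_e, d_e)
            r_i[i] = _transfer(a_i * i_i - b_i, d_i)
            if step >= burn_steps:
                acc[i] += r_e[i]
                acc_i[i] += i_e
        if step >= burn_steps:
            count += 1
        for i in range(n):
            ne = sq * np.random.normal() if sq > 0.0 else 0.0
            ni = sq * np.random.normal() if sq > 0.0 else 0.0
            s_e[i] += dt * (-s_e[i] / tau_e + (1.0 - s_e[i]) * gamma * r_e[i]) + ne
            s_i[i] += dt * (-s_i[i] / tau_i + r_i[i]) + ni
            if s_e[i] < -0.1 or s_e[i] > 1.1 or s_i[i] < -0.1 or s_i[i] > 1.1 \
                    or not math.isfinite(s_e[i]) or not math.isfinite(s_i[i]):
                return acc, acc_i, s_e, s_i, step
            if s_e[i] < 0.0:
                s_e[i] = 0.0
            elif s_e[i] > 1.0:
                s_e[i] = 1.0
            if s_i[i] < 0.0:
                s_i[i] = 0.0
            elif s_i[i] > 1.0:
                s_i[i] = 1.0
    if count > 0:
        for i in range(n):
            acc[i] /= count
            acc_i[i] /= count
    return acc, acc_i, s_e, s_i, -1


@njit(cache=True)
def integrate_balloon_kernel(z, dt, kappa, gamma_h, tau_h, alpha, rho,
                             v0, k1, k2, k3):
    """Balloon-Windkessel forward model, explicit Euler at the neural dt.

    ``z``: time x region neural drive.  State starts at the resting fixed
    point (s, f, v, q) = (0, 1, 1, 1).  Returns (BOLD trace, fail_step);
    fail_step >= 0 signals non-positive volume or deoxyhemoglobin.
    """
    n_t, n = z.shape
    s = np.zeros(n)
    f = np.ones(n)
    v = np.ones(n)
    q = np.ones(n)
    bold = np.empty((n_t, n))
    inv_alpha = 1.0 / alpha
    for t in range(n_t):
        for i in range(n):
            v_ia = v[i] ** inv_alpha
            ds = z[t, i] - kappa * s[i] - gamma_h * (f[i] - 1.0)
            df = s[i]
            dv = (f[i] - v_ia) / tau_h
            e_frac = (1.0 - (1.0 - rho) ** (1.0 / f[i])) / rho
            dq = (f[i] * e_frac - v_ia * q[i] / v[i]) / tau_h
            s[i] += dt * ds
            f[i] += dt * df
            v[i] += dt * dv
            q[i] += dt * dq
            if v[i] <= 0.0 or q[i] <= 0.0 or not math.isfinite(q[i]):
                return bold, t
            bold[t, i] = v0 * (k1 * (1.0 - q[i]) + k2 * (1.0 - q[i] / v[i])
                               + k3 * (1.0 - v[i]))
    return bold, -1
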
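"""Numba kernels for the dynamic mean-field and hemodynamic integrators.

These are the performance-critical inner loops; the public API and the
scientific documentation live in :mod:`burdendmf.dmf` and
:mod:`burdendmf.bold`. All kernels take plain float64 scalars/arrays and are
deterministic given the integer seed passed in.

Units inside the neural kernels: time in ms, currents in nA, rates in Hz.
The gating drifts convert rates to kHz (per-ms) — the excitatory kinetic
constant gamma already carries the factor 1/1000, and the inhibitory drift
divides r_I by 1000 explicitly. The hemodynamic kernel works in seconds.
"""

import numpy as np
from numba import njit

__all__ = ["simulate", "mean_rates", "hemo_bold"]


@njit(cache=True, inline="always")
def _rate(I, a, b, d, M):
    """Gain-modulated sigmoidal transfer M(aI-b)/(1-exp(-d(aI-b))).

    M acts as a multiplicative response gain, so rates scale monotonically
    with M (reduced inhibitory gain means reduced inhibitory firing). The
    removable singularity at aI-b=0 is filled by its Taylor expansion
    (limit M/d)."""
    u = a * I - b
    x = d * u
    if np.abs(x) < 1e-6:
        # u/(1-exp(-du)) = (1/d) * x/(1-exp(-x)) ~ (1/d)(1 + x/2 + x^2/12)
        return (M / d) * (1.0 + 0.5 * x + x * x / 12.0)
    return M * u / (1.0 - np.exp(-x))


@njit(cache=True)
def simulate(
    C, J, M_E, M_I,
    W_E, W_I, I0, w_plus, J_N, G, lam, I_ext,
    a_E, b_E, d_E, a_I, b_I, d_I,
    tau_E, tau_I, gamma, sigma, dt,
    S_E0, S_I0, n_steps, store_every, seed,
):
    """Euler-Maruyama integration of the coupled E/I gating equations.

    Returns (S_E, S_I, r_E, r_I) sampled every `store_every` steps; the
    sample at index t corresponds to the state *before* the t-th update, so
    the initial condition is included.
    """
    np.random.seed(seed)
    N = C.shape[0]
    n_stored = (n_steps - 1) // store_every + 1
    S_E_out = np.empty((n_stored, N))
    S_I_out = np.empty((n_stored, N))
    r_E_out = np.empty((n_stored, N))
    r_I_out = np.empty((n_stored, N))

    S_E = S_E0.copy()
    S_I = S_I0.copy()
    sq_dt = np.sqrt(dt)
    idx = 0
    for t in range(n_steps):
        coupling = np.dot(C, S_E)  # C[k, j] S_E[j]
        store = t % store_every == 0
        for k in range(N):
            I_E = (W_E * I0 + w_plus * J_N * S_E[k]
                   + J_N * G * coupling[k] - J[k] * S_I[k] + I_ext)
            I_I = (W_I * I0 + J_N * S_E[k] - S_I[k]
                   + lam * J_N * G * coupling[k])
            rE = _rate(I_E, a_E, b_E, d_E, M_E[k])
            rI = _rate(I_I, a_I, b_I, d_I, M_I[k])
            if store:
                S_E_out[idx, k] = S_E[k]
                S_I_out[idx, k] = S_I[k]
                r_E_out[idx, k] = rE
                r_I_out[idx, k] = rI
            dSE = -S_E[k] / tau_E + (1.0 - S_E[k]) * gamma * rE
            dSI = -S_I[k] / tau_I + rI / 1000.0
            nE = sigma * sq_dt * np.random.standard_normal() if sigma > 0 else 0.0
            nI = sigma * sq_dt * np.random.standard_normal() if sigma > 0 else 0.0
            sE = S_E[k] + dt * dSE + nE
            sI = S_I[k] + dt * dSI + nI
            # gating variables are fractions; noise may transiently overshoot
            S_E[k] = min(max(sE, 0.0), 1.0)
            S_I[k] = min(max(sI, 0.0), 1.0)
        if store:
            idx += 1
    return S_E_out, S_I_out, r_E_out, r_I_out


@njit(cache=True)
def mean_rates(
    C, J, M_E, M_I,
    W_E, W_I, I0, w_plus, J_N, G, lam, I_ext,
    a_E, b_E, d_E, a_I, b_I, d_I,
    tau_E, tau_I, gamma, sigma, dt,
    S_E0, S_I0, n_burn, n_window, seed,
):
    """Time-averaged per-node rates over a window after a burn-in.

    Storage-free variant of :func:`simulate` used by the feedback inhibition
    control loop; follows the identical update rule and noise stream.
    """
    np.random.seed(seed)
    N = C.shape[0]
    S_E = S_E0.copy()
    S_I = S_I0.copy()
    sum_rE = np.zeros(N)
    sum_rI = np.zeros(N)
    sq_dt = np.sqrt(dt)
    for t in range(n_burn + n_window):
        coupling = np.dot(C, S_E)
        accumulate = t >= n_burn
        for k in range(N):
            I_E = (W_E * I0 + w_plus * J_N * S_E[k]
                   + J_N * G * coupling[k] - J[k] * S_I[k] + I_ext)
            I_I = (W_I * I0 + J_N * S_E[k] - S_I[k]
                   + lam * J_N * G * coupling[k])
            rE = _rate(I_E, a_E, b_E, d_E, M_E[k])
            rI = _rate(I_I, a_I, b_I, d_I, M_I[k])
            if accumulate:
                sum_rE[k] += rE
                sum_rI[k] += rI
            dSE = -S_E[k] / tau_E + (1.0 - S_E[k]) * gamma * rE
            dSI = -S_I[k] / tau_I + rI / 1000.0
            nE = sigma * sq_dt * np.random.standard_normal() if sigma > 0 else 0.0
            nI = sigma * sq_dt * np.random.standard_normal() if sigma > 0 else 0.0
            sE = S_E[k] + dt * dSE + nE
            sI = S_I[k] + dt * dSI + nI
            S_E[k] = min(max(sE, 0.0), 1.0)
            S_I[k] = min(max(sI, 0.0), 1.0)
    return sum_rE / n_window, sum_rI / n_window


@njit(cache=True)
def hemo_bold(r_E, dt_s, kappa, gamma_h, tau_h, alpha, rho, v0, k1, k2, k3):
    """Integrate the hemodynamic cascade driven by excitatory rates.

    Explicit Euler on (s, ln f, ln v, ln q) at the neural time step; the log
    change of variables keeps inflow, volume and deoxyhemoglobin positive by
    construction. The log variables are additionally clamped to +-15
    (physiological values are O(1); the clamp only engages for explosive
    neural input, where it keeps the arithmetic finite instead of
    overflowing). Returns the BOLD signal, same shape and sampling as r_E.
    """
    LOG_CLAMP = 15.0
    T, N = r_E.shape
    bold = np.empty((T, N))
    s = np.zeros(N)
    f_hat = np.zeros(N)  # ln f, f=1 at rest
    v_hat = np.zeros(N)
    q_hat = np.zeros(N)
    inv_alpha = 1.0 / alpha
    for t in range(T):
        for k in range(N):
            f = np.exp(f_hat[k])
            v = np.exp(v_hat[k])
            q = np.exp(q_hat[k])
            bold[t, k] = v0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v)
                               + k3 * (1.0 - v))
            ds = 0.5 * r_E[t, k] + 3.0 - kappa * s[k] - gamma_h * (f - 1.0)
            df = s[k]
            dv = (f - v ** inv_alpha) / tau_h
            E_f = (1.0 - (1.0 - rho) ** (1.0 / f)) / rho
            dq = (f * E_f - q * v ** inv_alpha / v) / tau_h
            s[k] = s[k] + dt_s * ds
            f_hat[k] = min(max(f_hat[k] + dt_s * df / f, -LOG_CLAMP), LOG_CLAMP)
            v_hat[k] = min(max(v_hat[k] + dt_s * dv / v, -LOG_CLAMP), LOG_CLAMP)
            q_hat[k] = min(max(q_hat[k] + dt_s * dq / q, -LOG_CLAMP), LOG_CLAMP)
    return bold
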
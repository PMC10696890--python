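"""Hemodynamic forward model: excitatory rates to BOLD signals.

Generalized balloon-windkessel cascade: firing drives a vasodilatory signal
s (with autoregulatory feedback), s drives blood inflow f, inflow changes
blood volume v and deoxyhemoglobin content q, and the measured BOLD contrast
is a weighted combination of (1-q), (1-q/v) and (1-v). The inflow, volume
and deoxyhemoglobin states are integrated in log coordinates (z_hat = ln z,
dz_hat/dt = F(z)/z), which makes their positivity structural rather than a
numerical accident.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import _core

__all__ = [
    "HemodynamicConstants",
    "HemodynamicState",
    "hemodynamic_step",
    "hemodynamic_fixed_point",
    "bold_signal",
    "rates_to_bold",
    "downsample_to_tr",
]


@dataclass(frozen=True)
class HemodynamicConstants:
    """Biophysical constants of the hemodynamic cascade (SI where noted)."""

    kappa: float = 0.65    # vasodilatory signal decay (s^-1)
    gamma_h: float = 0.41  # flow autoregulation (s^-1)
    tau_h: float = 0.98    # hemodynamic transit time (s)
    alpha: float = 0.32    # Grubb vessel stiffness exponent
    rho: float = 0.34      # resting oxygen extraction fraction
    v0: float = 0.02       # resting venous blood volume fraction
    k1: float = 7 * 0.34   # BOLD coefficient 7*rho
    k2: float = 2.0
    k3: float = 2 * 0.34 - 0.2  # 2*rho - 0.2

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("kappa", "gamma_h", "tau_h", "rho", "v0", "k1", "k2", "k3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def asdict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class HemodynamicState:
    """Per-region hemodynamic state in log coordinates.

    ``s`` is the (unbounded) vasodilatory signal; ``f_hat``, ``v_hat``,
    ``q_hat`` are natural logs of inflow, volume and deoxyhemoglobin, so the
    physical states exp(.) are positive by construction.
    """

    s: np.ndarray
    f_hat: np.ndarray
    v_hat: np.ndarray
    q_hat: np.ndarray

    @classmethod
    def resting(cls, n_regions: int) -> "HemodynamicState":
        z = np.zeros(n_regions)
        return cls(z, z.copy(), z.copy(), z.copy())

    @property
    def f(self):
        return np.exp(self.f_hat)

    @property
    def v(self):
        return np.exp(self.v_hat)

    @property
    def q(self):
        return np.exp(self.q_hat)


def _drifts(state: HemodynamicState, r_E, c: HemodynamicConstants):
    f, v, q = state.f, state.v, state.q
    ds = 0.5 * np.asarray(r_E, dtype=float) + 3.0 - c.kappa * state.s \
        - c.gamma_h * (f - 1.0)
    df = state.s
    dv = (f - v ** (1.0 / c.alpha)) / c.tau_h
    E_f = (1.0 - (1.0 - c.rho) ** (1.0 / f)) / c.rho
    dq = (f * E_f - q * v ** (1.0 / c.alpha) / v) / c.tau_h
    return ds, df, dv, dq


def hemodynamic_step(
    state: HemodynamicState, r_E, c: HemodynamicConstants, dt_s: float
) -> HemodynamicState:
    """One explicit-Euler step of length ``dt_s`` (seconds) in log variables."""
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    ds, df, dv, dq = _drifts(state, r_E, c)
    new = HemodynamicState(
        state.s + dt_s * ds,
        state.f_hat + dt_s * df / state.f,
        state.v_hat + dt_s * dv / state.v,
        state.q_hat + dt_s * dq / state.q,
    )
    for arr in (new.s, new.f_hat, new.v_hat, new.q_hat):
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError("non-finite hemodynamic state")
    return new


def hemodynamic_fixed_point(
    r_E: float, c: HemodynamicConstants
) -> HemodynamicState:
    """Closed-form equilibrium under a constant drive r_E (single region).

    At equilibrium the vasodilatory signal vanishes (df/dt = s = 0), inflow
    balances the drive, volume follows the Grubb relation and oxygen
    extraction balances washout.
    """
    f = 1.0 + (0.5 * r_E + 3.0) / c.gamma_h
    v = f ** c.alpha
    E_f = (1.0 - (1.0 - c.rho) ** (1.0 / f)) / c.rho
    q = f * E_f * v / v ** (1.0 / c.alpha)
    one = np.ones(1)
    return HemodynamicState(0.0 * one, np.log(f) * one, np.log(v) * one,
                            np.log(q) * one)


def bold_signal(v, q, c: HemodynamicConstants):
    """BOLD contrast B = v0 [k1(1-q) + k2(1-q/v) + k3(1-v)]."""
    v = np.asarray(v, dtype=float)
    q = np.asarray(q, dtype=float)
    return c.v0 * (c.k1 * (1.0 - q) + c.k2 * (1.0 - q / v) + c.k3 * (1.0 - v))


def rates_to_bold(
    r_E: np.ndarray, dt_ms: float, c: HemodynamicConstants | None = None
) -> np.ndarray:
    """BOLD time series (same sampling as the rates) from a (T, N) rate array.

    Integrates the cascade at the neural time step from the resting state
    f = v = q = 1, s = 0.
    """
    c = c or HemodynamicConstants()
    r_E = np.ascontiguousarray(r_E, dtype=float)
    if r_E.ndim != 2:
        raise ValueError("r_E must be (time, regions)")
    return _core.hemo_bold(
        r_E, dt_ms / 1000.0, c.kappa, c.gamma_h, c.tau_h, c.alpha, c.rho,
        c.v0, c.k1, c.k2, c.k3,
    )


def downsample_to_tr(
    bold: np.ndarray, dt_ms: float, tr_s: float = 3.0, burn_in_s: float = 10.0
) -> np.ndarray:
    """Discard the burn-in and sample every TR, returning (regions, volumes).

    The volume count is floor((duration - burn_in)/TR).
    """
    bold = np.asarray(bold, dtype=float)
    stride = tr_s * 1000.0 / dt_ms
    if abs(stride - round(stride)) > 1e-9 * stride:
        raise ValueError(f"TR {tr_s}s is not a multiple of dt {dt_ms}ms")
    stride = int(round(stride))
    burn = int(round(burn_in_s * 1000.0 / dt_ms))
    duration_s = bold.shape[0] * dt_ms / 1000.0
    if burn >= bold.shape[0]:
        raise ValueError(
            f"burn-in {burn_in_s}s consumes the whole {duration_s}s series"
        )
    n_vol = int(np.floor((duration_s - burn_in_s) / tr_s))
    if n_vol < 1:
        raise ValueError("series too short for a single volume after burn-in")
    return bold[burn::stride][:n_vol].T
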
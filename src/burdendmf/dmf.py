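"""Balanced excitation-inhibition (BEI) dynamic mean-field network model.

Each brain region is a pair of coupled excitatory (NMDA-mediated) and
inhibitory (GABA_A-mediated) neural-mass populations described by synaptic
gating fractions S^(E), S^(I). Long-range coupling acts E-to-E through the
structural connectome, scaled by a single global coupling G. Per-node
feedback inhibition control (FIC) tunes the inhibitory-to-excitatory weight
J_n so every excitatory pool fires near a low spontaneous rate (~3 Hz),
providing the homogeneous reference model.

Regional heterogeneity enters through the gain factors M^(E), M^(I) of the
population transfer functions, modelled as products of first-order
polynomials in the regional amyloid-beta and tau burdens:

    M_k^E = (1 + b_E_abeta + s_E_abeta * abeta_k) (1 + b_E_tau + s_E_tau * tau_k)
    M_k^I = (1 + b_I_abeta + s_I_abeta * abeta_k) (1 + b_I_tau + s_I_tau * tau_k)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from . import _core
from .connectome import StructuralConnectome

__all__ = [
    "DMFParameters",
    "GainParameters",
    "BurdenMap",
    "FICWeights",
    "SimResult",
    "GAIN_EPS",
    "compute_gains",
    "transfer_rate",
    "currents",
    "integrate",
    "calibrate_fic",
]

logger = logging.getLogger(__name__)

#: lower clamp for gain factors; the transfer function requires M > 0
GAIN_EPS = 1e-6


@dataclass(frozen=True)
class DMFParameters:
    """Constants of the dynamic mean-field equations.

    Times in ms, currents in nA, rates in Hz. Defaults reproduce the
    standard resting-state parameterization in which an isolated node shows
    low spontaneous excitatory activity.
    """

    W_E: float = 1.0        # external-input scaling, excitatory pool
    W_I: float = 0.7        # external-input scaling, inhibitory pool
    I_0: float = 0.382      # overall effective external input (nA)
    w_plus: float = 1.4     # local E->E recurrence weight
    J_N: float = 0.15       # excitatory (NMDA) synaptic coupling (nA)
    G: float = 0.0          # global coupling (dimensionless)
    lam: float = 0.0        # long-range feedforward inhibition switch {0,1}
    I_ext: float = 0.0      # additional external current (nA)
    a_E: float = 310.0      # nC^-1
    b_E: float = 125.0      # Hz
    d_E: float = 0.16       # s
    a_I: float = 615.0      # nC^-1
    b_I: float = 177.0      # Hz
    d_I: float = 0.087      # s
    tau_E: float = 100.0    # NMDA decay (ms)
    tau_I: float = 10.0     # GABA decay (ms)
    gamma: float = 0.641 / 1000.0  # kinetic rate (carries the Hz->kHz factor)
    sigma: float = 0.01     # noise amplitude (nA)
    dt: float = 1.0         # integration step (ms)

    def __post_init__(self):
        if self.tau_E <= 0 or self.tau_I <= 0 or self.dt <= 0:
            raise ValueError("time constants and dt must be positive")
        if self.sigma < 0 or self.G < 0:
            raise ValueError("sigma and G must be non-negative")
        if self.lam not in (0.0, 1.0, 0, 1):
            raise ValueError("lam must be 0 or 1")

    def asdict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class GainParameters:
    """Bias/scaling coefficients of the burden-to-gain polynomials.

    The biological sign constraints (amyloid-beta disrupts inhibitory
    interneurons and impairs glutamate reuptake; tau targets excitatory
    synapses only) are: s_I_abeta < 0, s_E_abeta > 0, s_E_tau < 0,
    b_I_tau = s_I_tau = 0, leaving 6 free coefficients.
    """

    b_E_abeta: float = 0.0
    s_E_abeta: float = 0.0
    b_E_tau: float = 0.0
    s_E_tau: float = 0.0
    b_I_abeta: float = 0.0
    s_I_abeta: float = 0.0
    b_I_tau: float = 0.0
    s_I_tau: float = 0.0

    #: attribute order of the 6 coefficients that the constraints leave free
    FREE_NAMES = (
        "b_E_abeta", "s_E_abeta", "b_E_tau", "s_E_tau", "b_I_abeta", "s_I_abeta",
    )

    def validate_constraints(self) -> None:
        """Raise unless the directional constraints hold (zeros allowed only
        where a coefficient is unused, i.e. the homogeneous limit)."""
        if self.b_I_tau != 0.0 or self.s_I_tau != 0.0:
            raise ValueError("tau does not act on inhibitory pools: "
                             "b_I_tau and s_I_tau must be 0")
        if self.s_I_abeta > 0:
            raise ValueError("s_I_abeta must be <= 0 (GABAergic dysfunction)")
        if self.s_E_abeta < 0:
            raise ValueError("s_E_abeta must be >= 0 (impaired glutamate reuptake)")
        if self.s_E_tau > 0:
            raise ValueError("s_E_tau must be <= 0 (reduced excitatory release)")

    def free_values(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.FREE_NAMES])

    @classmethod
    def from_free_values(cls, values) -> "GainParameters":
        values = np.asarray(values, dtype=float)
        if values.shape != (6,):
            raise ValueError("expected 6 free coefficients")
        return cls(**dict(zip(cls.FREE_NAMES, values)))


@dataclass(frozen=True)
class BurdenMap:
    """Per-region protein load (SUVR-like units, non-negative)."""

    values: np.ndarray
    protein: str = "abeta"
    subject_id: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).copy()
        if v.ndim != 1:
            raise ValueError("burden map must be a 1-D vector")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValueError("burden values must be finite and non-negative")
        if self.protein not in ("abeta", "tau"):
            raise ValueError(f"unknown protein {self.protein!r}")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class FICWeights:
    """Per-node inhibitory-to-excitatory weights from FIC calibration."""

    J: np.ndarray
    converged: bool = True
    n_iterations: int = 0
    rate_history: np.ndarray | None = None  # (n_iter, N) mean excitatory rates

    def __post_init__(self):
        J = np.asarray(self.J, dtype=float).copy()
        if np.any(J <= 0):
            raise ValueError("FIC weights must be positive")
        J.setflags(write=False)
        object.__setattr__(self, "J", J)


@dataclass(frozen=True)
class SimResult:
    """Strided state/rate trajectories from :func:`integrate`."""

    S_E: np.ndarray   # (T, N) gating fractions
    S_I: np.ndarray
    r_E: np.ndarray   # (T, N) rates in Hz
    r_I: np.ndarray
    dt: float         # sampling interval of the stored rows (ms)
    seed: int
    params: DMFParameters


def compute_gains(
    abeta: BurdenMap, tau: BurdenMap, gp: GainParameters
) -> tuple[np.ndarray, np.ndarray]:
    """Regional excitatory/inhibitory gain factors from the burden maps.

    Products are clamped below at ``GAIN_EPS`` (the transfer function is only
    defined for positive gain); clamping events are counted and logged.
    """
    if len(abeta) != len(tau):
        raise ValueError(f"burden maps differ in length: {len(abeta)} vs {len(tau)}")
    a, t = abeta.values, tau.values
    M_E = (1.0 + gp.b_E_abeta + gp.s_E_abeta * a) * (1.0 + gp.b_E_tau + gp.s_E_tau * t)
    M_I = (1.0 + gp.b_I_abeta + gp.s_I_abeta * a) * (1.0 + gp.b_I_tau + gp.s_I_tau * t)
    n_clamped = int(np.sum(M_E < GAIN_EPS) + np.sum(M_I < GAIN_EPS))
    if n_clamped:
        logger.warning(
            "compute_gains: clamped %d gain value(s) to %.0e; "
            "coefficients drive the gain polynomial non-positive", n_clamped, GAIN_EPS
        )
    return np.maximum(M_E, GAIN_EPS), np.maximum(M_I, GAIN_EPS)


def transfer_rate(I, a: float, b: float, d: float, M=1.0):
    """Population transfer function H(I) = M(aI-b)/(1-exp(-d(aI-b))).

    The gain M scales the population response multiplicatively, so firing
    is monotone in M (a gain-suppressed inhibitory pool fires less — the
    disinhibition mechanism of the amyloid model). Total and continuous for
    M > 0; at the removable singularity aI-b = 0 it returns the analytic
    limit M/d (1/d for the unmodulated transfer). Vectorized over I and M.
    """
    I = np.asarray(I, dtype=float)
    M = np.asarray(M, dtype=float)
    if np.any(M <= 0):
        raise ValueError("gain M must be positive")
    u = a * I - b
    x = d * u
    with np.errstate(over="ignore"):
        direct = M * np.where(x == 0.0, 1.0, u) / np.where(
            x == 0.0, d, 1.0 - np.exp(-x)
        )
    taylor = (M / d) * (1.0 + 0.5 * x + x * x / 12.0)
    out = np.where(np.abs(x) < 1e-6, taylor, direct)
    return out if out.ndim else float(out)


def currents(
    S_E: np.ndarray,
    S_I: np.ndarray,
    sc: StructuralConnectome,
    fic: FICWeights,
    p: DMFParameters,
) -> tuple[np.ndarray, np.ndarray]:
    """Synaptic input currents (nA) to the E and I pools of every node."""
    S_E = np.asarray(S_E, dtype=float)
    S_I = np.asarray(S_I, dtype=float)
    N = sc.n_regions
    if S_E.shape != (N,) or S_I.shape != (N,) or fic.J.shape != (N,):
        raise ValueError("state/weight dimensions inconsistent with connectome")
    coupling = sc.weights @ S_E
    I_E = (p.W_E * p.I_0 + p.w_plus * p.J_N * S_E + p.J_N * p.G * coupling
           - fic.J * S_I + p.I_ext)
    I_I = p.W_I * p.I_0 + p.J_N * S_E - S_I + p.lam * p.J_N * p.G * coupling
    return I_E, I_I


def _gain_arrays(gains, n: int) -> tuple[np.ndarray, np.ndarray]:
    if gains is None:
        return np.ones(n), np.ones(n)
    M_E, M_I = gains
    M_E = np.ascontiguousarray(M_E, dtype=float)
    M_I = np.ascontiguousarray(M_I, dtype=float)
    if M_E.shape != (n,) or M_I.shape != (n,):
        raise ValueError("gain vectors must have one entry per region")
    return M_E, M_I


def _core_args(sc, fic, gains, p):
    n = sc.n_regions
    M_E, M_I = _gain_arrays(gains, n)
    return (
        np.ascontiguousarray(sc.weights, dtype=float),
        np.ascontiguousarray(fic.J, dtype=float),
        M_E, M_I,
        p.W_E, p.W_I, p.I_0, p.w_plus, p.J_N, p.G, float(p.lam), p.I_ext,
        p.a_E, p.b_E, p.d_E, p.a_I, p.b_I, p.d_I,
        p.tau_E, p.tau_I, p.gamma, p.sigma, p.dt,
    )


#: uniform low-activity initial gating; a burn-in is discarded downstream
S_INIT = 0.001


def integrate(
    sc: StructuralConnectome,
    fic: FICWeights,
    gains,
    p: DMFParameters,
    duration_ms: float,
    seed: int,
    store_every: int = 1,
) -> SimResult:
    """Euler-Maruyama integration of the network for ``duration_ms``.

    Uncorrelated Gaussian noise of amplitude sigma*sqrt(dt) enters both
    gating equations each step; gating is clamped to [0, 1] afterwards.
    Identical seeds give bitwise-identical trajectories. ``gains`` is an
    ``(M_E, M_I)`` pair or None for the homogeneous model.
    """
    if duration_ms < p.dt:
        raise ValueError("duration must cover at least one step")
    n_steps = int(round(duration_ms / p.dt))
    s0 = np.full(sc.n_regions, S_INIT)
    S_E, S_I, r_E, r_I = _core.simulate(
        *_core_args(sc, fic, gains, p), s0, s0.copy(),
        n_steps, int(store_every), int(seed),
    )
    if not (np.all(np.isfinite(S_E)) and np.all(np.isfinite(r_E))):
        raise FloatingPointError("non-finite network state during integration")
    return SimResult(S_E, S_I, r_E, r_I, p.dt * store_every, int(seed), p)


def simulate_mean_rates(
    sc, fic, gains, p, burn_ms: float, window_ms: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-node time-averaged (r_E, r_I) over a window after a burn-in."""
    n_burn = int(round(burn_ms / p.dt))
    n_window = int(round(window_ms / p.dt))
    if n_window < 1:
        raise ValueError("window must cover at least one step")
    s0 = np.full(sc.n_regions, S_INIT)
    return _core.mean_rates(
        *_core_args(sc, fic, gains, p), s0, s0.copy(), n_burn, n_window, int(seed)
    )


def calibrate_fic(
    sc: StructuralConnectome,
    gains,
    p: DMFParameters,
    target_rate: float = 3.0,
    tol: float = 0.2,
    max_iter: int = 100,
    seed: int = 0,
    eta: float = 0.5,
    J_min: float = 1e-3,
    burn_ms: float = 2000.0,
    window_ms: float = 10000.0,
) -> FICWeights:
    """Feedback inhibition control: tune J_n to clamp excitatory rates.

    Iterative rate-targeting scheme: simulate a window, measure per-node mean
    excitatory rates, and move each node's inhibitory weight proportionally
    to its relative rate error, J_n <- max(J_n + eta*(r_n - target)/target,
    J_min). The same seed is reused every iteration so the update sees a fixed
    noise realization. Non-convergence returns the best iterate with
    ``converged=False`` and a warning.
    """
    N = sc.n_regions
    J = np.ones(N)
    best_J, best_err = J.copy(), np.inf
    history = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        r_E, _ = simulate_mean_rates(
            sc, FICWeights(J), gains, p, burn_ms, window_ms, seed
        )
        history.append(r_E.copy())
        err = np.max(np.abs(r_E - target_rate))
        if err < best_err:
            best_err, best_J = err, J.copy()
        if err <= tol:
            converged = True
            break
        J = np.maximum(J + eta * (r_E - target_rate) / target_rate, J_min)
    if not converged:
        logger.warning(
            "FIC did not converge in %d iterations (max |rate error| = %.3f Hz); "
            "returning best iterate", max_iter, best_err,
        )
    return FICWeights(
        best_J if not converged else J,
        converged=converged,
        n_iterations=it,
        rate_history=np.array(history),
    )
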
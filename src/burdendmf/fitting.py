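"""Model fitting: homogeneous G-sweep and constrained gain optimization.

Two stages mirror the study design. First the homogeneous balanced model is
swept over the global coupling G, scoring each value against an empirical
target with three observables (static-FC correlation, sliding-window FCD KS,
phase-FCD KS); the phase-FCD KS minimum defines the working point G*.
Second, holding G* and the homogeneous FIC solution fixed, the six free
bias/scaling coefficients of the burden-to-gain polynomials are minimized
with Gaussian-process Bayesian optimization of the mean phase-FCD KS over
repeated stochastic trials, inside directional bounds encoding the known
physiology (amyloid-beta excites E pools and disables I pools, tau
depresses E pools only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .bold import HemodynamicConstants, downsample_to_tr, rates_to_bold
from .connectome import StructuralConnectome
from .dmf import (
    BurdenMap,
    DMFParameters,
    FICWeights,
    GainParameters,
    calibrate_fic,
    compute_gains,
    integrate,
)
from .observables import (
    FCDDistribution,
    FCMatrix,
    compare_fc,
    ks_distance,
    ph_fcd,
    static_fc,
    sw_fcd,
)
from .optim import OptimizeTrace, gp_minimize

__all__ = [
    "EmpiricalTarget",
    "FitResult",
    "SimulationSettings",
    "DEFAULT_BOUNDS",
    "simulate_trial",
    "sweep_g",
    "gain_objective",
    "optimize_gains",
    "restrict_2d",
    "restrict_abeta_only",
    "restrict_tau_only",
    "restrict_homogeneous",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationSettings:
    """Trial geometry shared by the sweep and the gain optimization."""

    trial_duration_s: float = 180.0  # includes the burn-in
    tr_s: float = 3.0
    burn_in_s: float = 10.0
    hemo: HemodynamicConstants = field(default_factory=HemodynamicConstants)
    ph_edge_trim: int = 10
    sw_window: int = 30
    sw_shift: int = 3

    @property
    def n_volumes(self) -> int:
        return int(np.floor((self.trial_duration_s - self.burn_in_s) / self.tr_s))


@dataclass(frozen=True)
class EmpiricalTarget:
    """Fitting target: FC matrix plus FCD distributions.

    Built either from a raw regions x volumes BOLD matrix or from
    precomputed observables. ``swfcd`` may be None for series too short for
    the sliding window.
    """

    phfcd: FCDDistribution
    fc: FCMatrix | None = None
    swfcd: FCDDistribution | None = None

    @classmethod
    def from_bold(cls, ts: np.ndarray, settings: SimulationSettings | None = None
                  ) -> "EmpiricalTarget":
        s = settings or SimulationSettings()
        ts = np.asarray(ts, dtype=float)
        fc = static_fc(ts)
        swfcd = None
        if ts.shape[1] >= s.sw_window + s.sw_shift:
            swfcd = sw_fcd(ts, s.sw_window, s.sw_shift)
        phfcd = ph_fcd(ts, s.tr_s, edge_trim=s.ph_edge_trim)
        return cls(phfcd=phfcd, fc=fc, swfcd=swfcd)


@dataclass(frozen=True)
class FitResult:
    """Observable distances for one parameter setting (means over trials)."""

    parameters: dict
    phfcd_ks: float
    fc_similarity: float | None = None
    swfcd_ks: float | None = None
    n_trials: int = 1
    seeds: tuple = ()
    per_trial: dict = field(default_factory=dict)
    trace: OptimizeTrace | None = None


def _trial_seed(master_seed: int, eval_index: int, trial: int) -> int:
    """Deterministic per-trial seed below 2^31."""
    ss = np.random.SeedSequence([int(master_seed), int(eval_index), int(trial)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def simulate_trial(
    sc: StructuralConnectome,
    fic: FICWeights,
    gains,
    p: DMFParameters,
    settings: SimulationSettings,
    seed: int,
) -> np.ndarray:
    """One stochastic forward trial: DMF -> hemodynamics -> TR sampling."""
    sim = integrate(sc, fic, gains, p, settings.trial_duration_s * 1000.0, seed)
    bold = rates_to_bold(sim.r_E, p.dt, settings.hemo)
    return downsample_to_tr(bold, p.dt, settings.tr_s, settings.burn_in_s)


def _score_trial(ts, target: EmpiricalTarget, s: SimulationSettings):
    ph = float(ks_distance(ph_fcd(ts, s.tr_s, edge_trim=s.ph_edge_trim),
                           target.phfcd))
    fc = sw = None
    if target.fc is not None:
        fc = compare_fc(static_fc(ts), target.fc)
    if target.swfcd is not None and ts.shape[1] >= s.sw_window + s.sw_shift:
        sw = float(ks_distance(sw_fcd(ts, s.sw_window, s.sw_shift), target.swfcd))
    return fc, sw, ph


def sweep_g(
    sc: StructuralConnectome,
    target: EmpiricalTarget,
    g_grid,
    trials_per_g: int = 1,
    settings: SimulationSettings | None = None,
    seed: int = 0,
    params: DMFParameters | None = None,
    fic_kwargs: dict | None = None,
) -> tuple[list[FitResult], float]:
    """Homogeneous G-sweep: FIC-calibrate and score every grid value.

    Returns the per-G results and the argmin of the phase-FCD KS distance.
    """
    g_grid = np.atleast_1d(np.asarray(g_grid, dtype=float))
    settings = settings or SimulationSettings()
    base = params or DMFParameters()
    fic_kwargs = fic_kwargs or {}
    results = []
    for gi, G in enumerate(g_grid):
        p = replace(base, G=float(G))
        fic = calibrate_fic(sc, None, p, seed=_trial_seed(seed, gi, 0),
                            **fic_kwargs)
        fcs, sws, phs, seeds = [], [], [], []
        for t in range(trials_per_g):
            ts_seed = _trial_seed(seed, gi, t + 1)
            ts = simulate_trial(sc, fic, None, p, settings, ts_seed)
            fc, sw, ph = _score_trial(ts, target, settings)
            seeds.append(ts_seed)
            phs.append(ph)
            if fc is not None:
                fcs.append(fc)
            if sw is not None:
                sws.append(sw)
        results.append(FitResult(
            parameters={"G": float(G)},
            phfcd_ks=float(np.mean(phs)),
            fc_similarity=float(np.mean(fcs)) if fcs else None,
            swfcd_ks=float(np.mean(sws)) if sws else None,
            n_trials=trials_per_g,
            seeds=tuple(seeds),
            per_trial={"phfcd_ks": np.array(phs), "fc_similarity": np.array(fcs),
                       "swfcd_ks": np.array(sws)},
        ))
    best_G = float(g_grid[int(np.argmin([r.phfcd_ks for r in results]))])
    return results, best_G


def gain_objective(
    gp: GainParameters,
    sc: StructuralConnectome,
    abeta: BurdenMap,
    tau: BurdenMap,
    target: EmpiricalTarget,
    G_star: float,
    n_trials: int = 10,
    seed: int = 0,
    fic: FICWeights | None = None,
    settings: SimulationSettings | None = None,
    params: DMFParameters | None = None,
    eval_index: int = 0,
    return_per_trial: bool = False,
):
    """Mean phase-FCD KS distance to the target over independent trials.

    FIC is calibrated at the homogeneous working point (G*, M=1) and held
    fixed while the gains act, unless a calibrated ``fic`` is supplied.
    Trial seeds derive deterministically from (seed, eval_index, trial).
    """
    gp.validate_constraints()
    settings = settings or SimulationSettings()
    p = replace(params or DMFParameters(), G=float(G_star))
    if fic is None:
        fic = calibrate_fic(sc, None, p, seed=_trial_seed(seed, 0, 0))
    gains = compute_gains(abeta, tau, gp)
    ph = np.empty(n_trials)
    for t in range(n_trials):
        ts = simulate_trial(sc, fic, gains, p, settings,
                            _trial_seed(seed, eval_index, t + 1))
        if not np.all(np.isfinite(ts)):
            # explosive dynamics in an extreme corner of the search box:
            # score with the maximal KS distance rather than propagating NaN
            ph[t] = 1.0
            continue
        ph[t] = ks_distance(ph_fcd(ts, settings.tr_s,
                                   edge_trim=settings.ph_edge_trim),
                            target.phfcd)
    return (float(ph.mean()), ph) if return_per_trial else float(ph.mean())


#: default search box: directional constraints with magnitude <= 5
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "b_E_abeta": (-5.0, 5.0),
    "s_E_abeta": (0.0, 5.0),
    "b_E_tau": (-5.0, 5.0),
    "s_E_tau": (-5.0, 0.0),
    "b_I_abeta": (-5.0, 5.0),
    "s_I_abeta": (-5.0, 0.0),
}


def _pin(bounds: dict, names) -> dict:
    out = dict(bounds)
    for n in names:
        out[n] = (0.0, 0.0)
    return out


def restrict_2d(bounds: dict | None = None) -> dict:
    """Free only the inhibitory amyloid coefficients (2-D search)."""
    b = dict(bounds or DEFAULT_BOUNDS)
    return _pin(b, [n for n in GainParameters.FREE_NAMES
                    if n not in ("b_I_abeta", "s_I_abeta")])


def restrict_abeta_only(bounds: dict | None = None) -> dict:
    """Zero out the tau pathway, keeping all amyloid coefficients free."""
    return _pin(dict(bounds or DEFAULT_BOUNDS), ["b_E_tau", "s_E_tau"])


def restrict_tau_only(bounds: dict | None = None) -> dict:
    """Zero out the amyloid pathway, keeping the tau (excitatory) terms."""
    return _pin(dict(bounds or DEFAULT_BOUNDS),
                ["b_E_abeta", "s_E_abeta", "b_I_abeta", "s_I_abeta"])


def restrict_homogeneous(bounds: dict | None = None) -> dict:
    """Pin every coefficient: the homogeneous balanced model."""
    return _pin(dict(bounds or DEFAULT_BOUNDS), GainParameters.FREE_NAMES)


def optimize_gains(
    sc: StructuralConnectome,
    abeta: BurdenMap,
    tau: BurdenMap,
    target: EmpiricalTarget,
    G_star: float,
    bounds: dict | None = None,
    n_calls: int = 100,
    n_trials: int = 10,
    seed: int = 0,
    settings: SimulationSettings | None = None,
    params: DMFParameters | None = None,
    x0: list[GainParameters] | None = None,
) -> FitResult:
    """GP Bayesian minimization of the gain objective inside the constraints.

    ``bounds`` maps each free coefficient name to a (low, high) box edge;
    coefficients pinned with low == high are held at that value (the
    ``restrict_*`` helpers build the isolation and 2-D variants). ``x0``
    gain points are evaluated before any random draws — useful for seeding
    a wide search with the optima of nested (restricted) searches. Returns
    the best coefficients and the full evaluation trace.
    """
    bounds = dict(DEFAULT_BOUNDS if bounds is None else bounds)
    unknown = set(bounds) - set(GainParameters.FREE_NAMES)
    if unknown:
        raise ValueError(f"unknown coefficients in bounds: {sorted(unknown)}")
    for n in GainParameters.FREE_NAMES:
        lo, hi = bounds.get(n, (0.0, 0.0))
        if lo > hi:
            raise ValueError(f"invalid bounds for {n}: ({lo}, {hi})")
    names = list(GainParameters.FREE_NAMES)
    free = [n for n in names if bounds.get(n, (0.0, 0.0))[0]
            < bounds.get(n, (0.0, 0.0))[1]]
    pinned = {n: bounds.get(n, (0.0, 0.0))[0] for n in names if n not in free}

    settings = settings or SimulationSettings()
    p = replace(params or DMFParameters(), G=float(G_star))
    fic = calibrate_fic(sc, None, p, seed=_trial_seed(seed, 0, 0))

    def to_gp(x: np.ndarray) -> GainParameters:
        coeffs = dict(pinned)
        coeffs.update(dict(zip(free, x)))
        return GainParameters(**coeffs)

    counter = {"i": 0}

    def objective(x: np.ndarray) -> float:
        counter["i"] += 1
        return gain_objective(
            to_gp(x), sc, abeta, tau, target, G_star, n_trials=n_trials,
            seed=seed, fic=fic, settings=settings, params=params,
            eval_index=counter["i"],
        )

    if free:
        starts = [[getattr(g, n) for n in free] for g in (x0 or [])]
        trace = gp_minimize(objective, [bounds[n] for n in free],
                            n_calls=n_calls, seed=seed, x0=starts or None)
        best = to_gp(trace.x_best)
        y_best = trace.y_best
    else:  # fully pinned: single evaluation of the homogeneous model
        best = to_gp(np.empty(0))
        y_best = objective(np.empty(0))
        trace = OptimizeTrace(np.empty(0), y_best, np.empty((1, 0)),
                              np.array([y_best]))
    return FitResult(
        parameters={**pinned, **dict(zip(free, np.atleast_1d(trace.x_best)))}
        if free else dict(pinned),
        phfcd_ks=float(y_best),
        n_trials=n_trials,
        seeds=(seed,),
        per_trial={"objective_trace": trace.y},
        trace=trace,
    )
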
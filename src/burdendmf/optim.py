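"""Sequential Gaussian-process minimization of expensive noisy objectives.

Bayesian optimization: the objective is approximated by a Gaussian-process
surrogate (Matern 5/2 kernel plus a white-noise term, fitted to the
evaluations so far), and each new point maximizes the expected-improvement
acquisition over a random candidate set. Suited to low-dimensional (<10)
problems whose evaluations cost seconds and are corrupted by simulation
noise, where gradient or local methods would stall in local minima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

__all__ = ["OptimizeTrace", "gp_minimize"]


@dataclass(frozen=True)
class OptimizeTrace:
    """Evaluation history and optimum of one gp_minimize run."""

    x_best: np.ndarray
    y_best: float
    X: np.ndarray  # (n_calls, n_dims) probed points, evaluation order
    y: np.ndarray  # (n_calls,) objective values


def _expected_improvement(mu, sd, y_best, xi=0.01):
    sd = np.maximum(sd, 1e-12)
    z = (y_best - mu - xi) / sd
    return (y_best - mu - xi) * stats.norm.cdf(z) + sd * stats.norm.pdf(z)


def gp_minimize(
    func: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    n_calls: int = 100,
    seed: int = 0,
    n_initial: int | None = None,
    n_candidates: int = 1024,
    x0: Sequence[Sequence[float]] | None = None,
) -> OptimizeTrace:
    """Minimize ``func`` over a box with a GP surrogate in ``n_calls`` calls.

    ``x0`` points (clipped to the box) are evaluated first, then
    ``n_initial`` uniform draws (default: min(10, n_calls), counting the
    ``x0`` evaluations); the remainder maximize expected improvement under
    the refitted surrogate. Fully deterministic given ``seed`` and a
    deterministic objective.
    """
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2 or np.any(bounds[:, 0] > bounds[:, 1]):
        raise ValueError("bounds must be a sequence of (low, high) pairs")
    if n_calls < 1:
        raise ValueError("n_calls must be >= 1")
    ndim = len(bounds)
    lo, hi = bounds[:, 0], bounds[:, 1]
    rng = np.random.default_rng(seed)
    n_initial = min(n_calls, n_initial if n_initial is not None else 10)

    X: list[np.ndarray] = []
    y: list[float] = []
    for x_start in list(x0 or [])[:n_calls]:
        x = np.clip(np.asarray(x_start, dtype=float), lo, hi)
        if x.shape != (ndim,):
            raise ValueError(f"x0 points must have {ndim} coordinates")
        X.append(x)
        y.append(float(func(x)))
    while len(X) < n_initial:
        x = lo + (hi - lo) * rng.random(ndim)
        X.append(x)
        y.append(float(func(x)))

    kernel = (
        ConstantKernel(1.0, (1e-3, 1e3))
        * Matern(length_scale=np.ones(ndim), length_scale_bounds=(1e-2, 1e2), nu=2.5)
        + WhiteKernel(1e-4, (1e-8, 1e1))
    )
    span = hi - lo
    while len(X) < n_calls:
        gpr = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, random_state=int(rng.integers(2**31)),
            n_restarts_optimizer=1,
        )
        Xs = (np.array(X) - lo) / np.where(span > 0, span, 1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gpr.fit(Xs, np.array(y))
        cand = rng.random((n_candidates, ndim))
        # densify around the incumbent: local perturbations of the best point
        best_x = Xs[int(np.argmin(y))]
        local = np.clip(best_x + 0.05 * rng.standard_normal((n_candidates // 4, ndim)),
                        0.0, 1.0)
        cand = np.vstack([cand, local])
        mu, sd = gpr.predict(cand, return_std=True)
        ei = _expected_improvement(mu, sd, float(np.min(y)))
        x = lo + span * cand[int(np.argmax(ei))]
        X.append(x)
        y.append(float(func(x)))

    X_arr, y_arr = np.array(X), np.array(y)
    ibest = int(np.argmin(y_arr))
    return OptimizeTrace(X_arr[ibest], float(y_arr[ibest]), X_arr, y_arr)
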
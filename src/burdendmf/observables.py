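"""Summary observables of BOLD dynamics and their comparison statistics.

Three observables characterize a regions x volumes BOLD matrix:

* static FC — the N x N Pearson correlation matrix over the full recording;
* swFCD — sliding-window functional connectivity dynamics: FC in windows of
  30 volumes stepped by 3, with window-to-window similarity given by the
  Pearson correlation of the upper-triangle FC vectors;
* phFCD — phase FCD: instantaneous phase coherence cos(theta_n - theta_p)
  from the Hilbert transform of (band-passed) signals, with time-to-time
  similarity given by the cosine similarity of the upper-triangle coherence
  vectors.

Distributions of the FCD matrices' upper triangles are compared with the
two-sample Kolmogorov-Smirnov distance, the model-fitting objective.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats

__all__ = [
    "FCMatrix",
    "FCDDistribution",
    "static_fc",
    "compare_fc",
    "sw_fcd",
    "ph_fcd",
    "ks_distance",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FCMatrix:
    """Symmetric unit-diagonal matrix of pairwise Pearson correlations."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).copy()
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_regions, k=1)
        return self.values[iu]


@dataclass(frozen=True)
class FCDDistribution:
    """Upper-triangle samples of a time x time similarity matrix."""

    samples: np.ndarray
    kind: str = "phase"  # {"sliding_window", "phase"}

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=float).ravel().copy()
        if self.kind not in ("sliding_window", "phase"):
            raise ValueError(f"unknown FCD kind {self.kind!r}")
        s.setflags(write=False)
        object.__setattr__(self, "samples", s)

    def __len__(self) -> int:
        return len(self.samples)


def _corrcoef_safe(ts: np.ndarray) -> np.ndarray:
    """Pearson correlation across rows with zero-variance rows zeroed out."""
    sd = ts.std(axis=1)
    flat = sd == 0
    if np.any(flat):
        logger.warning("%d zero-variance region(s); FC entries set to 0",
                       int(flat.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = np.corrcoef(ts)
    if np.any(flat):
        fc[flat, :] = 0.0
        fc[:, flat] = 0.0
    np.fill_diagonal(fc, 1.0)
    return np.clip(fc, -1.0, 1.0)


def static_fc(ts: np.ndarray) -> FCMatrix:
    """Static functional connectivity over the entire recording.

    ``ts`` is regions x volumes with at least 3 volumes.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be regions x volumes")
    if ts.shape[1] < 3:
        raise ValueError(f"need >= 3 volumes, got {ts.shape[1]}")
    return FCMatrix(_corrcoef_safe(ts))


def compare_fc(a: FCMatrix, b: FCMatrix) -> float:
    """Pearson correlation of the strictly-upper-triangle FC vectors."""
    if a.n_regions != b.n_regions:
        raise ValueError("FC matrices of different sizes")
    ua, ub = a.upper_triangle(), b.upper_triangle()
    r = np.corrcoef(ua, ub)[0, 1]
    return float(np.clip(r, -1.0, 1.0))


def sw_fcd(ts: np.ndarray, window: int = 30, shift: int = 3) -> FCDDistribution:
    """Sliding-window FCD distribution.

    Windows of ``window`` volumes stepped by ``shift``; the similarity of
    each pair of windows is the Pearson correlation of their upper-triangle
    FC vectors; the distribution is the upper triangle of the resulting
    window x window matrix (T'(T'-1)/2 samples for T' windows).
    """
    ts = np.asarray(ts, dtype=float)
    T = ts.shape[1]
    if T < window + shift:
        raise ValueError(f"need >= {window + shift} volumes, got {T}")
    starts = range(0, T - window + 1, shift)
    vecs = np.array(
        [FCMatrix(_corrcoef_safe(ts[:, s:s + window])).upper_triangle()
         for s in starts]
    )
    sim = np.corrcoef(vecs)
    iu = np.triu_indices(len(vecs), k=1)
    return FCDDistribution(np.clip(sim[iu], -1.0, 1.0), kind="sliding_window")


def _bandpass(ts: np.ndarray, tr_s: float, low_hz: float, high_hz: float,
              order: int = 2) -> np.ndarray:
    fs = 1.0 / tr_s
    nyq = fs / 2.0
    high = min(high_hz, 0.99 * nyq)
    sos = sp_signal.butter(order, [low_hz / nyq, high / nyq],
                           btype="band", output="sos")
    return sp_signal.sosfiltfilt(sos, ts, axis=1)


def ph_fcd(
    ts: np.ndarray,
    tr_s: float = 3.0,
    bandpass: tuple[float, float] | None = (0.008, 0.08),
    edge_trim: int = 10,
) -> FCDDistribution:
    """Phase-coherence FCD distribution.

    Instantaneous phases come from the Hilbert transform of each demeaned
    (and, by default, 0.008-0.08 Hz band-passed) regional signal. At every
    volume the coherence matrix cos(|theta_n - theta_p|) is vectorized over
    its upper triangle; the similarity of two volumes is the cosine
    similarity of their coherence vectors. ``edge_trim`` volumes at each end
    are discarded to suppress Hilbert edge effects.
    """
    ts = np.asarray(ts, dtype=float)
    N, T = ts.shape
    if T < 20:
        raise ValueError(f"need >= 20 volumes for phase estimation, got {T}")
    x = ts - ts.mean(axis=1, keepdims=True)
    if bandpass is not None:
        x = _bandpass(x, tr_s, *bandpass)
    phases = np.angle(sp_signal.hilbert(x, axis=1))  # (N, T)
    keep = slice(edge_trim, T - edge_trim if edge_trim else T)
    phases = phases[:, keep]
    Tk = phases.shape[1]
    if Tk < 2:
        raise ValueError("edge trimming leaves fewer than 2 volumes")
    # coherence vectors: cos(theta_n - theta_p) for n < p, per time point
    iu = np.triu_indices(N, k=1)
    diff = phases[iu[0], :] - phases[iu[1], :]          # (n_pairs, Tk)
    coh = np.cos(diff).T                                # (Tk, n_pairs)
    norms = np.linalg.norm(coh, axis=1)
    norms[norms == 0] = 1.0
    unit = coh / norms[:, None]
    sim = unit @ unit.T
    iut = np.triu_indices(Tk, k=1)
    return FCDDistribution(np.clip(sim[iut], -1.0, 1.0), kind="phase")


def ks_distance(a: FCDDistribution | np.ndarray,
                b: FCDDistribution | np.ndarray) -> float:
    """Two-sample Kolmogorov-Smirnov statistic between FCD distributions."""
    xa = a.samples if isinstance(a, FCDDistribution) else np.asarray(a).ravel()
    xb = b.samples if isinstance(b, FCDDistribution) else np.asarray(b).ravel()
    if len(xa) == 0 or len(xb) == 0:
        raise ValueError("cannot compute a KS distance with empty samples")
    return float(sp_stats.ks_2samp(xa, xb, method="asymp").statistic)
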
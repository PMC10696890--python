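"""Structural connectome container, averaging, and log-normalization.

The coupling substrate of the network model is a non-negative, zero-diagonal
weight matrix ``C`` where ``C[i, j]`` is the input to node ``i`` from node
``j`` (so the total "node input" of node ``j``'s outputs is the column sum).
Individual-subject connectomes are combined with an arithmetic mean and the
group matrix is compressed and rescaled with a log transform so that the
maximum node input equals a fixed target (0.7 by default); the target only
redefines the scale of the global coupling parameter G, not the dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StructuralConnectome",
    "average_connectomes",
    "log_normalize",
    "read_connectome",
    "write_connectome",
]

DEFAULT_NORMALIZATION_TARGET = 0.7


@dataclass(frozen=True)
class StructuralConnectome:
    """A weighted, non-negative, zero-diagonal structural connectivity matrix.

    Parameters
    ----------
    weights : (N, N) ndarray
        Coupling weights; ``weights[i, j]`` is the input to region ``i``
        from region ``j``.
    region_ids : tuple of str
        Ordered region labels, one per row/column.
    normalized : bool
        Whether :func:`log_normalize` has been applied. Guards against
        double application, which is not idempotent.
    """

    weights: np.ndarray
    region_ids: tuple = field(default=None)
    normalized: bool = False

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got shape {w.shape}")
        if np.any(w < 0):
            raise ValueError("connectome weights must be non-negative")
        if not np.all(np.isfinite(w)):
            raise ValueError("connectome weights must be finite")
        # self-coupling is modelled by the local recurrence term, not C
        w = w.copy()
        np.fill_diagonal(w, 0.0)
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)
        if self.region_ids is None:
            object.__setattr__(
                self, "region_ids", tuple(f"R{i:03d}" for i in range(w.shape[0]))
            )
        else:
            ids = tuple(str(r) for r in self.region_ids)
            if len(ids) != w.shape[0]:
                raise ValueError(
                    f"{len(ids)} region_ids for a {w.shape[0]}-region matrix"
                )
            object.__setattr__(self, "region_ids", ids)

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    @property
    def node_strength(self) -> np.ndarray:
        """Column sums: total input each node distributes to the network."""
        return self.weights.sum(axis=0)


def average_connectomes(
    connectomes: Sequence[StructuralConnectome],
) -> StructuralConnectome:
    """Entrywise arithmetic mean of subject connectomes.

    All inputs must share the region count and ordering. The result is not
    normalized, regardless of the inputs' flags.
    """
    if len(connectomes) == 0:
        raise ValueError("cannot average an empty list of connectomes")
    first = connectomes[0]
    for sc in connectomes[1:]:
        if sc.n_regions != first.n_regions:
            raise ValueError(
                f"dimension mismatch: {sc.n_regions} vs {first.n_regions}"
            )
        if sc.region_ids != first.region_ids:
            raise ValueError("region orderings differ between connectomes")
    mean = np.mean([sc.weights for sc in connectomes], axis=0)
    return StructuralConnectome(mean, first.region_ids, normalized=False)


def log_normalize(
    sc: StructuralConnectome, target: float = DEFAULT_NORMALIZATION_TARGET
) -> StructuralConnectome:
    """Compress weights with log(C+1) and rescale the maximum node input.

    Returns ``target * log(C+1) / maxNodeInput`` where ``maxNodeInput`` is the
    largest column sum of ``log(C+1)``. After the transform the maximum node
    input is exactly ``target`` (up to floating error).
    """
    if sc.normalized:
        raise ValueError("connectome is already normalized; refusing to re-apply")
    if target <= 0:
        raise ValueError(f"normalization target must be positive, got {target}")
    lc = np.log1p(sc.weights)
    max_node_input = lc.sum(axis=0).max()
    if max_node_input == 0:
        raise ValueError("all-zero connectome cannot be normalized")
    return StructuralConnectome(
        target * lc / max_node_input, sc.region_ids, normalized=True
    )


def write_connectome(sc: StructuralConnectome, path, sep: str = "\t") -> None:
    """Write as delimited text with a header row of region labels.

    The round trip through :func:`read_connectome` is lossless to well past
    12 significant digits (``repr``-precision floats).
    """
    df = pd.DataFrame(sc.weights, columns=sc.region_ids)
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_connectome(path, sep: str | None = None, normalized: bool = False) -> StructuralConnectome:
    """Read a square delimited-text matrix (tab or comma separated).

    A header row of region labels is used when present; a purely numeric
    first row is treated as data.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if sep is None:
        sep = "\t" if "\t" in first else ","
    tokens = [t for t in first.replace(",", "\t").strip().split("\t") if t]

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    header = 0 if not all(_numeric(t) for t in tokens) else None
    # float_precision="round_trip" keeps write -> read lossless to the bit
    df = pd.read_csv(path, sep=sep, header=header,
                     float_precision="round_trip")
    region_ids = tuple(df.columns.astype(str)) if header == 0 else None
    return StructuralConnectome(df.to_numpy(dtype=float), region_ids, normalized=normalized)
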
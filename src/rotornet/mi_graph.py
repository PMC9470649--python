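"""Pairwise mutual information between electrode signals and thresholded
functional-connectivity graphs.

Mutual information between two binary sequences is the plug-in (maximum
likelihood) estimate from their 2x2 joint histogram,

    I(X;Y) = sum_{a,b} p(a,b) ln( p(a,b) / (p(a) p(b)) ),   0 ln(.) = 0,

which is identical to the sample-average form (1/N) sum_i ln p(x_i,y_i) /
(p(x_i) p(y_i)).  Units are nats; for binary signals the two fixed-width
histogram bins make the estimator exact, so no binning parameter is
exposed.  The diagonal of the pairwise matrix is each signal's empirical
entropy (I(X;X) = H(X)).

An *information threshold* of q percent converts the matrix to a binary
adjacency graph keeping the top ceil(q/100 * P) most-informative of the
P = 48*47/2 = 1128 candidate electrode pairs; larger q means a denser
graph.  Ties at the cutoff are broken by ascending (i, j) lexicographic
pair order, which makes the edge sets nested across thresholds and every
graph reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

__all__ = [
    "MIMatrix",
    "Adjacency",
    "mutual_information",
    "mi_matrix",
    "adjacency_at_fraction",
    "write_mi_csv",
    "write_edge_list",
]


@dataclass(frozen=True)
class MIMatrix:
    """Symmetric pairwise mutual-information matrix in nats."""

    values: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("MI matrix must be square")
        if not np.array_equal(v, v.T):
            raise ValueError("MI matrix must be symmetric")
        if (v < 0).any():
            raise ValueError("MI values must be non-negative")
        object.__setattr__(self, "values", v)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class Adjacency:
    """Thresholded binary graph: symmetric, no self-loops."""

    matrix: np.ndarray
    edge_fraction_q: float
    n_edges: int

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.dtype != np.bool_:
            m = m.astype(bool)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(m, m.T):
            raise ValueError("adjacency must be symmetric")
        if np.diagonal(m).any():
            raise ValueError("adjacency must have a zero diagonal")
        object.__setattr__(self, "matrix", m)

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


def _mi_from_counts(
    n00: np.ndarray, n01: np.ndarray, n10: np.ndarray, n11: np.ndarray
) -> np.ndarray:
    """Plug-in MI (nats) from 2x2 joint counts; vectorized; 0 ln 0 = 0."""
    n00, n01, n10, n11 = (np.asarray(a, dtype=float) for a in (n00, n01, n10, n11))
    total = n00 + n01 + n10 + n11
    px1 = (n10 + n11) / total
    py1 = (n01 + n11) / total
    px0, py0 = 1.0 - px1, 1.0 - py1
    out = np.zeros_like(total, dtype=float)
    for njoint, pa, pb in (
        (n00, px0, py0),
        (n01, px0, py1),
        (n10, px1, py0),
        (n11, px1, py1),
    ):
        pj = njoint / total
        with np.errstate(divide="ignore", invalid="ignore"):
            term = pj * np.log(pj / (pa * pb))
        out += np.where(njoint > 0, term, 0.0)
    return np.maximum(out, 0.0)


def _as_binary(x: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(x)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D sequence")
    if arr.dtype != np.bool_ and not np.all(np.isin(np.unique(arr), (0, 1))):
        raise ValueError(f"{name} must be binary")
    return arr.astype(bool)


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information (nats) between two binary sequences."""
    xb = _as_binary(x, "x")
    yb = _as_binary(y, "y")
    if xb.shape != yb.shape:
        raise ValueError(f"length mismatch: {xb.size} vs {yb.size}")
    counts = np.bincount(2 * xb.astype(np.intp) + yb, minlength=4)
    return float(_mi_from_counts(counts[0], counts[1], counts[2], counts[3]))


def mi_matrix(signals) -> MIMatrix:
    """Pairwise MI matrix of an electrode signal set (or raw 2-D binary array).

    Diagonal entries are the per-signal entropies.  Entries are computed for
    i <= j and mirrored, so the matrix is exactly symmetric.
    """
    sig = signals.signals if hasattr(signals, "signals") else np.asarray(signals)
    if sig.ndim != 2:
        raise ValueError("signals must be 2-D (electrodes x frames)")
    if sig.dtype != np.bool_:
        if not np.all(np.isin(np.unique(sig), (0, 1))):
            raise ValueError("signals must be binary")
        sig = sig.astype(bool)
    t = sig.shape[1]
    if t < 1:
        raise ValueError("signals must have at least one frame")
    x = sig.astype(np.float64)
    n11 = x @ x.T
    ones = x.sum(axis=1)
    n10 = ones[:, None] - n11
    n01 = ones[None, :] - n11
    n00 = t - n11 - n10 - n01
    values = _mi_from_counts(n00, n01, n10, n11)
    iu = np.triu_indices(values.shape[0])
    sym = np.zeros_like(values)
    sym[iu] = values[iu]
    sym = sym + np.triu(sym, 1).T
    return MIMatrix(values=sym, n_samples=t)


def _ranked_pairs(mi: MIMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Off-diagonal pairs in MI-descending order, ties by (i, j) lex order."""
    iu, ju = np.triu_indices(mi.n_nodes, k=1)
    vals = mi.values[iu, ju]
    order = np.argsort(-vals, kind="stable")  # stable: lex order within ties
    return iu[order], ju[order], vals[order]


def adjacency_at_fraction(mi: MIMatrix, q: float) -> Adjacency:
    """Binary graph keeping the top ceil(q/100 * P) most-informative pairs."""
    if not 0 < q <= 100:
        raise ValueError("edge fraction q must be in (0, 100]")
    n = mi.n_nodes
    n_pairs = comb(n, 2)
    k = int(np.ceil(q / 100.0 * n_pairs))
    i_sorted, j_sorted, _ = _ranked_pairs(mi)
    mat = np.zeros((n, n), dtype=bool)
    mat[i_sorted[:k], j_sorted[:k]] = True
    mat |= mat.T
    return Adjacency(matrix=mat, edge_fraction_q=float(q), n_edges=k)


def write_mi_csv(mi: MIMatrix, path) -> None:
    pd.DataFrame(mi.values).to_csv(path, index=False, header=False)


def write_edge_list(mi_or_adj, path) -> None:
    """Rank-sorted edge list CSV: (i, j, mi) for an MIMatrix, (i, j) for an
    Adjacency."""
    if isinstance(mi_or_adj, MIMatrix):
        i, j, v = _ranked_pairs(mi_or_adj)
        df = pd.DataFrame({"i": i, "j": j, "mi": v})
    else:
        i, j = np.nonzero(np.triu(mi_or_adj.matrix, 1))
        df = pd.DataFrame({"i": i, "j": j})
    df.to_csv(path, index=False)
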
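"""Local efficiency, its threshold sweep, cubic fit and window derivative.

Local efficiency (Latora–Marchiori) at node i measures fault tolerance: how
well i's neighbours communicate when i is removed.  With G_i the set of
neighbours of i and L_{j,k} the unweighted shortest-path length between j
and k inside the subgraph induced by G_i (i excluded),

    E_local(i) = 1 / (|G_i| (|G_i| - 1)) * sum_{j != k in G_i} 1 / L_{j,k},

with 1/inf = 0 for disconnected pairs and E_local(i) = 0 when |G_i| < 2.
The graph summary is the plain mean over all nodes (isolated and
low-degree nodes contribute 0 rather than being dropped, keeping the
normalization fixed across thresholds).

Sweeping the edge-fraction threshold q gives mean local efficiency as a
function of graph density.  A third-degree polynomial is least-squares
fitted to the full curve and the discriminating statistic is the average of
its analytic first derivative over a threshold window — equal to
(P(hi) - P(lo)) / (hi - lo) by the fundamental theorem of calculus.  A flat
(plateaued) curve in the window, i.e. a small derivative, is the signature
of rotational activation: adding weakly informative connections to a
rotor's network barely improves its fault tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .mi_graph import Adjacency, MIMatrix, adjacency_at_fraction

__all__ = [
    "EfficiencyCurve",
    "DerivativeSummary",
    "local_efficiency",
    "efficiency_curve",
    "window_derivative",
    "default_q_grid",
]


def default_q_grid() -> np.ndarray:
    """Edge-fraction grid used for the threshold sweep: 2 to 100 % step 2."""
    return np.arange(2.0, 100.0 + 1e-9, 2.0)


@dataclass(frozen=True)
class EfficiencyCurve:
    """Mean local efficiency vs edge-fraction threshold with its cubic fit."""

    q_grid: np.ndarray
    mean_local_efficiency: np.ndarray
    poly: np.polynomial.Polynomial
    fit_residual: float

    def __post_init__(self) -> None:
        q = np.asarray(self.q_grid, dtype=float)
        e = np.asarray(self.mean_local_efficiency, dtype=float)
        if q.size != e.size or q.size < 8:
            raise ValueError("q_grid and efficiencies must match, length >= 8")
        if ((e < -1e-12) | (e > 1 + 1e-12)).any():
            raise ValueError("efficiency values must lie in [0, 1]")
        object.__setattr__(self, "q_grid", q)
        object.__setattr__(self, "mean_local_efficiency", e)

    @property
    def poly_coeffs(self) -> np.ndarray:
        """Cubic coefficients in ascending powers of q (unscaled domain)."""
        return self.poly.convert().coef


@dataclass(frozen=True)
class DerivativeSummary:
    """Average fitted-curve derivative over a threshold window for one
    catheter position."""

    window: tuple[float, float]
    mean_derivative: float
    group: str = ""
    position_id: int = -1
    degenerate: bool = False


def local_efficiency(adj: Adjacency | np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node local efficiency and its mean over all nodes."""
    a = adj.matrix if isinstance(adj, Adjacency) else np.asarray(adj)
    if a.dtype != np.bool_:
        a = a.astype(bool)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if np.diagonal(a).any():
        raise ValueError("adjacency must not contain self-loops")
    n = a.shape[0]
    eff = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        k = nbrs.size
        if k < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        dist = shortest_path(csr_matrix(sub), method="D", unweighted=True)
        with np.errstate(divide="ignore"):
            inv = 1.0 / dist
        inv[~np.isfinite(inv)] = 0.0
        np.fill_diagonal(inv, 0.0)
        eff[i] = inv.sum() / (k * (k - 1))
    return eff, float(eff.mean())


def efficiency_curve(mi: MIMatrix, q_grid: np.ndarray | None = None) -> EfficiencyCurve:
    """Mean local efficiency at each threshold of ``q_grid`` plus a cubic
    least-squares fit over the full grid."""
    q = default_q_grid() if q_grid is None else np.asarray(q_grid, dtype=float)
    if q.size < 8:
        raise ValueError("q_grid must contain at least 8 thresholds")
    if (np.diff(q) <= 0).any() or q[0] <= 0 or q[-1] > 100:
        raise ValueError("q_grid must be strictly increasing within (0, 100]")
    effs = np.empty_like(q)
    for idx, qi in enumerate(q):
        _, effs[idx] = local_efficiency(adjacency_at_fraction(mi, qi))
    poly = np.polynomial.Polynomial.fit(q, effs, deg=3)
    residual = float(np.sqrt(np.mean((poly(q) - effs) ** 2)))
    return EfficiencyCurve(
        q_grid=q, mean_local_efficiency=effs, poly=poly, fit_residual=residual
    )


def window_derivative(
    curve: EfficiencyCurve, window: tuple[float, float] = (40.0, 80.0)
) -> float:
    """Mean of the fitted cubic's first derivative over ``window``.

    By the fundamental theorem of calculus this equals
    (P(hi) - P(lo)) / (hi - lo) for the fitted polynomial P.
    """
    lo, hi = float(window[0]), float(window[1])
    if not lo < hi:
        raise ValueError("window must satisfy lo < hi")
    if lo < curve.q_grid[0] - 1e-9 or hi > curve.q_grid[-1] + 1e-9:
        raise ValueError("window must lie within the q_grid span")
    p = curve.poly
    return float((p(hi) - p(lo)) / (hi - lo))
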
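"""Weighted graph metrics for structural connectomes.

The four whole-brain characteristics of interest are

* **graph strength** — per-node sum of adjacent edge weights (physical wiring
  cost); reported globally as the mean over nodes so that the scale is
  comparable across parcellations of different size,
* **characteristic path length** — mean shortest-path distance over node
  pairs, where the length of an edge with weight ``w`` is ``1/w`` (strong
  connections are short),
* **global efficiency** — mean inverse shortest-path distance (ease of
  parallel communication; unreachable pairs contribute zero),
* **weighted transitivity** — ratio of the total geometric-mean triangle
  intensity to the number of connected triples, with weights normalized by
  the maximum weight (Onnela-style), a global variant of the clustering
  coefficient; its node-level analogue is the weighted clustering
  coefficient.

Everything here is computed from first principles on dense numpy arrays —
no graph library sits in the computational path.  Library implementations
(scipy's all-pairs solvers, brute-force triangle enumeration) serve as
independent oracles in the test suite only.

The transitivity variant is isolated in :func:`weighted_clustering` so that
alternative triangle intensities (e.g. arithmetic-mean/Barrat) could be
swapped in without touching callers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectome import ConnectivityMatrix

__all__ = [
    "MetricSet",
    "NodeMetrics",
    "node_strength",
    "shortest_paths",
    "characteristic_path_length",
    "global_efficiency",
    "weighted_clustering",
    "compute_metrics",
]


@dataclass(frozen=True)
class MetricSet:
    """The four whole-brain network characteristics of one subject."""

    strength_global: float
    char_path_length: float
    global_efficiency: float
    weighted_transitivity: float
    connected: bool


@dataclass(frozen=True)
class NodeMetrics:
    """Per-node measures: strength, degree, triangle intensity, clustering."""

    strength: np.ndarray
    degree: np.ndarray
    triangle_intensity: np.ndarray
    clustering: np.ndarray


def _as_weights(c: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    if isinstance(c, ConnectivityMatrix):
        return c.weights
    w = np.asarray(c, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("expected a square weight matrix")
    return w


def node_strength(c: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Per-node sum of adjacent edge weights, ``s_i = sum_j C[i, j]``."""
    return _as_weights(c).sum(axis=1)


def shortest_paths(c: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances with edge length ``1/weight``.

    Dijkstra's algorithm run from every source on the dense matrix.
    ``D[i, i] = 0``; unreachable pairs are ``+inf``.  Disconnection is a
    state, not an error — callers inspect finiteness.
    """
    w = _as_weights(c)
    r = w.shape[0]
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / w, np.inf)
    np.fill_diagonal(lengths, np.inf)  # no self-loops
    dist = np.full((r, r), np.inf)
    for s in range(r):
        d = np.full(r, np.inf)
        d[s] = 0.0
        unvisited = np.ones(r, dtype=bool)
        for _ in range(r):
            masked = np.where(unvisited, d, np.inf)
            u = int(np.argmin(masked))
            if not np.isfinite(masked[u]):
                break
            unvisited[u] = False
            cand = d[u] + lengths[u]
            improve = unvisited & (cand < d)
            d[improve] = cand[improve]
        dist[s] = d
    np.fill_diagonal(dist, 0.0)
    return dist


def _offdiag(d: np.ndarray) -> np.ndarray:
    r = d.shape[0]
    mask = ~np.eye(r, dtype=bool)
    return d[mask]


def characteristic_path_length(d: np.ndarray) -> tuple[float, bool]:
    """Mean shortest-path distance over finite ordered pairs.

    Returns ``(L, connected)``; ``connected`` is False when any off-diagonal
    distance is infinite (those pairs are excluded from the mean).  Raises
    when *no* pair is reachable, in which case the mean is undefined.
    """
    vals = _offdiag(np.asarray(d, dtype=float))
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("characteristic path length undefined: no reachable pairs")
    return float(vals[finite].mean()), bool(finite.all())


def global_efficiency(d: np.ndarray) -> float:
    """Mean inverse shortest-path distance over ordered pairs (1/inf = 0)."""
    vals = _offdiag(np.asarray(d, dtype=float))
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(vals) & (vals > 0), 1.0 / vals, 0.0)
    return float(inv.mean())


def weighted_clustering(
    c: ConnectivityMatrix | np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Weighted triangle intensity, degree, clustering and global transitivity.

    With weights normalized by the maximum, ``w_hat = C / max(C)``, the
    triangle intensity of node *i* is the geometric-mean weight of all
    triangles through it,

        ``t_i = 1/2 * sum_{j,h} (w_hat_ij * w_hat_ih * w_hat_jh)^(1/3)``,

    the local clustering coefficient is ``C_i = 2 t_i / (k_i (k_i - 1))``
    (zero when the degree ``k_i < 2``), and the global weighted transitivity
    is ``T = sum_i 2 t_i / sum_i k_i (k_i - 1)``.

    Returns ``(t, k, C_local, T)``.
    """
    w = _as_weights(c)
    wmax = w.max()
    if wmax <= 0:
        raise ValueError("weighted transitivity undefined for an all-zero matrix")
    w_hat = w / wmax
    w3 = np.cbrt(w_hat)
    t = np.einsum("ij,jh,hi->i", w3, w3, w3) / 2.0
    k = (w > 0).sum(axis=1).astype(float)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c_local = np.where(denom > 0, 2.0 * t / np.where(denom > 0, denom, 1.0), 0.0)
    total_triples = denom.sum()
    transitivity = float(2.0 * t.sum() / total_triples) if total_triples > 0 else 0.0
    return t, k, c_local, transitivity


def compute_metrics(
    c: ConnectivityMatrix | np.ndarray,
) -> tuple[MetricSet, NodeMetrics]:
    """All global and node-level measures of a single connectivity matrix."""
    s = node_strength(c)
    d = shortest_paths(c)
    cpl, connected = characteristic_path_length(d)
    eff = global_efficiency(d)
    t, k, c_local, transitivity = weighted_clustering(c)
    metric_set = MetricSet(
        strength_global=float(s.mean()),
        char_path_length=cpl,
        global_efficiency=eff,
        weighted_transitivity=transitivity,
        connected=connected,
    )
    node_metrics = NodeMetrics(
        strength=s, degree=k.astype(int), triangle_intensity=t, clustering=c_local
    )
    return metric_set, node_metrics
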
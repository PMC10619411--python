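"""Construction of weighted structural connectivity matrices.

A subject's probabilistic tractography run yields, for every ordered pair of
parcellated brain regions (nodes), the number of sample streamlines seeded in
region *i* that reached region *j*, together with the per-seed total of valid
streamlines (the ``waytotal``).  Dividing counts by waytotals gives a directed
connection-probability matrix; averaging the two directions gives the
symmetric weighted connectivity matrix used for all network analyses.

Spurious connections are removed with a population-level criterion: an edge
is excluded in *all* subjects when its across-subject mean plus ``k_sd``
standard deviations falls below a probability threshold ``theta`` (default
0.01).  Thresholding at the population level keeps the retained edge set
identical across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "StreamlineTally",
    "ConnectivityMatrix",
    "PopulationMask",
    "tally_to_probability",
    "symmetrize",
    "build_population_mask",
    "apply_mask",
    "write_matrix",
    "read_matrix",
]

_SYMMETRY_ATOL = 1e-10


@dataclass
class StreamlineTally:
    """Directed streamline counts for one subject.

    ``counts[i, j]`` is the number of streamlines seeded in node ``i`` that
    reached node ``j``; the diagonal is ignored (self-connections are not
    tractography targets) and forced to zero.  ``waytotal[i]`` is the number
    of valid streamlines drawn from seed ``i`` and bounds every entry of row
    ``i``.
    """

    counts: np.ndarray
    waytotal: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.waytotal = np.asarray(self.waytotal)
        c = self.counts
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError(f"counts must be a square matrix, got shape {c.shape}")
        r = c.shape[0]
        if r < 3:
            raise ValueError(f"need at least 3 nodes, got {r}")
        if self.waytotal.shape != (r,):
            raise ValueError(
                f"waytotal must have length {r}, got shape {self.waytotal.shape}"
            )
        if np.any(c < 0):
            raise ValueError("streamline counts must be non-negative")
        if np.any(self.waytotal < 1):
            bad = int(np.argmax(self.waytotal < 1))
            raise ValueError(f"waytotal must be >= 1 for every seed; node {bad} violates")
        c = c.copy()
        np.fill_diagonal(c, 0)
        over = c > self.waytotal[:, None]
        if np.any(over):
            i, j = np.argwhere(over)[0]
            raise ValueError(
                f"counts[{i}, {j}]={c[i, j]} exceeds waytotal[{i}]={self.waytotal[i]}"
            )
        self.counts = c

    @property
    def n_nodes(self) -> int:
        return self.counts.shape[0]


@dataclass
class ConnectivityMatrix:
    """Symmetric weighted connectivity matrix with weights in [0, 1]."""

    weights: np.ndarray
    node_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got shape {w.shape}")
        if not np.allclose(w, w.T, atol=_SYMMETRY_ATOL):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.abs(np.diag(w)) > _SYMMETRY_ATOL):
            raise ValueError("connectivity matrix must have a zero diagonal")
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("connection weights must lie in [0, 1]")
        w = (w + w.T) / 2.0  # remove floating asymmetry exactly
        np.fill_diagonal(w, 0.0)
        self.weights = w
        if self.node_labels is not None:
            self.node_labels = tuple(self.node_labels)
            if len(self.node_labels) != w.shape[0]:
                raise ValueError("node_labels length does not match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class PopulationMask:
    """Boolean edge-retention mask shared by every subject in a cohort."""

    keep: np.ndarray
    threshold: float = 0.01
    k_sd: float = 2.0

    def __post_init__(self) -> None:
        k = np.asarray(self.keep, dtype=bool)
        if k.ndim != 2 or k.shape[0] != k.shape[1]:
            raise ValueError("mask must be square")
        if not np.array_equal(k, k.T):
            raise ValueError("mask must be symmetric")
        k = k.copy()
        np.fill_diagonal(k, False)
        if not k.any():
            raise ValueError("population mask retains no edges")
        self.keep = k

    @property
    def n_edges_kept(self) -> int:
        return int(self.keep.sum() // 2)

    @property
    def n_edges_total(self) -> int:
        r = self.keep.shape[0]
        return r * (r - 1) // 2


def tally_to_probability(tally: StreamlineTally) -> np.ndarray:
    """Directed connection probabilities: counts divided by the seed waytotal.

    Returns the row-normalized matrix ``P[i, j] = counts[i, j] / waytotal[i]``
    with a zero diagonal.
    """
    p = tally.counts.astype(float) / tally.waytotal[:, None].astype(float)
    np.fill_diagonal(p, 0.0)
    return p


def symmetrize(p: np.ndarray, node_labels: tuple[str, ...] | None = None) -> ConnectivityMatrix:
    """Average the two directed probabilities of each node pair.

    ``C[i, j] = (P[i, j] + P[j, i]) / 2`` — the standard undirected weight for
    probabilistic-tractography connectomes.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError(f"probability matrix must be square, got shape {p.shape}")
    c = (p + p.T) / 2.0
    np.fill_diagonal(c, 0.0)
    return ConnectivityMatrix(weights=c, node_labels=node_labels)


def build_population_mask(
    matrices: list[ConnectivityMatrix],
    threshold: float = 0.01,
    k_sd: float = 2.0,
) -> PopulationMask:
    """Flag edges whose population distribution sits below the threshold.

    Edge (i, j) is *excluded* when ``mean_s(C_ij) + k_sd * sd_s(C_ij)``
    (sample standard deviation, ddof=1) is strictly below ``threshold``; it is
    retained otherwise, so an edge sitting exactly at the threshold is kept.
    """
    if len(matrices) < 2:
        raise ValueError("population mask needs at least 2 subjects")
    shapes = {m.n_nodes for m in matrices}
    if len(shapes) != 1:
        raise ValueError(f"matrix dimensions differ across subjects: {sorted(shapes)}")
    stack = np.stack([m.weights for m in matrices])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    keep = (mean + k_sd * sd) >= threshold
    np.fill_diagonal(keep, False)
    keep &= keep.T  # symmetric by construction, but be explicit
    return PopulationMask(keep=keep, threshold=threshold, k_sd=k_sd)


def apply_mask(c: ConnectivityMatrix, mask: PopulationMask) -> ConnectivityMatrix:
    """Zero out masked edges; retained edges are untouched."""
    if mask.keep.shape != c.weights.shape:
        raise ValueError(
            f"mask shape {mask.keep.shape} does not match matrix shape {c.weights.shape}"
        )
    w = np.where(mask.keep, c.weights, 0.0)
    return ConnectivityMatrix(weights=w, node_labels=c.node_labels)


def write_matrix(path: str | Path, matrix: np.ndarray, fmt: str = "%.10g") -> None:
    np.savetxt(path, np.asarray(matrix), fmt=fmt, delimiter="\t")


def read_matrix(path: str | Path) -> np.ndarray:
    path = Path(path)
    try:
        m = np.loadtxt(path, delimiter=None, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"malformed matrix file {path.name}: {exc}") from exc
    if m.shape[0] != m.shape[1]:
        raise ValueError(
            f"matrix file {path.name} is not square (shape {m.shape}); file may be truncated"
        )
    return m
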
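"""Electrode montages: 3-D positions on the scalp sphere and an adjacency graph.

The montage is the geometric substrate for spherical-spline interpolation,
for the spatially smooth noise model of the synthetic generator, and for the
"n adjacent electrodes" spatial-extent criterion of the mass-univariate
statistics. Positions are unit vectors in a head-centred frame; adjacency is
built by Delaunay triangulation with an edge-length cap so that rim
electrodes are not connected straight across the head.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = ["Montage", "make_hemisphere_montage", "read_montage", "write_montage"]


@dataclass(frozen=True)
class Montage:
    """Electrode identities, unit-sphere positions and neighbour graph.

    Parameters
    ----------
    labels : list of str
        Electrode names, one per channel.
    positions : ndarray, shape (n, 3)
        Unit vectors in a head-centred frame (x right, y front, z up).
    adjacency : scipy.sparse.csr_matrix, shape (n, n), bool
        Symmetric, irreflexive neighbour graph.
    """

    labels: tuple[str, ...]
    positions: np.ndarray
    adjacency: csr_matrix = field(repr=False)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must have shape (n, 3)")
        if len(self.labels) != pos.shape[0]:
            raise ValueError("labels and positions disagree on channel count")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("positions must be unit vectors (|pos| = 1 within 1e-6)")
        adj = self.adjacency
        if adj.shape != (len(self.labels),) * 2:
            raise ValueError("adjacency shape does not match channel count")
        if (adj != adj.T).nnz != 0:
            raise ValueError("adjacency must be symmetric")
        if adj.diagonal().any():
            raise ValueError("adjacency must be irreflexive")
        n_comp, _ = connected_components(adj, directed=False)
        if n_comp != 1:
            raise ValueError("adjacency graph must be connected")
        object.__setattr__(self, "positions", pos)

    @property
    def n_electrodes(self) -> int:
        return len(self.labels)

    def neighbors(self, index: int) -> np.ndarray:
        """Indices of electrodes adjacent to ``index``."""
        return self.adjacency.indices[
            self.adjacency.indptr[index] : self.adjacency.indptr[index + 1]
        ]

    def index(self, label: str) -> int:
        return self.labels.index(label)


def _fibonacci_hemisphere(n: int, z_min: float) -> np.ndarray:
    # Fibonacci lattice restricted to the upper cap z in [z_min, 1]; gives a
    # quasi-uniform electrode layout at any channel count.
    i = np.arange(n)
    z = z_min + (1.0 - z_min) * (i + 0.5) / n
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    theta = 2.0 * np.pi * i / golden
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _delaunay_adjacency(pos: np.ndarray, edge_cap_factor: float = 1.9) -> csr_matrix:
    """Neighbour graph from a stereographic Delaunay triangulation.

    Points are projected from the south pole onto the z = 0 plane (the cap
    never contains the pole), triangulated in 2-D, and triangle edges become
    graph edges. Edges longer than ``edge_cap_factor`` times the median edge
    chord length are dropped, which removes the spurious long rim edges the
    projection can create.
    """
    n = pos.shape[0]
    proj = pos[:, :2] / (1.0 + pos[:, 2])[:, None]
    tri = Delaunay(proj)
    edges = set()
    for simplex in tri.simplices:
        for a, b in ((0, 1), (1, 2), (0, 2)):
            i, j = sorted((simplex[a], simplex[b]))
            edges.add((i, j))
    edges = np.array(sorted(edges))
    lengths = np.linalg.norm(pos[edges[:, 0]] - pos[edges[:, 1]], axis=1)
    cap = edge_cap_factor * np.median(lengths)
    kept = edges[lengths <= cap]
    rows = np.concatenate([kept[:, 0], kept[:, 1]])
    cols = np.concatenate([kept[:, 1], kept[:, 0]])
    adj = csr_matrix(
        (np.ones(rows.size, dtype=bool), (rows, cols)), shape=(n, n), dtype=bool
    )
    # if the cap disconnected the graph, relax it until connected
    while connected_components(adj, directed=False)[0] > 1:
        cap *= 1.1
        kept = edges[lengths <= cap]
        rows = np.concatenate([kept[:, 0], kept[:, 1]])
        cols = np.concatenate([kept[:, 1], kept[:, 0]])
        adj = csr_matrix(
            (np.ones(rows.size, dtype=bool), (rows, cols)), shape=(n, n), dtype=bool
        )
    return adj


def make_hemisphere_montage(n_electrodes: int, z_min: float = -0.2) -> Montage:
    """Quasi-uniform synthetic cap montage with ``n_electrodes`` channels.

    Electrodes cover the upper sphere down to ``z_min`` (slightly below the
    equator, as real high-density caps do).
    """
    if n_electrodes < 4:
        raise ValueError("a montage needs at least 4 electrodes")
    pos = _fibonacci_hemisphere(n_electrodes, z_min)
    labels = tuple(f"E{i + 1}" for i in range(n_electrodes))
    return Montage(labels, pos, _delaunay_adjacency(pos))


def write_montage(montage: Montage, path) -> None:
    """Write a plain-text electrode file: ``label x y z`` per line."""
    with open(path, "w") as fh:
        for lab, p in zip(montage.labels, montage.positions):
            fh.write(f"{lab} {p[0]:.9f} {p[1]:.9f} {p[2]:.9f}\n")


def read_montage(path) -> Montage:
    """Read a plain-text electrode position file (label, x, y, z per line)."""
    labels, rows = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:4]])
    pos = np.asarray(rows)
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return Montage(tuple(labels), pos, _delaunay_adjacency(pos))
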
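"""Per-cell pathway activity via random walk with restart.

Cells and genes are pooled into one nearest-neighbor graph on their MCA
coordinates; a random walk restarting at the pathway's genes diffuses
relevance over the graph, and the stationary scores restricted to cells
(renormalized to sum 1) are the pathway activity levels (PAL).  Cells
are split into pathway-positive/negative groups at the antimode of the
PAL distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)


@dataclass
class CellGeneGraph:
    """Undirected simple kNN graph over pooled cell and gene nodes."""

    adjacency: scipy.sparse.csr_matrix  # (K+M) x (K+M), 0/1, symmetric
    node_ids: list[str]
    is_cell: np.ndarray  # bool per node
    k_neighbors: int

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def node_index(self, ids) -> np.ndarray:
        lookup = {n: i for i, n in enumerate(self.node_ids)}
        return np.array([lookup[i] for i in ids if i in lookup], dtype=int)


@dataclass
class PALVector:
    set_name: str
    cell_ids: list[str]
    scores: np.ndarray  # length K, non-negative, sums to 1


@dataclass
class BinaryLabels:
    antimode: float
    labels: np.ndarray  # bool per cell, True = positive
    cell_ids: list[str]


def build_graph(embedding, k: int = 300) -> CellGeneGraph:
    """k-nearest-neighbor graph over cells and genes pooled.

    Each node connects to its ``k`` nearest Euclidean neighbors in the
    MCA space; edges are symmetrized by union and deduplicated.  Ties in
    distance are broken by node index.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    coords = np.vstack([embedding.cell_coords, embedding.gene_coords])
    n = coords.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of nodes")
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="brute").fit(coords)
    _, idx = nn.kneighbors(coords)
    rows = np.repeat(np.arange(n), k + 1)
    cols = idx.ravel()
    keep = rows != cols  # drop self-loops
    rows, cols = rows[keep], cols[keep]
    # each node keeps at most k neighbors (self removed from its own list)
    order = np.argsort(rows, kind="stable")
    rows, cols = rows[order], cols[order]
    counts = np.bincount(rows, minlength=n)
    trim = np.concatenate(
        [np.arange(c)[:k] + off for c, off in zip(counts, np.cumsum(counts) - counts)]
    )
    rows, cols = rows[trim], cols[trim]
    A = scipy.sparse.coo_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(n, n)
    ).tocsr()
    A = A.maximum(A.T)  # union symmetrization
    A.data[:] = 1.0  # simple graph: no multi-edges
    node_ids = list(embedding.cell_ids) + list(embedding.gene_ids)
    is_cell = np.zeros(n, dtype=bool)
    is_cell[: len(embedding.cell_ids)] = True
    return CellGeneGraph(adjacency=A, node_ids=node_ids, is_cell=is_cell, k_neighbors=k)


def _transition_matrix(graph: CellGeneGraph) -> scipy.sparse.csr_matrix:
    """Symmetric degree normalization T = D^{-1/2} A D^{-1/2}."""
    deg = np.asarray(graph.adjacency.sum(axis=1)).ravel()
    inv_sqrt = np.zeros_like(deg)
    nz = deg > 0
    inv_sqrt[nz] = 1.0 / np.sqrt(deg[nz])
    D = scipy.sparse.diags(inv_sqrt)
    return D @ graph.adjacency @ D


def random_walk_restart(
    graph: CellGeneGraph,
    seeds,
    restart: float = 0.75,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> np.ndarray:
    """Propagate seed relevance over the graph.

    Iterates h <- (1 - r) T h + r s with T the symmetric degree-normalized
    adjacency and s uniform over the retained seed nodes, until the L1
    change between consecutive states is < tol.  The iteration converges
    to the resolvent fixed point r (I - (1 - r) T)^{-1} s; its overall
    scale is immaterial downstream because PAL renormalizes over cells.
    """
    if not 0 < restart <= 1:
        raise ValueError("restart must be in (0, 1]")
    seed_idx = graph.node_index(seeds)
    n_dropped = len(list(seeds)) - seed_idx.size
    if n_dropped:
        logger.warning("%d seed(s) not present in the graph were dropped", n_dropped)
    if seed_idx.size == 0:
        raise ValueError("no seed is present in the graph")
    deg = np.asarray(graph.adjacency.sum(axis=1)).ravel()
    if np.any(deg[seed_idx] == 0):
        logger.warning("isolated seed node(s): their mass stays local")

    s = np.zeros(graph.n_nodes)
    s[seed_idx] = 1.0 / seed_idx.size
    if restart == 1.0:
        return s
    T = _transition_matrix(graph)
    h = s.copy()
    for it in range(max_iter):
        h_new = (1.0 - restart) * (T @ h) + restart * s
        delta = np.abs(h_new - h).sum()
        h = h_new
        if delta < tol:
            logger.debug("RWR converged after %d iterations", it + 1)
            break
    else:
        logger.warning("RWR did not reach tol=%g in %d iterations", tol, max_iter)
    return h


def compute_pal(
    graph: CellGeneGraph, gene_set, set_name: str = "", restart: float = 0.75,
    tol: float = 1e-6,
) -> PALVector:
    """PAL: the RWR vector restricted to cell nodes, renormalized to 1."""
    h = random_walk_restart(graph, gene_set, restart=restart, tol=tol)
    w = h[graph.is_cell]
    total = w.sum()
    if total == 0:
        raise ValueError("no probability mass reached any cell node")
    cell_ids = [n for n, c in zip(graph.node_ids, graph.is_cell) if c]
    return PALVector(set_name=set_name, cell_ids=cell_ids, scores=w / total)


def _kde_1d(x: np.ndarray, grid: np.ndarray, bw: float) -> np.ndarray:
    d = (grid[:, None] - x[None, :]) / bw
    return np.exp(-0.5 * d**2).sum(axis=1) / (x.size * bw * np.sqrt(2 * np.pi))


def _count_modes(density: np.ndarray) -> int:
    # strict local maxima after collapsing plateaus
    keep = np.concatenate([[True], np.diff(density) != 0])
    d = density[keep]
    if d.size < 3:
        return 1
    interior = (d[1:-1] > d[:-2]) & (d[1:-1] > d[2:])
    n = int(interior.sum())
    if d[0] > d[1]:
        n += 1
    if d[-1] > d[-2]:
        n += 1
    return max(n, 1)


def binarize_pal(pal: PALVector, grid_size: int = 512) -> BinaryLabels:
    """Split cells at the antimode of the PAL distribution.

    A Gaussian KDE is fit with the smallest bandwidth yielding exactly
    two modes (critical-bandwidth bisection to 1e-6 relative); the
    antimode is the density minimum between the two modes and cells with
    PAL above it are labeled positive.  If no two-mode bandwidth exists
    in the search range, the midpoint of the largest gap between sorted
    scores is used instead, with a warning.
    """
    x = np.asarray(pal.scores, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("PAL is degenerate (all values equal)")
    span = x.max() - x.min()
    grid = np.linspace(x.min() - 0.1 * span, x.max() + 0.1 * span, grid_size)

    def modes_at(bw: float) -> int:
        return _count_modes(_kde_1d(x, grid, bw))

    # scan a geometric bandwidth ladder for the first (smallest) bw with
    # exactly two modes, then bisect down to the critical bandwidth
    ladder = span * np.geomspace(1e-3, 1.0, 48)
    found = None
    for lo_bw, hi_bw in zip(ladder[:-1], ladder[1:]):
        if modes_at(hi_bw) == 2:
            found = (lo_bw, hi_bw)
            break
    if found is None:
        logger.warning("no two-mode bandwidth found; falling back to largest gap")
        xs = np.sort(x)
        gaps = np.diff(xs)
        j = int(np.argmax(gaps))
        antimode = float((xs[j] + xs[j + 1]) / 2)
    else:
        lo_bw, hi_bw = found
        while (hi_bw - lo_bw) / hi_bw > 1e-6:
            mid = 0.5 * (lo_bw + hi_bw)
            if modes_at(mid) == 2:
                hi_bw = mid
            else:
                lo_bw = mid
        dens = _kde_1d(x, grid, hi_bw)
        peaks = np.where(
            np.r_[dens[0] > dens[1],
                  (dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:]),
                  dens[-1] > dens[-2]]
        )[0]
        lo_peak, hi_peak = int(peaks[0]), int(peaks[-1])
        between = dens[lo_peak : hi_peak + 1]
        antimode = float(grid[lo_peak + int(np.argmin(between))])

    labels = x > antimode
    if labels.all() or not labels.any():
        raise ValueError("binarization produced an empty class")
    return BinaryLabels(antimode=antimode, labels=labels, cell_ids=list(pal.cell_ids))
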
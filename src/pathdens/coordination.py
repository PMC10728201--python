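"""Gene-set coordination testing in the co-embedding space.

A gene set is "coordinated" when its members concentrate in a compact
region of the MCA space, i.e. they are specifically co-expressed in some
subpopulation.  The test contrasts the set's density, evaluated at grid
points, with the density of all genes via Kullback-Leibler divergence,
against a null of size-matched random gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import norm
from sklearn.cluster import kmeans_plusplus
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

EPS = 1e-12  # floor for Q before the log


@dataclass
class GridPoints:
    coords: np.ndarray  # N x D, in the scaled MCA space
    bandwidth: float

    def __post_init__(self) -> None:
        if self.coords.shape[0] < 2:
            raise ValueError("need at least 2 grid points")
        if not self.bandwidth > 0:
            raise ValueError("bandwidth must be positive")


@dataclass
class CoordinationResult:
    set_name: str
    kld: float
    log_kld: float
    null_mean: float
    null_sd: float
    z: float
    p_value: float
    p_empirical: float
    fdr: float = np.nan
    n_genes: int = 0


def scale_embedding(embedding) -> tuple[np.ndarray, np.ndarray]:
    """Z-score each MCA dimension, each point cloud by its own moments.

    Gene coordinates (principal scale, variance shrinking with the
    singular values) and cell coordinates (standard scale, unit
    weighted variance) live on very different numeric scales in the
    asymmetric co-embedding.  Standardizing each cloud separately puts
    the cell-derived grid points inside the standardized gene cloud,
    which is what the grid construction requires: grid points close to
    genes, not a bandwidth dominated by the cell-gene scale gap.
    """

    def _z(coords: np.ndarray) -> np.ndarray:
        sd = coords.std(axis=0)
        sd[sd == 0] = 1.0
        return (coords - coords.mean(axis=0)) / sd

    return _z(embedding.gene_coords), _z(embedding.cell_coords)


def balanced_kmeans(
    points: np.ndarray, n_groups: int, seed: int = 0, n_iter: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Partition points into equal-size groups (sizes differ by <= 1).

    k-means++ initialization, then repeated rounds of capacity-limited
    assignment: all (point, centroid) distances are sorted ascending and
    points claim the closest non-full centroid.
    """
    n = points.shape[0]
    if n_groups > n:
        raise ValueError("more groups than points")
    base = n // n_groups
    caps = np.full(n_groups, base)
    caps[: n % n_groups] += 1  # sizes differ by at most one

    centroids, _ = kmeans_plusplus(
        points, n_clusters=n_groups, random_state=int(seed) % (2**32)
    )
    labels = np.full(n, -1)
    for _ in range(n_iter):
        D = cdist(points, centroids)
        labels = np.full(n, -1)
        remaining = caps.copy()
        n_assigned = 0
        for flat in np.argsort(D, axis=None, kind="stable"):
            i, j = divmod(flat, n_groups)
            if labels[i] >= 0 or remaining[j] == 0:
                continue
            labels[i] = j
            remaining[j] -= 1
            n_assigned += 1
            if n_assigned == n:
                break
        new_centroids = np.stack(
            [points[labels == j].mean(axis=0) for j in range(n_groups)]
        )
        if np.allclose(new_centroids, centroids):
            centroids = new_centroids
            break
        centroids = new_centroids
    return labels, centroids


def select_grid_points(embedding, n_grid: int = 100, seed: int = 0) -> GridPoints:
    """Choose grid points as balanced-cluster centroids of the cells.

    Cells (scaled coordinates) are partitioned into ``n_grid`` equal-size
    groups; the group centroids become the grid.  The kernel bandwidth is
    the median over genes of the distance to the closest grid point.
    """
    gene_scaled, cell_scaled = scale_embedding(embedding)
    if n_grid > cell_scaled.shape[0]:
        raise ValueError("n_grid exceeds the number of cells")
    _, centroids = balanced_kmeans(cell_scaled, n_grid, seed=seed)
    bandwidth = float(np.median(cdist(gene_scaled, centroids).min(axis=1)))
    if bandwidth <= 0:
        raise ValueError("degenerate bandwidth: genes coincide with grid points")
    return GridPoints(coords=centroids, bandwidth=bandwidth)


def grid_density(points: np.ndarray, grid: GridPoints) -> np.ndarray:
    """Gaussian-kernel density of ``points`` at the grid, normalized to 1.

    density[j] = sum_i exp(-(||g_i - p_j|| / bandwidth)^2 / 2).
    """
    points = np.atleast_2d(points)
    if points.shape[0] == 0:
        raise ValueError("empty point list")
    d = cdist(points, grid.coords) / grid.bandwidth
    dens = np.exp(-0.5 * d**2).sum(axis=0)
    return dens / dens.sum()


def kl_divergence(p: np.ndarray, q: np.ndarray, eps: float = EPS) -> float:
    """Natural-log KL divergence sum_x P[x] log(P[x]/Q[x]).

    Q is floored at ``eps``; terms with P[x] = 0 contribute 0.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must have the same length")
    q = np.maximum(q, eps)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def test_coordination(
    embedding,
    sets,
    n_grid: int = 100,
    n_controls: int = 100,
    seed: int = 0,
) -> list[CoordinationResult]:
    """Test every gene set for coordination in the MCA space.

    Q is the density of all genes; P the density of the set's genes
    present in the embedding.  For each set, ``n_controls`` size-matched
    random gene sets (sampled without replacement from all embedded
    genes) form the null; z scores log KL(P||Q) against the null
    log-KL moments and p is the upper-tail normal probability.  P-values
    are Benjamini-Hochberg adjusted across the tested sets.  Control
    draws are seeded per set from (seed, set index) so adding sets does
    not perturb earlier results.
    """
    gene_scaled, _ = scale_embedding(embedding)
    grid = select_grid_points(embedding, n_grid=n_grid, seed=seed)
    Q = grid_density(gene_scaled, grid)
    n_genes = gene_scaled.shape[0]

    results: list[CoordinationResult] = []
    for idx, (name, genes) in enumerate(sets):
        present = embedding.gene_index(genes)
        if present.size < 2:
            logger.warning(
                "set %r has %d gene(s) in the embedding; skipped", name, present.size
            )
            continue
        P = grid_density(gene_scaled[present], grid)
        kld = kl_divergence(P, Q)
        log_kld = np.log(max(kld, EPS))

        rng = np.random.default_rng(np.random.SeedSequence([int(seed), idx]))
        null_klds = np.empty(n_controls)
        for ctrl in range(n_controls):
            pick = rng.choice(n_genes, size=present.size, replace=False)
            Pr = grid_density(gene_scaled[pick], grid)
            null_klds[ctrl] = kl_divergence(Pr, Q)
        log_null = np.log(np.maximum(null_klds, EPS))
        mu, sd = float(log_null.mean()), float(log_null.std(ddof=1))
        if sd == 0:
            logger.warning("null log-KLD has zero spread for set %r", name)
            z = p = np.nan
        else:
            z = (log_kld - mu) / sd
            p = float(norm.sf(z))
        p_emp = float((1 + np.sum(null_klds >= kld)) / (1 + n_controls))
        results.append(
            CoordinationResult(
                set_name=name,
                kld=kld,
                log_kld=float(log_kld),
                null_mean=mu,
                null_sd=sd,
                z=float(z),
                p_value=p,
                p_empirical=p_emp,
                n_genes=int(present.size),
            )
        )

    pvals = np.array([r.p_value for r in results], dtype=float)
    ok = ~np.isnan(pvals)
    if ok.any():
        fdr = np.full(len(results), np.nan)
        fdr[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
        for r, f in zip(results, fdr):
            r.fdr = float(f)
    return results


def results_to_records(results: list[CoordinationResult]) -> list[dict]:
    return [
        {
            "set": r.set_name,
            "n_genes": r.n_genes,
            "kld": r.kld,
            "z": r.z,
            "p": r.p_value,
            "p_empirical": r.p_empirical,
            "fdr": r.fdr,
        }
        for r in results
    ]
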
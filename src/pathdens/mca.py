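"""Co-embedding of cells and genes by multiple correspondence analysis.

Continuous expression is fuzzy-coded per gene into a membership pair
(g+, g- = 1 - g+) by min-max rescaling, the resulting K x 2M indicator
table is analyzed as a correspondence problem, and cells and genes land
in one shared low-dimensional space where cell-gene proximity reflects
mutual specificity.  Only the '+' category coordinates of genes are
retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.utils.extmath import randomized_svd

logger = logging.getLogger(__name__)

# Below this size the exact LAPACK SVD is cheap; above it a seeded
# randomized SVD (deterministic for fixed internal state) is used.
_DENSE_SVD_MAX = 512


@dataclass
class FuzzyMatrix:
    """Membership degrees g+ per cell and gene (g- = 1 - g+ implied)."""

    plus: np.ndarray  # K x M, entries in [0, 1]


@dataclass
class CoEmbedding:
    """Shared MCA coordinates for cells and genes.

    ``cell_coords`` is K x D, ``gene_coords`` M x D; rows are keyed to
    ``cell_ids`` / ``gene_ids``.  ``singular_values`` are the retained
    non-trivial singular values, non-increasing.
    """

    cell_coords: np.ndarray
    gene_coords: np.ndarray
    singular_values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    @property
    def dim(self) -> int:
        return self.cell_coords.shape[1]

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: j for j, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes if g in lookup], dtype=int)


def fuzzy_code(X) -> FuzzyMatrix:
    """Min-max rescale each gene column to [0, 1].

    plus[i, j] = (X[i, j] - min_j) / (max_j - min_j).  Constant columns
    must have been filtered upstream.
    """
    values = np.asarray(X.values if hasattr(X, "values") else X, dtype=float)
    col_min = values.min(axis=0)
    col_rng = values.max(axis=0) - col_min
    if np.any(col_rng == 0):
        raise ValueError("constant gene column reached fuzzy coding")
    return FuzzyMatrix((values - col_min) / col_rng)


def _svd(Z: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-k left singular vectors and values of Z, descending."""
    if min(Z.shape) <= _DENSE_SVD_MAX:
        U, s, _ = np.linalg.svd(Z, full_matrices=False)
        return U[:, :k], s[:k]
    U, s, _ = randomized_svd(Z, n_components=k, n_iter=7, random_state=0)
    return U, s


def run_mca(X, n_dims: int = 20) -> CoEmbedding:
    """Run MCA on a fuzzy-coded expression matrix.

    The full coded table Y = [g+ | g-] (K x 2M) is converted to relative
    frequencies R = Y / sum(Y), standardized as
    Z = D_r^{-1/2} R D_c^{-1/2} with D_r / D_c the diagonal row/column
    sums of R, and decomposed Z = U D_a V^T.  Cell coordinates are
    D_r^{-1/2} U and gene coordinates D_c^{-1/2} Z^T U, restricted to
    the '+' columns.  The trivial leading component (singular value 1,
    constant in U) is discarded before counting ``n_dims``.
    """
    if n_dims < 2:
        raise ValueError("n_dims must be >= 2")
    values = np.asarray(X.values, dtype=float)
    K, M = values.shape
    plus = fuzzy_code(X).plus
    Y = np.concatenate([plus, 1.0 - plus], axis=1)  # K x 2M
    del plus

    total = Y.sum()
    r = Y.sum(axis=1) / total  # row masses (== M / total per row, exactly)
    c = Y.sum(axis=0) / total
    # Z built in place to keep one K x 2M buffer
    Z = Y
    Z /= total
    Z /= np.sqrt(r)[:, None]
    Z /= np.sqrt(c)[None, :]

    max_rank = min(K, 2 * M) - 1
    if n_dims > max_rank:
        logger.warning(
            "n_dims=%d exceeds available rank; reduced to %d", n_dims, max_rank
        )
        n_dims = max_rank
    k = min(n_dims + 1, min(K, 2 * M))
    U, s = _svd(Z, k)

    # drop the trivial component: singular value ~= 1, constant U column
    trivial = int(np.argmax(s))
    u0 = U[:, trivial]
    if not (abs(s[trivial] - 1.0) < 1e-6 and np.ptp(u0) < 1e-6 * max(1, abs(u0[0]))):
        logger.warning("leading component does not look trivial (s=%g)", s[trivial])
    keep = [i for i in range(U.shape[1]) if i != trivial][:n_dims]
    U = U[:, keep]
    s = s[keep]
    order = np.argsort(-s)
    U, s = U[:, order], s[order]

    # sign convention: largest-magnitude entry of each U column positive
    flip = np.sign(U[np.abs(U).argmax(axis=0), np.arange(U.shape[1])])
    flip[flip == 0] = 1.0
    U *= flip

    cell_coords = U / np.sqrt(r)[:, None]
    gene_full = (Z.T @ U) / np.sqrt(c)[:, None]
    gene_coords = gene_full[:M]  # '+' category only

    return CoEmbedding(
        cell_coords=cell_coords,
        gene_coords=np.ascontiguousarray(gene_coords),
        singular_values=s,
        cell_ids=list(X.cell_ids),
        gene_ids=list(X.gene_ids),
    )
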
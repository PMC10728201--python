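"""Synthetic scRNA-seq and spatial datasets with planted ground truth.

The scRNA-seq generator plants tiered marker programs (strong / medium /
weak fold-changes) into a negative-binomial count model with uniform
Bernoulli dropout calibrated to a target sparsity, emulating the
structure relevant to benchmarking: graded marker specificity crossed
with dropout severity.  The spatial generator places cells uniformly on
the unit square and plants signal genes whose expression follows one of
four spatial modes: hotspot, hotspot with gradient, streak, gradient.
A separate helper derives perturbed gene-set variants (downsampled
markers, marker/random mixtures, fully random) used to probe the
sensitivity of the coordination test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    ExpressionMatrix,
    GeneSetCollection,
    SpatialMap,
    drop_constant_genes,
    normalize_counts,
)

logger = logging.getLogger(__name__)

SPATIAL_PATTERNS = ("hotspot", "hotspot_gradient", "streak", "gradient")

# per-pattern default cell counts of the simulated tissue sections
_PATTERN_CELLS = {
    "hotspot": 4059,
    "hotspot_gradient": 4457,
    "streak": 4457,
    "gradient": 4657,
}


@dataclass
class SyntheticDataset:
    expression: ExpressionMatrix
    true_labels: np.ndarray  # per-cell type / region label
    marker_sets: GeneSetCollection
    tiers: dict[str, str] = field(default_factory=dict)  # set name -> tier
    spatial: SpatialMap | None = None
    pattern: str | None = None


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, size_param: float):
    """Negative binomial counts via the gamma-Poisson mixture."""
    lam = rng.gamma(shape=size_param, scale=mean / size_param)
    return rng.poisson(lam)


def _thin_to_sparsity(
    rng: np.random.Generator, counts: np.ndarray, target: float
) -> np.ndarray:
    """Uniform Bernoulli dropout calibrated to the target zero fraction.

    For entry-wise thinning the realized zero fraction is
    d + (1 - d) * z0, so d = (target - z0) / (1 - z0) exactly.
    """
    z0 = float(np.mean(counts == 0))
    if z0 > target + 0.03:
        raise ValueError(
            f"infeasible sparsity target {target}: matrix already {z0:.2f} zero"
        )
    d = max(0.0, (target - z0) / (1.0 - z0))
    if d > 0:
        counts = np.where(rng.random(counts.shape) < d, 0, counts)
    return counts


def _drop_empty_cells(counts: np.ndarray, *aligned):
    """Drop cells whose library is all zero after thinning (rare, high sparsity)."""
    keep = counts.sum(axis=1) > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d cell(s) with empty libraries", n_dropped)
    return (counts[keep], *[a[keep] for a in aligned])


def simulate_scrnaseq(
    n_types: int = 3,
    cells_per_type: int = 1500,
    n_genes: int = 5000,
    markers_per_type: int = 100,
    effect_tiers: dict[str, float] | None = None,
    target_sparsity: float = 0.65,
    dispersion: float = 0.5,
    seed: int = 0,
) -> SyntheticDataset:
    """Multi-cell-type scRNA-seq with planted tiered marker programs.

    Baseline gene means are log-normal; each cell type gets
    ``markers_per_type`` marker genes per tier, multiplied by the tier's
    fold-change in their own type only.  Counts are negative binomial
    (variance mu + dispersion * mu^2), thinned to the target zero
    fraction, then library-size normalized and log1p transformed.
    """
    if effect_tiers is None:
        effect_tiers = {"strong": 4.0, "medium": 2.5, "weak": 1.5}
    n_tiers = len(effect_tiers)
    if markers_per_type * n_tiers * n_types > n_genes:
        raise ValueError("marker genes exceed the gene universe")
    rng = np.random.default_rng(seed)
    K = n_types * cells_per_type

    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    gene_ids = [f"g{j:05d}" for j in range(n_genes)]
    labels = np.repeat([f"type{t}" for t in range(n_types)], cells_per_type)

    # assign disjoint marker blocks: type-major, tier-minor
    mu = np.tile(base, (K, 1))
    marker_sets: dict[str, list[str]] = {}
    tiers: dict[str, str] = {}
    g = 0
    for t in range(n_types):
        rows = slice(t * cells_per_type, (t + 1) * cells_per_type)
        for tier, fold in effect_tiers.items():
            cols = np.arange(g, g + markers_per_type)
            mu[rows, cols[0] : cols[-1] + 1] *= fold
            name = f"type{t}.{tier}"
            marker_sets[name] = [gene_ids[j] for j in cols]
            tiers[name] = tier
            g += markers_per_type

    size_param = 1.0 / dispersion
    counts = _nb_counts(rng, mu, size_param)
    counts = _thin_to_sparsity(rng, counts, target_sparsity)
    counts, labels = _drop_empty_cells(counts, labels)

    values = normalize_counts(counts)
    values, kept_genes = drop_constant_genes(values, gene_ids)
    kept = set(kept_genes)
    for name in list(marker_sets):
        marker_sets[name] = [g for g in marker_sets[name] if g in kept]
    expr = ExpressionMatrix(
        values, [f"c{i:05d}" for i in range(values.shape[0])], kept_genes
    )
    return SyntheticDataset(
        expression=expr,
        true_labels=labels,
        marker_sets=GeneSetCollection(marker_sets),
        tiers=tiers,
    )


def derive_marker_mixes(
    markers: GeneSetCollection,
    universe,
    n_reps: int = 5,
    seed: int = 0,
) -> GeneSetCollection:
    """Perturbed variants of marker sets for sensitivity benchmarking.

    Per input set and rep: (a) ``<set>.marker`` — 80% downsample;
    (b) ``<set>.mix1`` — 40% markers + an equal count of random genes;
    (c) ``<set>.mix3`` — 20% markers + three times as many random genes;
    (d) ``<set>.random`` — fully random, size-matched to (a).  Random
    genes are drawn from the universe excluding the source set.
    """
    universe = list(universe)
    out: dict[str, list[str]] = {}
    rng = np.random.default_rng(seed)
    for name, genes in markers:
        s = len(genes)
        if s < 5:
            logger.warning("set %r has fewer than 5 genes; skipped", name)
            continue
        members = set(genes)
        pool = np.array([g for g in universe if g not in members])
        genes = np.array(genes)
        n_a = round(0.8 * s)
        n_b = round(0.4 * s)
        n_c = round(0.2 * s)
        if len(pool) < max(n_a, 3 * n_c):
            logger.warning(
                "universe too small for random variants of set %r; skipped", name
            )
            continue
        for rep in range(n_reps):
            pick = lambda arr, n: list(rng.choice(arr, size=n, replace=False))
            out[f"{name}.marker.r{rep}"] = pick(genes, n_a)
            out[f"{name}.mix1.r{rep}"] = pick(genes, n_b) + pick(pool, n_a - n_b)
            out[f"{name}.mix3.r{rep}"] = pick(genes, n_c) + pick(pool, 3 * n_c)
            out[f"{name}.random.r{rep}"] = pick(pool, n_a)
    return GeneSetCollection(out)


def _region_membership(pattern: str, xy: np.ndarray) -> np.ndarray:
    x, y = xy[:, 0], xy[:, 1]
    if pattern == "hotspot":
        return (np.hypot(x - 0.5, y - 0.5) < 0.25).astype(float)
    if pattern == "hotspot_gradient":
        return np.clip(1.0 - np.hypot(x - 0.5, y - 0.5) / 0.35, 0.0, 1.0)
    if pattern == "streak":
        return (np.abs(x - y) / np.sqrt(2) < 0.1).astype(float)
    if pattern == "gradient":
        return x.copy()
    raise ValueError(f"unknown pattern {pattern!r}")


def simulate_spatial(
    pattern: str,
    n_cells: int | None = None,
    n_positive: int = 500,
    n_negative: int = 500,
    n_noise: int = 5000,
    fold: float = 2.0,
    mean: float = 1.0,
    dispersion: float = 1.0,
    target_sparsity: float = 0.85,
    seed: int = 0,
) -> SyntheticDataset:
    """Spatial transcriptomics with a planted spatially structured program.

    Cell positions are uniform on the unit square; a pattern-specific
    region membership m in [0, 1] scales positive signal genes up by
    1 + (fold - 1) m and negative signal genes down by the additive
    complement 1 - (fold - 1) m (requires fold <= 2 with equal group
    sizes).  The complement keeps the expected library size constant
    over space, so after library normalization the noise genes carry no
    spatial structure — without it, positive genes would inflate the
    in-region library and normalization would imprint an artifactual
    (inverted) pattern on every other gene.  Counts are NB(mean,
    dispersion) thinned to the target sparsity, then normalized.
    Returned marker sets: ``positive_signal``, ``negative_signal``,
    ``noise``.
    """
    if pattern not in SPATIAL_PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}")
    if n_cells is None:
        n_cells = _PATTERN_CELLS[pattern]
    rng = np.random.default_rng(seed)
    xy = rng.random((n_cells, 2))
    m = _region_membership(pattern, xy)

    n_genes = n_positive + n_negative + n_noise
    gene_ids = [f"g{j:05d}" for j in range(n_genes)]
    excess = (fold - 1.0) * m  # per-cell positive-gene excess share
    if np.any(excess * n_positive > n_negative):
        raise ValueError("fold too large for library-share-neutral negatives")
    mu = np.full((n_cells, n_genes), mean)
    mu[:, :n_positive] *= (1.0 + excess)[:, None]
    mu[:, n_positive : n_positive + n_negative] *= np.maximum(
        1.0 - excess * n_positive / n_negative, 0.0
    )[:, None]

    counts = _nb_counts(rng, mu, dispersion)
    counts = _thin_to_sparsity(rng, counts, target_sparsity)
    counts, xy, m = _drop_empty_cells(counts, xy, m)
    values = normalize_counts(counts)
    values, kept_genes = drop_constant_genes(values, gene_ids)
    kept = set(kept_genes)

    sets = {
        "positive_signal": [g for g in gene_ids[:n_positive] if g in kept],
        "negative_signal": [
            g for g in gene_ids[n_positive : n_positive + n_negative] if g in kept
        ],
        "noise": [g for g in gene_ids[n_positive + n_negative :] if g in kept],
    }
    cell_ids = [f"c{i:05d}" for i in range(counts.shape[0])]
    labels = np.where(m > 0.5, "inside", "outside")
    return SyntheticDataset(
        expression=ExpressionMatrix(values, cell_ids, kept_genes),
        true_labels=labels,
        marker_sets=GeneSetCollection(sets),
        tiers={"positive_signal": "strong", "negative_signal": "strong"},
        spatial=SpatialMap(cell_ids, xy),
        pattern=pattern,
    )
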
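"""Readers and writers for the standard formats the tool touches.

Expression comes in as Matrix Market triplets with gene/barcode TSV
sidecars or as dense CSV/TSV; gene sets as GMT; spatial coordinates and
cluster labels as two/three-column CSV.  Internally everything is held
cells x genes with library-size-normalized, log-scale values.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

#: Common target library size used when normalizing raw counts
#: (per-cell scaling to 10,000 counts, then log1p).
SCALE_FACTOR = 10_000.0


@dataclass
class ExpressionMatrix:
    """Normalized expression, K cells (rows) x M genes (columns)."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        k, m = self.values.shape
        if k == 0 or m == 0:
            raise ValueError("empty expression matrix")
        if len(self.cell_ids) != k or len(self.gene_ids) != m:
            raise ValueError("identifier count does not match matrix shape")
        if len(set(self.cell_ids)) != k:
            raise ValueError("duplicate cell identifiers")
        if len(set(self.gene_ids)) != m:
            raise ValueError("duplicate gene identifiers")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, genes) -> np.ndarray:
        """Column indices of ``genes`` present in the matrix (input order)."""
        lookup = {g: j for j, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes if g in lookup], dtype=int)


@dataclass
class GeneSetCollection:
    """Named gene sets with GMT semantics (unique names, unique members)."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(set(genes)) != len(genes):
                raise ValueError(f"duplicate genes within set {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class SpatialMap:
    """Per-cell planar coordinates (arbitrary units)."""

    cell_ids: list[str]
    coords: np.ndarray  # K x 2

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be K x 2")
        if len(self.cell_ids) != self.coords.shape[0]:
            raise ValueError("one coordinate pair per cell required")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell identifiers")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")


def normalize_counts(values: np.ndarray, scale_factor: float = SCALE_FACTOR) -> np.ndarray:
    """Scale every cell to a common library size, then log1p.

    Mirrors the default normalization of mainstream scRNA-seq toolkits:
    ``log1p(count / library_size * scale_factor)``.
    """
    values = np.asarray(values, dtype=float)
    lib = values.sum(axis=1, keepdims=True)
    if np.any(lib == 0):
        raise ValueError("cell with zero library size cannot be normalized")
    return np.log1p(values / lib * scale_factor)


def drop_constant_genes(
    values: np.ndarray, gene_ids: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Remove gene columns with max == min (fuzzy coding divides by the range)."""
    col_min = values.min(axis=0)
    col_max = values.max(axis=0)
    keep = col_max > col_min
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d constant gene column(s)", n_dropped)
    return values[:, keep], [g for g, k in zip(gene_ids, keep) if k]


def read_expression(
    path: str,
    format: str = "csv",
    orientation: str = "cells_by_genes",
    normalize: bool = False,
) -> ExpressionMatrix:
    """Read an expression matrix from MTX (with sidecars) or dense CSV/TSV.

    Parameters
    ----------
    path
        The matrix file.  For ``format="mtx"`` the directory must also
        contain ``genes.tsv`` (or ``features.tsv``) and ``barcodes.tsv``.
    orientation
        Layout of the file on disk; output is always cells x genes.
    normalize
        Treat the input as raw counts and apply library-size
        normalization (common library of 10,000) followed by log1p.
    """
    if format not in {"mtx", "csv", "tsv"}:
        raise ValueError(f"unknown format {format!r}")
    if orientation not in {"cells_by_genes", "genes_by_cells"}:
        raise ValueError(f"unknown orientation {orientation!r}")

    if format == "mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=float)
        d = os.path.dirname(os.path.abspath(path))
        gene_path = os.path.join(d, "genes.tsv")
        if not os.path.exists(gene_path):
            gene_path = os.path.join(d, "features.tsv")
        genes = pd.read_csv(gene_path, sep="\t", header=None)[0].astype(str).tolist()
        cells = pd.read_csv(
            os.path.join(d, "barcodes.tsv"), sep="\t", header=None
        )[0].astype(str).tolist()
        if orientation == "genes_by_cells":
            mat = mat.T
        row_ids, col_ids = cells, genes
    else:
        sep = "," if format == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        mat = df.to_numpy(dtype=float)
        if orientation == "genes_by_cells":
            mat = mat.T
            row_ids = [str(c) for c in df.columns]
            col_ids = [str(i) for i in df.index]
        else:
            row_ids = [str(i) for i in df.index]
            col_ids = [str(c) for c in df.columns]

    if mat.size == 0:
        raise ValueError("empty expression matrix")
    if normalize:
        mat = normalize_counts(mat)
    mat, col_ids = drop_constant_genes(mat, col_ids)
    return ExpressionMatrix(mat, row_ids, col_ids)


def write_expression_mtx(expr: ExpressionMatrix, out_dir: str) -> None:
    """Write matrix.mtx + genes.tsv + barcodes.tsv (cells x genes)."""
    os.makedirs(out_dir, exist_ok=True)
    scipy.io.mmwrite(
        os.path.join(out_dir, "matrix.mtx"), scipy.sparse.coo_matrix(expr.values)
    )
    with open(os.path.join(out_dir, "genes.tsv"), "w") as fh:
        fh.write("\n".join(expr.gene_ids) + "\n")
    with open(os.path.join(out_dir, "barcodes.tsv"), "w") as fh:
        fh.write("\n".join(expr.cell_ids) + "\n")


def read_gmt(path: str) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            name = parts[0]
            genes = list(dict.fromkeys(g for g in parts[2:] if g))
            if name in sets:
                raise ValueError(f"duplicate gene set name {name!r}")
            if not genes:
                logger.warning("gene set %r is empty and was dropped", name)
                continue
            sets[name] = genes
    return GeneSetCollection(sets)


def write_gmt(sets: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for name, genes in sets:
            fh.write("\t".join([name, "na"] + list(genes)) + "\n")


def read_spatial(path: str) -> SpatialMap:
    """Read a CSV with columns cell_id, x, y."""
    df = pd.read_csv(path)
    return SpatialMap(
        df.iloc[:, 0].astype(str).tolist(), df.iloc[:, 1:3].to_numpy(dtype=float)
    )


def write_spatial(smap: SpatialMap, path: str) -> None:
    pd.DataFrame(
        {"cell_id": smap.cell_ids, "x": smap.coords[:, 0], "y": smap.coords[:, 1]}
    ).to_csv(path, index=False)


def read_labels(path: str) -> pd.Series:
    """Read a CSV with columns cell_id, label into a cell-indexed Series."""
    df = pd.read_csv(path)
    return pd.Series(
        df.iloc[:, 1].astype(str).to_numpy(), index=df.iloc[:, 0].astype(str)
    )


def write_results(table, path: str) -> None:
    """Write result records as a TSV with >= 6 significant digits.

    ``table`` is a list of dicts sharing a schema, or a DataFrame.
    Row order is preserved.
    """
    df = pd.DataFrame(table)
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_results(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_embedding(embedding, path: str) -> None:
    """Write a co-embedding as TSV: id, kind, dim1..dimD."""
    d = embedding.dim
    cols = [f"dim{i + 1}" for i in range(d)]
    df_c = pd.DataFrame(embedding.cell_coords, columns=cols)
    df_c.insert(0, "kind", "cell")
    df_c.insert(0, "id", embedding.cell_ids)
    df_g = pd.DataFrame(embedding.gene_coords, columns=cols)
    df_g.insert(0, "kind", "gene")
    df_g.insert(0, "id", embedding.gene_ids)
    pd.concat([df_c, df_g]).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_embedding(path: str):
    from .mca import CoEmbedding

    df = pd.read_csv(path, sep="\t")
    dims = [c for c in df.columns if c.startswith("dim")]
    cells = df[df["kind"] == "cell"]
    genes = df[df["kind"] == "gene"]
    return CoEmbedding(
        cell_coords=cells[dims].to_numpy(dtype=float),
        gene_coords=genes[dims].to_numpy(dtype=float),
        singular_values=np.array([]),
        cell_ids=cells["id"].astype(str).tolist(),
        gene_ids=genes["id"].astype(str).tolist(),
    )


def write_pal_table(pal_vectors, path: str) -> None:
    """Write PAL vectors as a cells x sets TSV (first column cell_id)."""
    data = {"cell_id": pal_vectors[0].cell_ids}
    for p in pal_vectors:
        data[p.set_name] = p.scores
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_pal_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0])
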
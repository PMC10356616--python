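"""Spot-to-cell assignment, cell-by-gene matrix, QC and single-cell analysis.

Decoded spots are assigned to the segmented cell containing their nearest
voxel; label 0 means extracellular (kept in the assignment table, flagged,
excluded from the matrix). The cell-by-gene count matrix is then filtered
(cells with fewer than six transcripts are dropped), log(1+x) transformed
and analysed with the standard single-cell stack: PCA (10 components), a
kNN graph (5 neighbours), Leiden community detection (resolution 1) and a
UMAP embedding for visualization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from plantfish.segmentation import SegmentationMask

__all__ = [
    "CellByGeneMatrix",
    "ClusterResult",
    "assign_spots",
    "build_matrix",
    "filter_cells",
    "qc_summaries",
    "replicate_correlation",
    "log_normalize",
    "embed_and_cluster",
    "cluster_heatmap_table",
]


@dataclass
class CellByGeneMatrix:
    """Sparse non-negative counts over (cell, gene) with cell metadata.

    ``cells`` carries one row per retained cell (label, centroid, volume,
    ``total_counts``, ``genes_detected``); rows of ``counts`` align with it.
    """

    counts: sparse.csr_matrix
    genes: list[str]
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        if self.counts.shape != (len(self.cells), len(self.genes)):
            raise ValueError("counts shape inconsistent with cells/genes")
        if (self.counts.data < 0).any():
            raise ValueError("negative counts")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def gene_totals(self) -> pd.Series:
        return pd.Series(np.asarray(self.counts.sum(axis=0)).ravel(), index=self.genes)

    def to_anndata(self) -> ad.AnnData:
        adata = ad.AnnData(
            X=self.counts.copy(),
            obs=self.cells.set_index(self.cells["label"].astype(str)),
            var=pd.DataFrame(index=pd.Index(self.genes, name="gene")),
        )
        return adata


@dataclass
class ClusterResult:
    """Per-cell cluster ids, 2D embedding and per-cluster expression means."""

    cluster: pd.Series  # index aligned with matrix cells, values str ids
    embedding: np.ndarray  # (n_cells, 2)
    adata: ad.AnnData = field(repr=False, default=None)


def assign_spots(spots: pd.DataFrame, mask: SegmentationMask) -> pd.DataFrame:
    """Label each decoded spot with the segmentation label at its voxel.

    Spots outside the volume get label 0 and ``in_volume=False`` (with a
    warning count in the table attrs); label 0 inside the volume means
    extracellular. Spot rows are copied, never dropped — counts are
    conserved.
    """
    out = spots.copy().reset_index(drop=True)
    vs = np.asarray(mask.voxel_size)
    shape = np.asarray(mask.label_volume.shape)
    pos_vox = np.rint(out[["z_um", "y_um", "x_um"]].to_numpy() / vs).astype(int)
    in_volume = np.all((pos_vox >= 0) & (pos_vox < shape), axis=1)
    labels = np.zeros(len(out), dtype=np.int64)
    if in_volume.any():
        idx = pos_vox[in_volume]
        labels[in_volume] = mask.label_volume[idx[:, 0], idx[:, 1], idx[:, 2]]
    out["cell"] = labels
    out["in_volume"] = in_volume
    out["assigned"] = labels > 0
    out.attrs["n_outside_volume"] = int((~in_volume).sum())
    return out


def build_matrix(
    assignments: pd.DataFrame, genes: list[str], mask: SegmentationMask | None = None
) -> CellByGeneMatrix:
    """Tally assigned spots into a sparse (cell, gene) count matrix.

    Only in-cell spots (label > 0) enter the matrix; the matrix total equals
    their number exactly. Cells present in the mask but hit by no spot get
    all-zero rows (so segmentation and matrix stay aligned).
    """
    assigned = assignments.loc[assignments["assigned"].astype(bool)]
    if mask is not None:
        cell_labels = mask.cell_table["label"].to_numpy()
        cells_meta = mask.cell_table.copy()
    else:
        cell_labels = np.unique(assigned["cell"].to_numpy())
        cells_meta = pd.DataFrame({"label": cell_labels})
    label_index = {label: i for i, label in enumerate(cell_labels)}
    gene_index = {g: i for i, g in enumerate(genes)}
    unknown = set(assigned["gene"]) - set(genes)
    if unknown:
        raise ValueError(f"assigned spots carry genes not in the gene list: {sorted(unknown)}")
    rows = assigned["cell"].map(label_index).to_numpy()
    cols = assigned["gene"].map(gene_index).to_numpy()
    counts = sparse.coo_matrix(
        (np.ones(len(assigned), dtype=np.int64), (rows, cols)),
        shape=(len(cell_labels), len(genes)),
    ).tocsr()
    cells_meta = cells_meta.reset_index(drop=True)
    cells_meta["total_counts"] = np.asarray(counts.sum(axis=1)).ravel()
    cells_meta["genes_detected"] = np.asarray((counts > 0).sum(axis=1)).ravel()
    return CellByGeneMatrix(counts=counts, genes=list(genes), cells=cells_meta)


def filter_cells(m: CellByGeneMatrix, min_spots: int = 6) -> CellByGeneMatrix:
    """Drop cells with fewer than ``min_spots`` transcripts (keep >= min)."""
    if min_spots < 0:
        raise ValueError("min_spots must be >= 0")
    totals = np.asarray(m.counts.sum(axis=1)).ravel()
    keep = totals >= min_spots
    return CellByGeneMatrix(
        counts=m.counts[keep], genes=list(m.genes), cells=m.cells.loc[keep].reset_index(drop=True)
    )


def qc_summaries(m: CellByGeneMatrix) -> dict:
    """Per-cell molecule/gene counts and per-gene bulk totals with medians."""
    per_cell = m.cells[["label"]].copy()
    per_cell["molecules"] = np.asarray(m.counts.sum(axis=1)).ravel()
    per_cell["genes_detected"] = np.asarray((m.counts > 0).sum(axis=1)).ravel()
    return {
        "per_cell": per_cell,
        "per_gene_totals": m.gene_totals(),
        "median_molecules_per_cell": float(per_cell["molecules"].median()) if len(per_cell) else 0.0,
        "median_genes_per_cell": float(per_cell["genes_detected"].median()) if len(per_cell) else 0.0,
        "n_cells": int(m.n_cells),
        "total_molecules": int(per_cell["molecules"].sum()),
    }


def replicate_correlation(
    matrices: list[CellByGeneMatrix], pseudocount_per: float = 1e4
) -> pd.DataFrame:
    """Pairwise Pearson correlation of normalized bulk expression profiles.

    Per sample, gene totals are normalized to proportions and log-scaled as
    ``log1p(proportion * pseudocount_per)`` (one pseudocount per 10⁴
    transcripts); Pearson correlation across genes for every sample pair.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two samples")
    genes = matrices[0].genes
    for m in matrices[1:]:
        if m.genes != genes:
            raise ValueError("samples must share one gene list")
    profiles = []
    for m in matrices:
        totals = m.gene_totals().to_numpy().astype(float)
        tot = totals.sum()
        props = totals / tot if tot > 0 else totals
        profiles.append(np.log1p(props * pseudocount_per))
    table = pd.DataFrame(np.corrcoef(np.stack(profiles)))
    table.index = table.columns = [f"sample{i + 1}" for i in range(len(matrices))]
    return table


def log_normalize(m: CellByGeneMatrix) -> np.ndarray:
    """Elementwise log(1 + count); zero-preserving and monotone."""
    return np.log1p(m.dense().astype(float))


def embed_and_cluster(
    m: CellByGeneMatrix,
    n_pcs: int = 10,
    n_neighbors: int = 5,
    resolution: float = 1.0,
    seed: int = 0,
) -> ClusterResult:
    """log1p -> PCA -> kNN graph -> Leiden communities -> UMAP.

    Deterministic per seed. Degenerate inputs (all-identical cells) yield a
    single cluster rather than an error.
    """
    import scanpy as sc

    if m.n_cells < n_neighbors + 1:
        raise ValueError(f"need at least {n_neighbors + 1} cells")
    adata = m.to_anndata()
    adata.layers["counts"] = adata.X.copy()
    adata.X = np.log1p(np.asarray(adata.X.todense()).astype(np.float32))
    if np.allclose(adata.X.var(axis=0), 0):
        cluster = pd.Series(["0"] * m.n_cells, index=m.cells.index, name="cluster")
        return ClusterResult(cluster=cluster, embedding=np.zeros((m.n_cells, 2)), adata=adata)
    n_pcs = min(n_pcs, min(adata.shape) - 1)
    sc.pp.pca(adata, n_comps=n_pcs, random_state=seed)
    sc.pp.neighbors(adata, n_neighbors=n_neighbors, n_pcs=n_pcs, random_state=seed)
    with warnings.catch_warnings():
        # scanpy announces the future igraph default; leidenalg is pinned
        # here deliberately for seeded determinism
        warnings.filterwarnings("ignore", category=FutureWarning, message=".*leiden.*")
        sc.tl.leiden(adata, resolution=resolution, random_state=seed, flavor="leidenalg")
    sc.tl.umap(adata, random_state=seed)
    cluster = pd.Series(
        np.asarray(adata.obs["leiden"]).astype(str), index=m.cells.index, name="cluster"
    )
    return ClusterResult(cluster=cluster, embedding=np.asarray(adata.obsm["X_umap"]), adata=adata)


def cluster_heatmap_table(result: ClusterResult, m: CellByGeneMatrix) -> pd.DataFrame:
    """Per-gene z-scored cluster means of log1p expression.

    Rows are clusters, columns genes; with a single cluster the z-scores are
    all zero.
    """
    expr = pd.DataFrame(log_normalize(m), columns=m.genes, index=m.cells.index)
    means = expr.groupby(result.cluster).mean()
    std = means.std(axis=0, ddof=0)
    centered = means - means.mean(axis=0)
    z = centered.div(std.replace(0, np.nan), axis=1).fillna(0.0)
    return z
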
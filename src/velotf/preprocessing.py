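"""Gene filtering, HVG selection, normalization, kNN moments and per-gene
problem assembly.

The preprocessing contract mirrors the standard single-cell velocity
pipeline, applied to total mRNA counts: drop genes detected in fewer than 2%
of cells, keep the top 2000 genes by mean-binned normalized dispersion,
normalize each cell by its total count, then smooth each gene by averaging
over a 30-nearest-neighbor graph built in 30-PC space of the log-transformed
normalized counts.  Fitting instances are then cut out per target gene using
a TF→target prior table, with zero-expression cells dropped and both the TF
rows and the target scaled to unit standard deviation.
"""

from __future__ import annotations

import numpy as np
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import ExpressionDataset, GeneProblem, RegulatoryPriorTable, SkipGene

__all__ = [
    "filter_and_select",
    "compute_moments",
    "assemble_gene_problem",
    "normalized_dispersion",
]

#: minimum cells with nonzero target expression required to fit a gene
MIN_CELLS_PER_GENE = 10


def normalized_dispersion(matrix: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Mean-binned normalized dispersion per gene (dispersion = var/mean).

    Genes are binned by mean expression; within each bin the dispersion is
    z-scored (a lone gene in a bin keeps its raw dispersion, std treated as
    1).  Computed on non-log normalized counts.
    """
    mean = matrix.mean(axis=0)
    var = matrix.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    order = np.argsort(mean, kind="stable")
    bins = np.array_split(order, min(n_bins, len(order)))
    norm = np.zeros_like(disp)
    for idx in bins:
        if len(idx) == 0:
            continue
        mu, sd = disp[idx].mean(), disp[idx].std()
        norm[idx] = (disp[idx] - mu) / sd if sd > 0 else 0.0
    return norm


def filter_and_select(ds: ExpressionDataset, min_cell_fraction: float = 0.02,
                      n_top: int = 2000) -> ExpressionDataset:
    """Detection filter, HVG selection and per-cell total-count normalization.

    Genes detected (strictly positive) in fewer than ``min_cell_fraction`` of
    cells are removed; of the remainder the ``n_top`` genes with the highest
    normalized dispersion are kept (ties broken by gene name for
    determinism); each cell is then scaled so its total over the retained
    genes equals the median cell total.
    """
    detected_frac = (ds.matrix > 0).mean(axis=0)
    keep = detected_frac >= min_cell_fraction
    if not np.any(keep):
        raise ValueError("all genes removed by the detection filter")
    matrix = ds.matrix[:, keep]
    genes = ds.gene_names[keep]

    if matrix.shape[1] > n_top:
        disp = normalized_dispersion(matrix)
        # sort by (-dispersion, name) and keep the first n_top
        order = sorted(range(len(genes)), key=lambda i: (-disp[i], str(genes[i])))
        sel = np.sort(np.asarray(order[:n_top]))
        matrix, genes = matrix[:, sel], genes[sel]

    totals = matrix.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("some cells have zero total count over retained genes")
    target_total = float(np.median(totals))
    matrix = matrix * (target_total / totals)[:, None]

    return ExpressionDataset(
        matrix=matrix, gene_names=genes, cell_names=ds.cell_names.copy(),
        cell_labels=None if ds.cell_labels is None else ds.cell_labels.copy(),
        embedding=None if ds.embedding is None else ds.embedding.copy(),
    )


def compute_moments(ds: ExpressionDataset, n_pcs: int = 30,
                    n_neighbors: int = 30) -> ExpressionDataset:
    """First- and second-order kNN moments of the normalized counts.

    The neighbor graph is built from Euclidean distances in the top
    ``n_pcs`` principal components of log1p-transformed normalized counts;
    the smoothed value of gene g in cell c is the plain mean of g over c's
    neighbor set (the cell itself included), and the second moment the
    corresponding uncentered mean of squares.  The log transform is used only
    for the graph; the smoothed values stay on the linear normalized scale.
    """
    n_cells = ds.n_cells
    if n_neighbors >= n_cells:
        raise ValueError(
            f"n_neighbors={n_neighbors} must be smaller than n_cells={n_cells}")
    logm = np.log1p(ds.matrix)
    n_comp = min(n_pcs, n_cells - 1, ds.n_genes)
    coords = PCA(n_components=n_comp, svd_solver="full").fit_transform(logm) \
        if n_comp >= 1 else logm
    nn = NearestNeighbors(n_neighbors=n_neighbors).fit(coords)
    _, idx = nn.kneighbors(coords)
    # sklearn returns each query point among its own neighbors (distance 0),
    # but guard against duplicate-coordinate cells displacing it
    self_missing = idx[:, 0] != np.arange(n_cells)
    if np.any(self_missing):
        idx[self_missing, -1] = np.flatnonzero(self_missing)
    smoothed = ds.matrix[idx].mean(axis=1)
    smoothed_sq = (ds.matrix[idx] ** 2).mean(axis=1)
    return ExpressionDataset(
        matrix=ds.matrix.copy(), gene_names=ds.gene_names.copy(),
        cell_names=ds.cell_names.copy(),
        cell_labels=None if ds.cell_labels is None else ds.cell_labels.copy(),
        embedding=None if ds.embedding is None else ds.embedding.copy(),
        smoothed=smoothed, smoothed_sq=smoothed_sq, neighbor_indices=idx,
    )


def assemble_gene_problem(ds: ExpressionDataset, priors: RegulatoryPriorTable,
                          target: str,
                          min_cells: int = MIN_CELLS_PER_GENE) -> GeneProblem:
    """Build one target gene's fitting instance.

    The TF set is the prior regulators of ``target`` present in the dataset
    (case-insensitive symbol match); cells where the target reads zero are
    dropped; the target and every retained TF row are divided by their
    standard deviation over the kept cells.  TFs constant over the kept cells
    carry no signal and are dropped.  Raises :class:`SkipGene` when no TF is
    available or too few cells remain.
    """
    values = ds.values
    name_by_upper = {str(g).upper(): i for i, g in enumerate(ds.gene_names)}
    t_idx = name_by_upper.get(target.upper())
    if t_idx is None:
        raise KeyError(f"target gene {target!r} not in dataset")
    tf_cols = [(tf, name_by_upper[tf]) for tf in priors.tfs_of(target)
               if tf in name_by_upper and name_by_upper[tf] != t_idx]
    if not tf_cols:
        raise SkipGene(f"{target}: no prior TFs present in the dataset")

    y_raw = values[:, t_idx]
    kept = np.flatnonzero(y_raw != 0)
    if kept.size < min_cells:
        raise SkipGene(
            f"{target}: only {kept.size} cells with nonzero expression "
            f"(minimum {min_cells})")
    y = y_raw[kept]
    y_scale = float(np.std(y))
    if y_scale == 0:
        raise SkipGene(f"{target}: constant nonzero expression")
    y = y / y_scale

    tf_names, rows, scales = [], [], []
    for tf, j in tf_cols:
        x = values[kept, j]
        s = float(np.std(x))
        if s == 0:
            continue  # constant TF carries no dynamic signal
        tf_names.append(tf)
        rows.append(x / s)
        scales.append(s)
    if not rows:
        raise SkipGene(f"{target}: all prior TFs constant over kept cells")

    return GeneProblem(
        target_name=str(ds.gene_names[t_idx]),
        X=np.vstack(rows), y=y, tf_names=tf_names,
        kept_cell_indices=kept, x_scale=np.asarray(scales, float),
        y_scale=y_scale,
    )
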
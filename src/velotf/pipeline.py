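"""End-to-end orchestration: fit many genes, then derive cell-level results.

These helpers tie the per-module pieces together the way the examples and
the command-line interface use them: assemble a fitting problem per target
gene, run the generalized-EM fitter, stack per-gene velocities into
cell × gene matrices, and produce the transition matrix, root/end cells,
pseudotime, stream genes and embedding arrows.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from . import dynamics, trajectory
from .io import ExpressionDataset, RegulatoryPriorTable, SkipGene
from .preprocessing import assemble_gene_problem

logger = logging.getLogger("velotf")

__all__ = ["fit_all_genes", "velocity_matrices", "cell_neighbors",
           "compute_pseudotime"]


def fit_all_genes(ds: ExpressionDataset, priors: RegulatoryPriorTable,
                  targets=None, n_iters: int = 20, n_theta_starts: int = 4,
                  grid: int = 1000, seed: int = 0, min_cells: int = 10,
                  update_w: bool = True) -> dict:
    """Fit every requested target gene; skipped genes are logged, not fatal.

    ``targets`` defaults to all dataset genes that appear as a target in the
    prior table.  Returns a dict target name -> GeneDynamicsFit.
    """
    if targets is None:
        prior_targets = {tgt for (_, tgt) in priors.edges}
        targets = [str(g) for g in ds.gene_names if str(g).upper() in prior_targets]
    fits = {}
    for target in targets:
        try:
            problem = assemble_gene_problem(ds, priors, target, min_cells=min_cells)
            fits[problem.target_name] = dynamics.fit_gene(
                problem, n_iters=n_iters, n_theta_starts=n_theta_starts,
                grid=grid, seed=seed, update_w=update_w)
            logger.info("fitted %s: loss=%.4g", target,
                        fits[problem.target_name].state.loss)
        except SkipGene as exc:
            logger.info("skipped: %s", exc)
    return fits


def velocity_matrices(ds: ExpressionDataset, fits: dict) -> tuple:
    """Cell × gene velocity and (scaled) expression over the fitted genes.

    Velocity is W.X - gamma*y evaluated for *all* cells on each gene's
    unit-standard-deviation scale (the defining formula needs no latent
    time, so cells dropped during fitting still get a velocity).
    """
    values = ds.values
    name_to_col = {str(g).upper(): i for i, g in enumerate(ds.gene_names)}
    genes = sorted(fits)
    n = ds.n_cells
    V = np.zeros((n, len(genes)))
    E = np.zeros((n, len(genes)))
    for j, g in enumerate(genes):
        fit = fits[g]
        y = values[:, name_to_col[g.upper()]] / fit.y_scale
        X = np.vstack([values[:, name_to_col[tf.upper()]] for tf in fit.tf_names])
        X = X / fit.x_scale[:, None]
        V[:, j] = fit.params.W @ X - fit.params.gamma * y
        E[:, j] = y
    return V, E, genes


def cell_neighbors(ds: ExpressionDataset, n_neighbors: int = 30,
                   n_pcs: int = 30) -> np.ndarray:
    """kNN sets (self included), reusing the preprocessing graph if stored."""
    if ds.neighbor_indices is not None:
        return ds.neighbor_indices
    logm = np.log1p(ds.matrix)
    n_comp = min(n_pcs, ds.n_cells - 1, ds.n_genes)
    coords = PCA(n_components=n_comp, svd_solver="full").fit_transform(logm)
    nn = NearestNeighbors(n_neighbors=min(n_neighbors, ds.n_cells)).fit(coords)
    return nn.kneighbors(coords)[1]


def compute_pseudotime(ds: ExpressionDataset, fits: dict,
                       kernel_scale: float = 0.1, root_quantile: float = 0.02,
                       n_neighbors: int = 30,
                       alignment_threshold: float = 0.5) -> dict:
    """Transition matrix, roots/ends, pseudotime, stream genes and arrows.

    Returns a dict with keys ``transition``, ``result`` (PseudotimeResult),
    ``stream_genes``, ``arrows`` (None when the dataset has no embedding)
    and ``embedding``.
    """
    if not fits:
        raise ValueError("no fitted genes")
    V, E, genes = velocity_matrices(ds, fits)
    neighbors = cell_neighbors(ds, n_neighbors=n_neighbors)
    T = trajectory.build_transition_matrix(V, E, neighbors,
                                           kernel_scale=kernel_scale)
    roots, ends = trajectory.find_root_end_cells(T, quantile=root_quantile)
    pt = trajectory.velocity_pseudotime(T, roots)
    result = trajectory.PseudotimeResult(pt, roots, ends)
    try:
        stream_genes = trajectory.select_stream_genes(
            fits, pt, alignment_threshold=alignment_threshold)
    except ValueError:
        stream_genes = genes
    embedding = ds.embedding
    if embedding is None:
        # fall back to the first two PCs of the log-normalized matrix
        logger.warning("no embedding provided; using 2 PCs of log counts")
        logm = np.log1p(ds.matrix)
        embedding = PCA(n_components=2, svd_solver="full").fit_transform(logm)
    arrows = trajectory.embed_velocity_stream(T, embedding)
    return {"transition": T, "result": result, "stream_genes": stream_genes,
            "arrows": arrows, "embedding": embedding}
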
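"""Readers and writers for expression matrices and TF→target prior tables.

Expression data comes in as an annotated-matrix container (h5ad, loom) or a
dense CSV/TSV with cells in rows; total mRNA counts are used throughout —
when spliced/unspliced layers exist they are summed, since the model needs
no splicing information.  Regulatory priors are flat two-column edge lists
(as distributed for the ENCODE and ChEA TF-target annotations).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "RegulatoryPriorTable",
    "GeneProblem",
    "SkipGene",
    "FormatError",
    "load_expression",
    "load_tf_target_priors",
    "write_loom",
    "results_to_anndata",
]


class FormatError(ValueError):
    """An input file could not be parsed as the expected format."""


class SkipGene(Exception):
    """A gene cannot be fitted (no TFs, too few cells, constant expression).

    This is a control-flow signal, not a hard pipeline error: callers log the
    reason and move on to the next gene.
    """


@dataclass
class ExpressionDataset:
    """Cells × genes abundance matrix with optional annotations.

    ``smoothed`` holds first-order kNN moments once computed; ``smoothed_sq``
    the corresponding uncentered second moments.  ``neighbor_indices`` keeps
    the kNN sets (cell itself included) so downstream transition-matrix code
    reuses the same graph as preprocessing.
    """

    matrix: np.ndarray
    gene_names: np.ndarray
    cell_names: np.ndarray
    cell_labels: np.ndarray | None = None
    embedding: np.ndarray | None = None
    smoothed: np.ndarray | None = None
    smoothed_sq: np.ndarray | None = field(default=None, repr=False)
    neighbor_indices: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.cell_names = np.asarray(self.cell_names, dtype=object)
        if self.matrix.ndim != 2:
            raise FormatError("expression matrix must be 2-D (cells × genes)")
        if self.matrix.size == 0:
            raise FormatError("expression matrix is empty")
        n_cells, n_genes = self.matrix.shape
        if len(self.gene_names) != n_genes or len(self.cell_names) != n_cells:
            raise FormatError("gene/cell name lengths do not match the matrix")
        if len(set(self.gene_names)) != n_genes:
            raise FormatError("gene names are not unique")
        if len(set(self.cell_names)) != n_cells:
            raise FormatError("cell names are not unique")
        if np.any(self.matrix < 0):
            raise FormatError("expression matrix contains negative entries")
        if self.smoothed is not None and np.shape(self.smoothed) != self.matrix.shape:
            raise FormatError("smoothed moments must match the matrix shape")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def gene_index(self, name: str) -> int:
        """Case-insensitive lookup of a gene column."""
        target = name.upper()
        for i, g in enumerate(self.gene_names):
            if str(g).upper() == target:
                return i
        raise KeyError(name)

    @property
    def values(self) -> np.ndarray:
        """Smoothed moments when available, raw matrix otherwise."""
        return self.smoothed if self.smoothed is not None else self.matrix


@dataclass
class RegulatoryPriorTable:
    """Deduplicated union of (TF, target) edges with per-edge source tags."""

    edges: dict  # (TF, TARGET) upper-cased -> set of source tags

    def __len__(self) -> int:
        return len(self.edges)

    def tfs_of(self, target: str) -> list:
        """TF symbols annotated as regulators of ``target`` (upper-cased)."""
        t = target.upper()
        return sorted(tf for (tf, tgt) in self.edges if tgt == t)


@dataclass
class GeneProblem:
    """One target gene's fitting instance on unit-standard-deviation scale."""

    target_name: str
    X: np.ndarray  # n_TF × n_cell
    y: np.ndarray  # n_cell
    tf_names: list
    kept_cell_indices: np.ndarray
    x_scale: np.ndarray  # per-TF standard deviation divided out
    y_scale: float

    @property
    def n_tfs(self) -> int:
        return self.X.shape[0]

    @property
    def n_cells(self) -> int:
        return self.y.size


# ---------------------------------------------------------------------------
# expression readers
# ---------------------------------------------------------------------------

_LABEL_KEYS = ("clusters", "cell_type", "celltype", "cell_types", "leiden", "louvain")
_EMBED_KEYS = ("X_umap", "X_tsne", "X_pca")


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense() if hasattr(x, "todense") else x, dtype=float)


def _from_anndata(adata) -> ExpressionDataset:
    layers = [k for k in ("spliced", "unspliced") if k in adata.layers]
    if layers:
        matrix = sum(_dense(adata.layers[k]) for k in layers)
    else:
        matrix = _dense(adata.X)
    labels = None
    for key in _LABEL_KEYS:
        if key in adata.obs:
            labels = np.asarray(adata.obs[key]).astype(object)
            break
    embedding = None
    for key in _EMBED_KEYS:
        if key in adata.obsm:
            embedding = np.asarray(adata.obsm[key])[:, :2].astype(float)
            break
    return ExpressionDataset(
        matrix=matrix,
        gene_names=np.asarray(adata.var_names, dtype=object),
        cell_names=np.asarray(adata.obs_names, dtype=object),
        cell_labels=labels,
        embedding=embedding,
    )


def _read_loom(path: str) -> ExpressionDataset:
    # loom files are plain HDF5: /matrix is genes × cells, row_attrs hold gene
    # metadata, col_attrs cell metadata, extra layers sit under /layers
    import h5py

    def _decode(arr):
        return np.array(
            [v.decode() if isinstance(v, bytes) else str(v) for v in np.asarray(arr)],
            dtype=object)

    def _names(grp, keys, n, prefix):
        for k in keys:
            if k in grp:
                return _decode(grp[k][:])
        return np.array([f"{prefix}{i}" for i in range(n)], dtype=object)

    with h5py.File(path, "r") as f:
        if "matrix" not in f:
            raise FormatError(f"{path}: no /matrix dataset; not a loom file")
        matrix = np.asarray(f["matrix"][:], dtype=float)  # genes × cells
        layers = f.get("layers", {})
        present = [k for k in ("spliced", "unspliced") if k in layers]
        if present:
            matrix = sum(np.asarray(layers[k][:], dtype=float) for k in present)
        ra, ca = f.get("row_attrs", {}), f.get("col_attrs", {})
        genes = _names(ra, ("var_names", "Gene", "GeneName"), matrix.shape[0], "gene_")
        cells = _names(ca, ("obs_names", "CellID", "obs_id"), matrix.shape[1], "cell_")
        labels = None
        for k in _LABEL_KEYS:
            if k in ca:
                labels = _decode(ca[k][:])
    return ExpressionDataset(matrix=matrix.T, gene_names=genes, cell_names=cells,
                             cell_labels=labels)


def _read_csv(path: str, sep: str) -> ExpressionDataset:
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:
        raise FormatError(f"{path}: could not parse as delimited text: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: empty expression table")
    return ExpressionDataset(
        matrix=df.to_numpy(dtype=float),
        gene_names=np.asarray(df.columns, dtype=object),
        cell_names=np.asarray(df.index.astype(str), dtype=object),
    )


def load_expression(path: str, format: str | None = None) -> ExpressionDataset:
    """Read an expression file into an :class:`ExpressionDataset`.

    ``format`` is one of ``h5ad``, ``loom``, ``csv``, ``tsv``; inferred from
    the extension when omitted.  For container formats, spliced/unspliced
    layers (when present) are summed into total counts; the raw count scale
    is preserved (no normalization happens here).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        ext = os.path.splitext(path)[1].lower().lstrip(".")
        format = {"h5ad": "h5ad", "loom": "loom", "csv": "csv",
                  "tsv": "tsv", "txt": "tsv"}.get(ext)
        if format is None:
            raise FormatError(f"cannot infer format from extension of {path}")
    if format == "h5ad":
        import anndata
        try:
            adata = anndata.read_h5ad(path)
        except Exception as exc:
            raise FormatError(f"{path}: not a readable h5ad file: {exc}") from exc
        return _from_anndata(adata)
    if format == "loom":
        return _read_loom(path)
    if format in ("csv", "tsv"):
        return _read_csv(path, sep="," if format == "csv" else "\t")
    raise FormatError(f"unknown format {format!r}")


def write_loom(path: str, ds: ExpressionDataset) -> None:
    """Write a minimal loom (HDF5) file: /matrix genes × cells plus names."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("matrix", data=ds.matrix.T)
        ra = f.create_group("row_attrs")
        ra.create_dataset("Gene", data=np.asarray(ds.gene_names, dtype="S"))
        ca = f.create_group("col_attrs")
        ca.create_dataset("CellID", data=np.asarray(ds.cell_names, dtype="S"))
        if ds.cell_labels is not None:
            ca.create_dataset("clusters", data=np.asarray(ds.cell_labels, dtype="S"))
        f.create_group("layers")


# ---------------------------------------------------------------------------
# regulatory priors
# ---------------------------------------------------------------------------

def load_tf_target_priors(paths, source_tags=None) -> RegulatoryPriorTable:
    """Union of two-column (tf, target) edge lists.

    Lines starting with '#' are comments; an optional header line whose first
    two fields are 'tf' and 'target' (any case) is skipped.  Matching is
    case-insensitive: symbols are upper-cased on load so that mouse-style and
    human-style capitalization meet.  A malformed line raises
    :class:`FormatError` naming the file and line number.
    """
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    if source_tags is None:
        source_tags = [os.path.splitext(os.path.basename(p))[0] for p in paths]
    edges: dict = {}
    for path, tag in zip(paths, source_tags):
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.replace(",", "\t").split("\t")
                fields = [f.strip() for f in fields if f.strip()]
                if len(fields) < 2:
                    raise FormatError(
                        f"{path}:{lineno}: expected two columns (tf, target), "
                        f"got {line!r}")
                tf, target = fields[0].upper(), fields[1].upper()
                if lineno == 1 and (tf, target) == ("TF", "TARGET"):
                    continue
                edges.setdefault((tf, target), set()).add(tag)
    return RegulatoryPriorTable(edges=edges)


# ---------------------------------------------------------------------------
# result export
# ---------------------------------------------------------------------------

def results_to_anndata(ds: ExpressionDataset, fits: dict,
                       pseudotime=None) -> "anndata.AnnData":
    """Pack fitted results into an AnnData container for h5ad export.

    Per-gene parameters land in ``var``; per-cell latent time and velocity in
    ``layers`` (NaN for cells a gene dropped); sparse TF weights as a tidy
    table in ``uns['tf_weights']``; pseudotime in ``obs``.
    """
    import anndata

    adata = anndata.AnnData(
        X=ds.matrix.copy(),
        obs=pd.DataFrame(index=ds.cell_names.astype(str)),
        var=pd.DataFrame(index=ds.gene_names.astype(str)),
    )
    if ds.cell_labels is not None:
        adata.obs["clusters"] = pd.Categorical(ds.cell_labels.astype(str))
    if ds.embedding is not None:
        adata.obsm["X_umap"] = np.asarray(ds.embedding, float)
    if ds.smoothed is not None:
        adata.layers["smoothed"] = ds.smoothed

    n_cells, n_genes = ds.matrix.shape
    for col in ("alpha", "beta", "theta", "gamma", "loss", "sigma"):
        adata.var[f"fit_{col}"] = np.nan
    adata.var["fit_init_index"] = -1
    latent = np.full((n_cells, n_genes), np.nan)
    velo = np.full((n_cells, n_genes), np.nan)
    rows = []
    name_to_col = {str(g): i for i, g in enumerate(ds.gene_names)}
    for gene, fit in fits.items():
        j = name_to_col[str(gene)]
        p = fit.params
        adata.var.loc[str(gene), ["fit_alpha", "fit_beta", "fit_theta",
                                  "fit_gamma", "fit_loss", "fit_sigma"]] = [
            p.alpha, p.beta, p.theta, p.gamma, fit.state.loss, fit.state.sigma]
        adata.var.loc[str(gene), "fit_init_index"] = fit.init_index
        latent[fit.kept_cell_indices, j] = fit.state.t
        velo[fit.kept_cell_indices, j] = fit.velocity
        xbar = np.array([
            ds.values[fit.kept_cell_indices, name_to_col[tf]].mean()
            if tf in name_to_col else 1.0 for tf in fit.tf_names])
        from .dynamics import normalize_weights
        try:
            wn = normalize_weights(p.W, xbar)
        except ValueError:
            wn = np.zeros_like(p.W)
        for tf, w, nw in zip(fit.tf_names, p.W, wn):
            rows.append((str(gene), str(tf), float(w), float(nw)))
    adata.layers["latent_time"] = latent
    adata.layers["velocity"] = velo
    adata.uns["tf_weights"] = pd.DataFrame(
        rows, columns=["gene", "tf", "weight", "normalized_weight"])
    if pseudotime is not None:
        adata.obs["velocity_pseudotime"] = np.asarray(pseudotime, float)
    return adata
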
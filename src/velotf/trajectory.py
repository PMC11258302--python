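"""Cell-level trajectory analysis from per-gene velocity fits.

Per-gene velocities are combined into a cell-to-cell transition matrix on
the kNN graph: the probability of a transition c→j grows with the cosine
similarity between cell c's velocity vector and the expression displacement
toward j (an exponential kernel).  Root and end cells fall out of the
stationary distributions of the (transposed) transition matrix; pseudotime
is the expected number of random-walk steps separating a cell from the root
set; and arrows on a 2D embedding are transition-probability-weighted
neighbor displacements with the uniform-kernel drift removed.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import sparse, stats

__all__ = [
    "TransitionMatrix",
    "PseudotimeResult",
    "build_transition_matrix",
    "find_root_end_cells",
    "velocity_pseudotime",
    "normalize_gene_time",
    "select_stream_genes",
    "embed_velocity_stream",
    "plot_stream",
]


class TransitionMatrix:
    """Row-stochastic cell × cell matrix supported on the kNN graph."""

    def __init__(self, T: sparse.csr_matrix):
        T = sparse.csr_matrix(T)
        rows = np.asarray(T.sum(axis=1)).ravel()
        if T.nnz and np.any(T.data < 0):
            raise ValueError("transition probabilities must be nonnegative")
        if not np.allclose(rows, 1.0, atol=1e-8):
            raise ValueError("every row must sum to 1")
        self.T = T

    @property
    def n_cells(self) -> int:
        return self.T.shape[0]

    def transpose_normalized(self) -> sparse.csr_matrix:
        """The reversed-edge matrix, row-renormalized to be stochastic."""
        R = sparse.csr_matrix(self.T.T)
        rows = np.asarray(R.sum(axis=1)).ravel()
        rows[rows == 0] = 1.0
        return sparse.diags(1.0 / rows) @ R


class PseudotimeResult:
    """Per-cell pseudotime in [0, 1] plus the detected root/end cells."""

    def __init__(self, pseudotime: np.ndarray, root_cells: np.ndarray,
                 end_cells: np.ndarray):
        self.pseudotime = np.asarray(pseudotime, float)
        self.root_cells = np.asarray(root_cells, int)
        self.end_cells = np.asarray(end_cells, int)


def _cosine_rows(v: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Cosine of one vector against each row of D; zero vectors give 0."""
    nv = np.linalg.norm(v)
    nd = np.linalg.norm(D, axis=1)
    denom = nv * nd
    out = np.zeros(D.shape[0])
    ok = denom > 0
    out[ok] = (D[ok] @ v) / denom[ok]
    return out


def build_transition_matrix(velocity: np.ndarray, expression: np.ndarray,
                            neighbors: np.ndarray,
                            kernel_scale: float = 0.1) -> TransitionMatrix:
    """Exponential cosine kernel between velocities and neighbor displacements.

    For each neighbor j of cell c (self-edges excluded), the unnormalized
    weight is exp(cos(velocity_c, expression_j - expression_c) / scale);
    rows are normalized to probability.  A cell with zero velocity gets a
    uniform row over its neighbors.
    """
    velocity = np.asarray(velocity, float)
    expression = np.asarray(expression, float)
    if velocity.shape != expression.shape:
        raise ValueError("velocity and expression must share shape")
    if kernel_scale <= 0:
        raise ValueError("kernel_scale must be positive")
    n = velocity.shape[0]
    rows, cols, vals = [], [], []
    for c in range(n):
        nb = np.asarray(neighbors[c], int)
        nb = nb[nb != c]
        if nb.size == 0:
            rows.append(c); cols.append(c); vals.append(1.0)
            continue
        sims = _cosine_rows(velocity[c], expression[nb] - expression[c])
        w = np.exp(sims / kernel_scale)
        w = w / w.sum()
        rows.extend([c] * nb.size)
        cols.extend(nb.tolist())
        vals.extend(w.tolist())
    T = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return TransitionMatrix(T)


def _stationary(T: sparse.csr_matrix, max_iter: int = 5000,
                tol: float = 1e-10) -> np.ndarray:
    """Stationary distribution (left eigenvector for eigenvalue 1).

    Lazy power iteration: the half-self-loop chain (I + T)/2 has the same
    stationary vector and is aperiodic, so the iteration converges even on
    directed cycles.  If the chain mixes too slowly for the iteration cap,
    the last iterate is still a meaningful smoothed occupancy and is used
    with a warning.
    """
    n = T.shape[0]
    pi = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        nxt = 0.5 * pi + 0.5 * (pi @ T)
        nxt = nxt / nxt.sum()
        if np.abs(nxt - pi).sum() < tol:
            return nxt
        pi = nxt
    warnings.warn("stationary-vector iteration did not converge; "
                  "using the last iterate")
    return pi


def find_root_end_cells(T: TransitionMatrix,
                        quantile: float = 0.02) -> tuple:
    """Root and end cells as the top quantile of stationary mass.

    End cells accumulate stationary mass under the forward walk; root cells
    under the reversed (transposed, row-renormalized) walk.  Ties break by
    cell index for determinism.
    """
    n = T.n_cells
    k = max(1, int(np.ceil(quantile * n)))

    def top_k(pi):
        order = np.lexsort((np.arange(n), -pi))
        return np.sort(order[:k])

    ends = top_k(_stationary(T.T))
    roots = top_k(_stationary(T.transpose_normalized()))
    return roots, ends


def velocity_pseudotime(T: TransitionMatrix, roots: np.ndarray,
                        n_steps: int = 500) -> np.ndarray:
    """Expected walk depth from the root set, min-max scaled to [0, 1].

    Solves the expected-steps recursion tau = 1 + R tau (tau = 0 on roots)
    by truncated value iteration on the reversed chain R, i.e. the average
    number of steps a walk started at the roots needs to arrive at each
    cell.  Truncation at ``n_steps`` caps cells the walk cannot reach, which
    then map to pseudotime 1.
    """
    roots = np.asarray(roots, int)
    if roots.size == 0:
        raise ValueError("root set must be nonempty")
    R = T.transpose_normalized()
    n = T.n_cells
    mask = np.ones(n, bool)
    mask[roots] = False
    tau = np.zeros(n)
    for _ in range(n_steps):
        nxt = 1.0 + R @ tau
        nxt[~mask] = 0.0
        if np.max(np.abs(nxt - tau)) < 1e-12:
            tau = nxt
            break
        tau = nxt
    if np.any(tau >= n_steps - 1):
        warnings.warn("some cells are unreachable from the roots; "
                      "they are assigned pseudotime 1")
    lo, hi = tau.min(), tau.max()
    return (tau - lo) / (hi - lo) if hi > lo else np.zeros(n)


def normalize_gene_time(latent_time: np.ndarray, n_bins: int = 50,
                        min_run: int = 3) -> np.ndarray:
    """Order cells along a cyclic latent time by cutting at the largest gap.

    The sine profile is periodic, so latent time is only defined up to a
    cyclic rotation.  If the histogram of latent times (``n_bins`` bins over
    [0, 1)) has a run of at least ``min_run`` consecutive empty bins
    (cyclically), time is rotated so it starts at the first occupied bin
    after the longest empty run; the rotated times are then min-max mapped
    to [0, 1].
    """
    t = np.asarray(latent_time, float)
    counts, edges = np.histogram(t, bins=n_bins, range=(0.0, 1.0))
    empty = counts == 0
    if np.any(empty) and not np.all(empty):
        # longest cyclic run of empty bins; ties -> smallest start index
        doubled = np.concatenate([empty, empty])
        best_len, best_start, run, start = 0, 0, 0, 0
        for i, e in enumerate(doubled):
            if e:
                if run == 0:
                    start = i
                run += 1
                if start < n_bins and run <= n_bins and run > best_len:
                    best_len, best_start = run, start
            else:
                run = 0
        if best_len >= min_run:
            cut = edges[(best_start + best_len) % n_bins]
            t = np.mod(t - cut, 1.0)
    lo, hi = t.min(), t.max()
    return (t - lo) / (hi - lo) if hi > lo else np.zeros_like(t)


def select_stream_genes(fits: dict, pseudotime: np.ndarray,
                        alignment_threshold: float = 0.5,
                        n_bins: int = 50) -> list:
    """Genes whose fit is good and whose gene time tracks the pseudotime.

    Keeps genes with mean per-cell loss in the bottom 50% whose normalized
    latent time has Spearman correlation >= ``alignment_threshold`` with the
    cell pseudotime; flat (low-dynamics) fits are excluded up front.  If the
    intersection is empty the 10 best-aligned genes are returned with a
    warning.
    """
    usable = {g: f for g, f in fits.items() if not f.low_dynamics}
    if len(usable) < 2:
        raise ValueError("need at least two fitted genes")
    losses = {g: f.mean_loss for g, f in usable.items()}
    cutoff = float(np.median(list(losses.values())))
    aligned = {}
    for g, f in usable.items():
        gt = normalize_gene_time(f.state.t, n_bins=n_bins)
        rho = stats.spearmanr(gt, pseudotime[f.kept_cell_indices]).statistic
        aligned[g] = float(rho) if np.isfinite(rho) else -1.0
    selected = [g for g in usable
                if losses[g] <= cutoff and aligned[g] >= alignment_threshold]
    if not selected:
        warnings.warn("no gene passed both filters; relaxing to the 10 "
                      "best-aligned genes")
        selected = sorted(aligned, key=lambda g: (-aligned[g], g))[:10]
    return sorted(selected)


def embed_velocity_stream(T: TransitionMatrix,
                          embedding: np.ndarray) -> np.ndarray:
    """Project transitions into arrows on a 2D embedding.

    arrow_c = sum_j T[c,j] (e_j - e_c) minus the unweighted mean neighbor
    displacement, so a fully uninformative (uniform) row yields a zero
    arrow instead of drifting toward dense regions.
    """
    emb = np.asarray(embedding, float)
    n = T.n_cells
    arrows = np.zeros((n, 2))
    M = T.T.tocsr()
    for c in range(n):
        sl = slice(M.indptr[c], M.indptr[c + 1])
        nb = M.indices[sl]
        if nb.size == 0:
            continue
        disp = emb[nb] - emb[c]
        arrows[c] = M.data[sl] @ disp - disp.mean(axis=0)
    return arrows


def plot_stream(embedding: np.ndarray, arrows: np.ndarray, color=None,
                ax=None, density: float = 1.5):
    """Quiver-style stream view of embedding arrows (matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    sc = ax.scatter(embedding[:, 0], embedding[:, 1], c=color, s=8, alpha=0.6)
    ax.quiver(embedding[:, 0], embedding[:, 1], arrows[:, 0], arrows[:, 1],
              angles="xy", scale_units="xy", width=0.002, alpha=0.8)
    if color is not None:
        plt.colorbar(sc, ax=ax)
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    return ax
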
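"""Quantitative evaluation of phase-portrait fits and velocity streams.

Phase-portrait metrics operate on the (W.X, y) plane (or the
unspliced/spliced plane for splicing-based methods): intra-class distance
(cells of one type should cluster; lower is better), inter-class distance
(type centroids should separate; higher is better) and fitting error
(distance of each cell to its matched model point).  All three standardize
each coordinate by its standard deviation, so they are invariant to
separate affine rescaling of the two axes.

Stream metrics follow the conventions of velocity benchmarking: CBDir
(cross-boundary direction correctness) checks that boundary-cell velocities
point toward the annotated next cell type; ICCoh (in-cluster coherence)
checks that velocities within a cluster agree; velocity consistency scores
each cell's velocity against its neighborhood mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhasePoints",
    "intra_class_distance",
    "inter_class_distance",
    "fitting_error",
    "cross_boundary_direction_correctness",
    "in_cluster_coherence",
    "velocity_consistency",
]


@dataclass
class PhasePoints:
    """Per-cell phase-portrait coordinates with cell-type labels."""

    x: np.ndarray
    y: np.ndarray
    labels: np.ndarray
    model_curve: np.ndarray | None = None  # n × 2 modeled (x(t_c), y(t_c))

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        self.labels = np.asarray(self.labels)
        if not (self.x.shape == self.y.shape == self.labels.shape):
            raise ValueError("x, y and labels must have the same length")
        if np.std(self.x) == 0 or np.std(self.y) == 0:
            raise ValueError("degenerate phase coordinates (zero spread)")


def _cos(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0  # cosine of a zero vector is defined as 0
    return float(a @ b / (na * nb))


def intra_class_distance(pp: PhasePoints) -> float:
    """Summed squared standardized distance of cells to their type centroid."""
    sx, sy = np.std(pp.x), np.std(pp.y)
    total = 0.0
    for k in np.unique(pp.labels):
        m = pp.labels == k
        if not np.any(m):
            continue
        cx, cy = pp.x[m].mean(), pp.y[m].mean()
        total += np.sum(((pp.x[m] - cx) / sx) ** 2 + ((pp.y[m] - cy) / sy) ** 2)
    return float(total)


def inter_class_distance(pp: PhasePoints) -> float:
    """Summed squared standardized distance between type centroids.

    The sum runs over ordered pairs k1 != k2, i.e. each unordered pair
    counts twice.
    """
    classes = np.unique(pp.labels)
    if classes.size < 2:
        raise ValueError("inter-class distance needs at least two cell types")
    sx, sy = np.std(pp.x), np.std(pp.y)
    cents = np.array([[pp.x[pp.labels == k].mean(), pp.y[pp.labels == k].mean()]
                      for k in classes])
    total = 0.0
    for i in range(len(classes)):
        for j in range(len(classes)):
            if i == j:
                continue
            total += ((cents[i, 0] - cents[j, 0]) / sx) ** 2 \
                + ((cents[i, 1] - cents[j, 1]) / sy) ** 2
    return float(total)


def fitting_error(pp: PhasePoints) -> float:
    """Summed squared standardized distance of cells to their model points."""
    if pp.model_curve is None:
        raise ValueError("fitting_error requires model_curve")
    mc = np.asarray(pp.model_curve, float)
    sx, sy = np.std(pp.x), np.std(pp.y)
    return float(np.sum(((pp.x - mc[:, 0]) / sx) ** 2
                        + ((pp.y - mc[:, 1]) / sy) ** 2))


def cross_boundary_direction_correctness(velocity, expression, labels,
                                         transitions, neighbors) -> dict:
    """CBDir per annotated (source type, target type) transition.

    A boundary cell is a source-type cell with at least one target-type
    neighbor; its score is the mean cosine between its velocity and the
    displacement vectors toward those neighbors.  The transition score
    averages over boundary cells; transitions with no boundary cells are
    omitted with a warning.
    """
    velocity = np.asarray(velocity, float)
    expression = np.asarray(expression, float)
    labels = np.asarray(labels)
    out = {}
    for src, tgt in transitions:
        scores = []
        for c in np.flatnonzero(labels == src):
            nb = np.asarray(neighbors[c], int)
            nb = nb[(nb != c) & (labels[nb] == tgt)]
            if nb.size == 0:
                continue
            cos = [_cos(velocity[c], expression[j] - expression[c]) for j in nb]
            scores.append(np.mean(cos))
        if scores:
            out[(src, tgt)] = float(np.mean(scores))
        else:
            warnings.warn(f"no boundary cells for transition {src!r} -> {tgt!r}")
    return out


def in_cluster_coherence(velocity, labels, neighbors) -> dict:
    """ICCoh: mean cosine of each cell's velocity with same-cluster neighbors."""
    velocity = np.asarray(velocity, float)
    labels = np.asarray(labels)
    out = {}
    for k in np.unique(labels):
        scores = []
        for c in np.flatnonzero(labels == k):
            nb = np.asarray(neighbors[c], int)
            nb = nb[(nb != c) & (labels[nb] == k)]
            if nb.size == 0:
                continue
            scores.append(np.mean([_cos(velocity[c], velocity[j]) for j in nb]))
        if scores:
            out[k] = float(np.mean(scores))
    return out


def velocity_consistency(velocity, neighbors) -> np.ndarray:
    """Per-cell cosine between a cell's velocity and its neighbors' mean."""
    velocity = np.asarray(velocity, float)
    n = velocity.shape[0]
    out = np.zeros(n)
    for c in range(n):
        nb = np.asarray(neighbors[c], int)
        nb = nb[nb != c]
        if nb.size == 0:
            continue
        out[c] = _cos(velocity[c], velocity[nb].mean(axis=0))
    return out
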
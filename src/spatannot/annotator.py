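"""Marker-gated semi-supervised clustering.

The annotation strategy replaces manually labeled training data with
*representative cells*: for every expected cell type a marker score is
computed as the product of its positive-marker intensities and the
complements of its negative-marker intensities on the unit-normalized
matrix.  Cells between the ``q_high`` and ``q_max`` score percentiles are
gated as high-confidence representatives; cells scoring below ``q_low``
for *every* type seed the Unknown class.  Representatives seed cluster
centroids and keep their label at every iteration of a constrained
K-means; the resulting labels become training data for the classifier.

All operations here are deterministic — there is no randomness in gating
or clustering, so a fixed input and configuration always reproduce the
same labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import MarkerSpec, UNKNOWN_LABEL, ValidationError
from .preprocessing import NormalizedMatrix

__all__ = [
    "GateConfig",
    "GatingError",
    "RepresentativeSets",
    "ClusterState",
    "marker_score",
    "abundance_order",
    "select_representatives",
    "seed_centroids",
    "constrained_kmeans",
]


class GatingError(ValueError):
    """Representative selection produced an unusable (empty) set."""


@dataclass
class GateConfig:
    """Percentile gates for representative selection.

    ``q_high`` may be a single percentile or a per-cell-type mapping; a
    higher value restricts the gate to fewer, higher-scoring cells and is
    appropriate for rarer cell types.  ``q_max`` trims the extreme top of
    the score distribution to keep assay artifacts out of the seeds
    (``q_max=100`` disables the trim).  ``q_low`` bounds the per-type
    low-score sets whose intersection seeds the Unknown class.
    """

    q_high: float | dict[str, float] = 95.0
    q_max: float = 100.0
    q_low: float = 50.0
    max_iter: int = 100

    def q_high_for(self, cell_type: str) -> float:
        if isinstance(self.q_high, dict):
            try:
                return float(self.q_high[cell_type])
            except KeyError:
                raise KeyError(f"no q_high configured for cell type '{cell_type}'") from None
        return float(self.q_high)

    def validate(self, cell_types: list[str]) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")
        if not self.q_max <= 100:
            raise ValueError(f"q_max must be <= 100, got {self.q_max}")
        for ct in cell_types:
            qh = self.q_high_for(ct)
            if not self.q_low < qh < self.q_max:
                raise ValueError(
                    f"need q_low < q_high < q_max for '{ct}', got "
                    f"{self.q_low} / {qh} / {self.q_max}"
                )


@dataclass
class RepresentativeSets:
    """Disjoint per-type representative index sets plus the Unknown seeds."""

    order: list[str]  # abundance order in which sets were claimed
    rep_indices: dict[str, np.ndarray]
    unknown: np.ndarray | None
    low_sets: dict[str, np.ndarray] = field(default_factory=dict)

    def sets_for(self, labels: list[str]) -> list[np.ndarray]:
        """Index sets in the given label order (Unknown last when present)."""
        out = []
        for lab in labels:
            if lab == UNKNOWN_LABEL:
                out.append(self.unknown if self.unknown is not None else np.empty(0, dtype=int))
            else:
                out.append(self.rep_indices[lab])
        return out


@dataclass
class ClusterState:
    """Result of the constrained K-means run."""

    labels: np.ndarray  # integer cluster index per cell
    centroids: np.ndarray
    label_names: list[str]
    n_iter: int
    converged: bool
    objective_history: list[float] = field(default_factory=list)

    def label_strings(self) -> np.ndarray:
        names = np.asarray(self.label_names, dtype=object)
        return names[self.labels]


def _require_unit(X: NormalizedMatrix) -> None:
    if not isinstance(X, NormalizedMatrix) or X.provenance != "unit":
        prov = getattr(X, "provenance", type(X).__name__)
        raise ValidationError(f"expected a unit-normalized matrix, got {prov!r}")


def marker_score(X: NormalizedMatrix, spec: MarkerSpec, cell_type: str) -> np.ndarray:
    """Per-cell marker score for one cell type.

    ``M_c[i] = prod_{p in M+} X[i,p] * prod_{p in M-} (max(X[:,p]) - X[i,p])``

    Positive markers contribute their intensity directly; negative markers
    contribute the complement relative to the column maximum, so a cell at
    the top of a negative-marker channel scores zero.  Scores are
    nonnegative because the unit-normalized matrix is.
    """
    _require_unit(X)
    if cell_type not in spec.cell_types:
        raise ValidationError(f"cell type '{cell_type}' not in marker specification")
    panel = {p: j for j, p in enumerate(X.protein_names)}
    score = np.ones(X.n_cells)
    for p in spec.positive.get(cell_type, []):
        if p not in panel:
            raise ValidationError(
                f"positive marker '{p}' of cell type '{cell_type}' not in panel"
            )
        score = score * X.values[:, panel[p]]
    for p in spec.negative.get(cell_type, []):
        if p not in panel:
            raise ValidationError(
                f"negative marker '{p}' of cell type '{cell_type}' not in panel"
            )
        col = X.values[:, panel[p]]
        score = score * (col.max() - col)
    return score


def abundance_order(X: NormalizedMatrix, spec: MarkerSpec) -> list[str]:
    """Cell types in decreasing order of expected abundance.

    Abundance is proxied by the total (over cells) mean intensity of each
    type's positive-marker columns on the scale-normalized matrix; exact
    ties keep marker-file order.
    """
    _require_unit(X)
    panel = {p: j for j, p in enumerate(X.protein_names)}
    totals = []
    for ct in spec.cell_types:
        cols = [panel[p] for p in spec.positive[ct]]
        totals.append(X.values[:, cols].mean(axis=1).sum())
    order = sorted(range(len(spec.cell_types)), key=lambda i: (-totals[i], i))
    return [spec.cell_types[i] for i in order]


def select_representatives(
    scores: dict[str, np.ndarray],
    cfg: GateConfig,
    order: list[str],
    include_unknown: bool = True,
) -> RepresentativeSets:
    """Gate high-confidence representatives per type, most abundant first.

    For each type (in abundance order) the representatives are the cells
    strictly between the ``q_high`` and ``q_max`` score percentiles, minus
    cells already claimed by a more abundant type; at ``q_max = 100`` the
    upper gate admits the column maximum.  The Unknown seeds are the
    intersection over types of the below-``q_low`` sets, again minus
    claimed cells.
    """
    cfg.validate(order)
    if set(order) != set(scores):
        raise ValidationError("abundance order must be a permutation of the scored types")
    n = len(next(iter(scores.values())))
    claimed = np.zeros(n, dtype=bool)
    rep_indices: dict[str, np.ndarray] = {}
    for ct in order:
        m = scores[ct]
        hi = np.percentile(m, cfg.q_high_for(ct))
        mx = np.percentile(m, cfg.q_max)
        mask = m > hi
        if cfg.q_max < 100:
            mask &= m < mx
        mask &= ~claimed
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise GatingError(
                f"no representative cells for '{ct}' between percentiles "
                f"{cfg.q_high_for(ct)} and {cfg.q_max}; lower q_high for this type"
            )
        rep_indices[ct] = idx
        claimed[idx] = True

    low_sets = {
        ct: np.flatnonzero(scores[ct] < np.percentile(scores[ct], cfg.q_low)) for ct in order
    }
    unknown = None
    if include_unknown:
        mask = np.ones(n, dtype=bool)
        for ct in order:
            low = np.zeros(n, dtype=bool)
            low[low_sets[ct]] = True
            mask &= low
        mask &= ~claimed
        unknown = np.flatnonzero(mask)
        if unknown.size == 0:
            warnings.warn(
                "Unknown representative set is empty (no cell scores below "
                "q_low for every type); the Unknown cluster cannot be seeded"
            )
    return RepresentativeSets(order=list(order), rep_indices=rep_indices,
                              unknown=unknown, low_sets=low_sets)


def seed_centroids(values: np.ndarray, rep_sets: list[np.ndarray]) -> np.ndarray:
    """Initial centroid per cluster = mean of its representative cells."""
    values = np.asarray(values, dtype=float)
    centroids = np.empty((len(rep_sets), values.shape[1]))
    for k, idx in enumerate(rep_sets):
        if len(idx) == 0:
            raise GatingError(f"cluster {k} has no representative cells to seed a centroid")
        centroids[k] = values[idx].mean(axis=0)
    return centroids


def constrained_kmeans(
    values: np.ndarray,
    rep_sets: list[np.ndarray],
    centroids: np.ndarray,
    max_iter: int = 100,
    label_names: list[str] | None = None,
) -> ClusterState:
    """Lloyd iterations with representative cells pinned to their cluster.

    Representatives keep their seeded label at every iteration; every other
    cell is assigned to the nearest centroid (squared Euclidean, ties to
    the lowest cluster index).  Centroids are recomputed as member means;
    a cluster emptied of all members keeps its previous centroid with a
    warning.  Early-stops when assignments no longer change.
    """
    values = np.asarray(values, dtype=float)
    n, _ = values.shape
    k = len(rep_sets)
    centroids = np.asarray(centroids, dtype=float).copy()
    if centroids.shape[0] != k:
        raise ValueError(f"{k} representative sets but {centroids.shape[0]} centroids")
    if label_names is None:
        label_names = [str(i) for i in range(k)]

    pinned = np.full(n, -1, dtype=int)
    for j, idx in enumerate(rep_sets):
        if (pinned[idx] != -1).any():
            raise ValueError("representative sets are not disjoint")
        pinned[idx] = j
    is_pinned = pinned >= 0

    labels = np.full(n, -1, dtype=int)
    sq = (values**2).sum(axis=1, keepdims=True)
    history: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d2 = sq - 2.0 * values @ centroids.T + (centroids**2).sum(axis=1)
        new_labels = np.argmin(d2, axis=1)  # ties -> lowest index
        new_labels[is_pinned] = pinned[is_pinned]
        free = ~is_pinned
        history.append(float(np.take_along_axis(d2[free], new_labels[free, None], axis=1).sum()))
        if np.array_equal(new_labels, labels):
            converged = True
            break
        labels = new_labels
        for j in range(k):
            members = labels == j
            if members.any():
                centroids[j] = values[members].mean(axis=0)
            else:
                warnings.warn(f"cluster {label_names[j]} emptied; keeping previous centroid")
    return ClusterState(
        labels=labels,
        centroids=centroids,
        label_names=list(label_names),
        n_iter=n_iter,
        converged=converged,
        objective_history=history,
    )
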
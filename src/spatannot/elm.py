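"""Extreme learning machine classifier and ROI-level data splitting.

The classifier is a single-hidden-layer feed-forward network whose input
weights and biases are drawn once from standard normal distributions and
never updated; only the output layer is learned, in closed form, as
``W_out = pinv(H) @ Y`` where ``H = phi(X @ W_in + b_in)`` is the hidden
activation matrix and ``Y`` the one-hot training labels.  The
Moore-Penrose pseudo-inverse gives the minimum-norm least-squares
solution in a single step — no backpropagation, no tuning — which is why
training scales to millions of cells.

Splitting is always at the ROI level (cells of one imaged region never
straddle the train/test boundary), optionally stratified by disease
status so each cohort contributes equally to both halves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .io import AnnotationTable, IntensityTable, TrainedAnnotator, ValidationError
from .preprocessing import NormalizedMatrix

__all__ = [
    "ELMConfig",
    "SplitPlan",
    "ACTIVATIONS",
    "split_rois",
    "elm_train",
    "elm_predict",
]

ACTIVATIONS = {
    "sigmoid": expit,
    "tanh": np.tanh,
    "relu": lambda z: np.maximum(z, 0.0),
}


@dataclass
class ELMConfig:
    """Hidden layer size, activation and seed for the random projection.

    ``n_hidden=None`` resolves to ``min(1024, 8 * P)`` for a P-protein
    panel — enough capacity for tens of proteins while keeping the
    pseudo-inverse cheap.
    """

    n_hidden: int | None = None
    activation: str = "sigmoid"
    seed: int = 0

    def resolve_hidden(self, n_proteins: int) -> int:
        if self.n_hidden is not None:
            if self.n_hidden < 1:
                raise ValueError("n_hidden must be positive")
            return int(self.n_hidden)
        return min(1024, 8 * n_proteins)

    def activation_fn(self):
        try:
            return ACTIVATIONS[self.activation]
        except KeyError:
            raise ValueError(
                f"unknown activation '{self.activation}'; choose from {sorted(ACTIVATIONS)}"
            ) from None


@dataclass
class SplitPlan:
    """Disjoint train/test ROI id sets covering the whole dataset."""

    train_rois: list[str]
    test_rois: list[str]
    stratify_by: str | None = None

    def __post_init__(self) -> None:
        if set(self.train_rois) & set(self.test_rois):
            raise ValueError("train and test ROI sets overlap")

    def train_mask(self, roi_ids: np.ndarray) -> np.ndarray:
        return np.isin(np.asarray(roi_ids, dtype=object), list(self.train_rois))


def split_rois(
    table: IntensityTable,
    frac: float = 0.5,
    stratify: bool = False,
    seed: int = 0,
) -> SplitPlan:
    """Assign each ROI (never individual cells) to the train or test half.

    With ``stratify=True`` the split is drawn within each disease-status
    stratum so both halves contain the same share of every cohort; a
    stratum with a single ROI goes to the training set with a warning.
    Deterministic given ``seed``.
    """
    if not 0 < frac < 1:
        raise ValueError(f"train fraction must be in (0, 1), got {frac}")
    rois = sorted(set(map(str, table.roi_ids)))
    if len(rois) < 2:
        raise ValidationError("need at least 2 ROIs to split")
    rng = np.random.default_rng(seed)

    if stratify:
        if table.status is None:
            raise ValidationError("stratified split requested but no status column present")
        roi_status: dict[str, str] = {}
        for roi, st in zip(map(str, table.roi_ids), map(str, table.status)):
            roi_status.setdefault(roi, st)
        strata: dict[str, list[str]] = {}
        for roi in rois:
            strata.setdefault(roi_status[roi], []).append(roi)
        train: list[str] = []
        test: list[str] = []
        for status in sorted(strata):
            group = strata[status]
            if len(group) == 1:
                warnings.warn(
                    f"status '{status}' has a single ROI; assigning it to the training set"
                )
                train.extend(group)
                continue
            perm = rng.permutation(len(group))
            n_train = int(round(frac * len(group)))
            n_train = min(max(n_train, 1), len(group) - 1)
            train.extend(group[i] for i in perm[:n_train])
            test.extend(group[i] for i in perm[n_train:])
        if not test:
            # every stratum was singleton; fall back to an unstratified holdout
            moved = train.pop()
            test.append(moved)
        return SplitPlan(sorted(train), sorted(test), stratify_by="status")

    perm = rng.permutation(len(rois))
    n_train = int(round(frac * len(rois)))
    n_train = min(max(n_train, 1), len(rois) - 1)
    train = sorted(rois[i] for i in perm[:n_train])
    test = sorted(rois[i] for i in perm[n_train:])
    return SplitPlan(train, test)


def _one_hot(labels: np.ndarray, label_order: list[str]) -> np.ndarray:
    index = {lab: j for j, lab in enumerate(label_order)}
    onehot = np.zeros((len(labels), len(label_order)))
    for i, lab in enumerate(labels):
        try:
            onehot[i, index[lab]] = 1.0
        except KeyError:
            raise ValidationError(f"training label '{lab}' not in the fixed label order") from None
    return onehot


def elm_train(
    X_train: NormalizedMatrix,
    labels: np.ndarray,
    label_order: list[str],
    cfg: ELMConfig | None = None,
    pseudo_count: float = 1.0,
    train_rois: list[str] | None = None,
) -> TrainedAnnotator:
    """Closed-form training of the output layer.

    ``labels`` are the per-row training labels (strings from
    ``label_order``, typically the constrained-K-means output).  The
    returned model freezes the label order, the panel, the random input
    layer and the solved output weights.
    """
    if X_train.provenance != "unit":
        raise ValidationError(
            f"training matrix must be unit-normalized, got {X_train.provenance!r}"
        )
    cfg = cfg or ELMConfig()
    phi = cfg.activation_fn()
    n, p = X_train.values.shape
    h = cfg.resolve_hidden(p)
    if h > n:
        warnings.warn(
            f"n_hidden={h} exceeds n_train={n}; the system is underdetermined "
            "(pseudo-inverse still yields the minimum-norm solution)"
        )
    rng = np.random.default_rng(cfg.seed)
    W_in = rng.standard_normal((p, h))
    b_in = rng.standard_normal(h)
    H = phi(X_train.values @ W_in + b_in)
    Y = _one_hot(np.asarray(labels, dtype=object), label_order)
    # SVD pseudo-inverse with relative cutoff 1e-12 * sigma_max for
    # stability on collinear channels
    W_out = np.linalg.pinv(H, rcond=1e-12) @ Y
    return TrainedAnnotator(
        labels=list(label_order),
        protein_names=list(X_train.protein_names),
        W_in=W_in,
        b_in=b_in,
        W_out=W_out,
        activation=cfg.activation,
        pseudo_count=pseudo_count,
        unit_norm=True,
        seed=cfg.seed,
        train_rois=list(train_rois or []),
    )


def elm_hidden(model: TrainedAnnotator, values: np.ndarray) -> np.ndarray:
    """Hidden-layer activations for an already-normalized matrix."""
    phi = ACTIVATIONS[model.activation]
    return phi(np.asarray(values, dtype=float) @ model.W_in + model.b_in)


def elm_scores(model: TrainedAnnotator, X: NormalizedMatrix) -> np.ndarray:
    """Raw per-label network outputs (cells x labels)."""
    if list(X.protein_names) != list(model.protein_names):
        missing = sorted(set(model.protein_names) - set(X.protein_names))
        extra = sorted(set(X.protein_names) - set(model.protein_names))
        raise ValidationError(
            f"protein panel mismatch: missing {missing}, unexpected {extra} "
            "(order must match training)"
        )
    return elm_hidden(model, X.values) @ model.W_out


def elm_predict(
    model: TrainedAnnotator,
    X: NormalizedMatrix,
    cell_ids: np.ndarray | None = None,
    roi_ids: np.ndarray | None = None,
    min_score: float | None = None,
) -> AnnotationTable:
    """Label cells by the argmax network output (ties to the lowest index).

    The Unknown cluster, when trained, competes as an ordinary class.  An
    optional ``min_score`` relabels low-confidence argmax winners as
    Unknown; the default is pure argmax.
    """
    scores = elm_scores(model, X)
    winners = np.argmax(scores, axis=1)
    win_scores = scores[np.arange(len(winners)), winners]
    labels = np.asarray(model.labels, dtype=object)[winners]
    if min_score is not None:
        from .io import UNKNOWN_LABEL

        labels = labels.copy()
        labels[win_scores < min_score] = UNKNOWN_LABEL
    n = len(labels)
    if cell_ids is None:
        cell_ids = np.array([f"cell{i}" for i in range(n)], dtype=object)
    if roi_ids is None:
        roi_ids = np.array([""] * n, dtype=object)
    return AnnotationTable(
        cell_ids=np.asarray(cell_ids, dtype=object),
        roi_ids=np.asarray(roi_ids, dtype=object),
        labels=labels,
        sources=np.array(["classified"] * n, dtype=object),
        scores=win_scores,
    )
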
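"""End-to-end annotation pipeline.

``train_annotator`` wires the full training path: pseudo-count log +
unit normalization, ROI-level train/test split, abundance-ordered marker
gating, constrained K-means on the training half, and closed-form
classifier training on the resulting labels.  ``annotate`` applies a
frozen model to any cell table with a matching panel — new ROIs are
labeled without re-clustering or re-training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .annotator import (
    GateConfig,
    abundance_order,
    constrained_kmeans,
    marker_score,
    seed_centroids,
    select_representatives,
)
from .elm import ELMConfig, SplitPlan, elm_predict, elm_train, split_rois
from .io import (
    AnnotationTable,
    IntensityTable,
    MarkerSpec,
    TrainedAnnotator,
    UNKNOWN_LABEL,
)
from .preprocessing import log_pseudocount, unit_normalize

__all__ = [
    "TrainingResult",
    "adaptive_q_high",
    "train_annotator",
    "annotate",
]


@dataclass
class TrainingResult:
    model: TrainedAnnotator
    train_annotations: AnnotationTable
    split: SplitPlan
    abundance_order: list[str] = field(default_factory=list)


def adaptive_q_high(
    proportions: dict[str, float],
    floor: float = 95.0,
    ceiling: float = 99.9,
) -> dict[str, float]:
    """Abundance-informed gate percentiles.

    When the expected abundance of each type is known a priori, gating at
    ``100 * (1 - proportion / 2)`` targets roughly the top half of the
    expected positive population, clipped to [floor, ceiling] so abundant
    types keep a generous gate and rare types a stringent one.
    """
    return {
        ct: float(np.clip(100.0 * (1.0 - p / 2.0), floor, ceiling))
        for ct, p in proportions.items()
    }


def train_annotator(
    table: IntensityTable,
    spec: MarkerSpec,
    gate: GateConfig | None = None,
    elm_cfg: ELMConfig | None = None,
    frac: float = 0.5,
    stratify: bool = False,
    seed: int = 0,
    pseudo_count: float = 1.0,
) -> TrainingResult:
    """Train a cell-type annotator without any manually labeled cells.

    The split seed doubles as the classifier seed unless an explicit
    ``ELMConfig`` is given.  Returns the frozen model plus the training
    half's labels (sources ``representative`` for gated cells,
    ``clustered`` for the rest).
    """
    gate = gate or GateConfig()
    elm_cfg = elm_cfg or ELMConfig(seed=seed)
    spec.validate_panel(table.protein_names)

    split = split_rois(table, frac=frac, stratify=stratify, seed=seed)
    train_mask = split.train_mask(table.roi_ids)
    train_idx = np.flatnonzero(train_mask)
    X_tr = unit_normalize(log_pseudocount(table.subset(train_mask), pseudo=pseudo_count))

    order = abundance_order(X_tr, spec)
    scores = {ct: marker_score(X_tr, spec, ct) for ct in spec.cell_types}
    reps = select_representatives(scores, gate, order, include_unknown=spec.include_unknown)

    labels = list(spec.cell_types)
    if spec.include_unknown:
        if reps.unknown is not None and reps.unknown.size > 0:
            labels.append(UNKNOWN_LABEL)
        else:
            warnings.warn("dropping the Unknown cluster: no seed cells")
    rep_sets = reps.sets_for(labels)
    centroids = seed_centroids(X_tr.values, rep_sets)
    state = constrained_kmeans(
        X_tr.values, rep_sets, centroids, max_iter=gate.max_iter, label_names=labels
    )

    train_labels = state.label_strings()
    sources = np.array(["clustered"] * len(train_labels), dtype=object)
    for idx in rep_sets:
        sources[idx] = "representative"

    model = elm_train(
        X_tr,
        train_labels,
        labels,
        cfg=elm_cfg,
        pseudo_count=pseudo_count,
        train_rois=split.train_rois,
    )
    ann = AnnotationTable(
        cell_ids=table.cell_ids[train_idx],
        roi_ids=table.roi_ids[train_idx],
        labels=train_labels,
        sources=sources,
    )
    return TrainingResult(model=model, train_annotations=ann, split=split,
                          abundance_order=order)


def annotate(model: TrainedAnnotator, table: IntensityTable) -> AnnotationTable:
    """Apply a frozen model to a cell table (training preprocessing replayed)."""
    X = log_pseudocount(table, pseudo=model.pseudo_count)
    if model.unit_norm:
        X = unit_normalize(X)
    return elm_predict(model, X, cell_ids=table.cell_ids, roi_ids=table.roi_ids)
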
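"""Intensity transformations.

Two pipelines live here:

1. the annotation pipeline's ``ln(e + 1)`` pseudo-count log followed by
   per-cell l2 unit normalization, which projects every cell onto the unit
   sphere so Euclidean distances track cosine similarity in proteomic
   space; and
2. a TF-IDF-style display normalization that min-max scales each protein
   between its 0.01th and 99.99th percentile and then down-weights
   proteins abundant across many cell types (non-specific antibodies) by
   the factor ln(p_total / p_sum).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import IntensityTable

__all__ = [
    "NormalizedMatrix",
    "PipelineOrderError",
    "log_pseudocount",
    "unit_normalize",
    "tfidf_minmax",
]


class PipelineOrderError(ValueError):
    """The transformations were applied out of their defined order."""


@dataclass
class NormalizedMatrix:
    """A cells x proteins matrix tagged with its transformation provenance."""

    values: np.ndarray
    protein_names: list[str]
    provenance: str  # raw | log1p | unit | tfidf
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("normalized matrix must be 2-D")
        if self.values.shape[1] != len(self.protein_names):
            raise ValueError("protein name list does not match matrix width")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def column(self, protein: str) -> np.ndarray:
        return self.values[:, self.protein_names.index(protein)]


def log_pseudocount(raw: IntensityTable, pseudo: float = 1.0) -> NormalizedMatrix:
    """Elementwise ``ln(e + pseudo)`` of the raw channel intensities.

    The pseudo-count guards the log at zero intensity and the natural log
    compresses the heavy right tail typical of IMC/CODEX channels.
    """
    if pseudo <= 0:
        raise ValueError(f"pseudo-count must be positive, got {pseudo}")
    if isinstance(raw, NormalizedMatrix):
        raise PipelineOrderError(
            "log_pseudocount applies to raw intensities, not an already "
            f"normalized matrix (provenance={raw.provenance!r})"
        )
    values = np.log(raw.intensities + pseudo)
    return NormalizedMatrix(
        values=values,
        protein_names=list(raw.protein_names),
        provenance="log1p",
        params={"pseudo_count": float(pseudo)},
    )


def unit_normalize(m: NormalizedMatrix) -> NormalizedMatrix:
    """Scale each cell's vector to unit l2 length.

    All-zero cells (segmentation artifacts with no signal) are left as
    zeros rather than NaN; they end up in the Unknown class downstream.
    Idempotent on its own output.
    """
    if not isinstance(m, NormalizedMatrix) or m.provenance not in ("log1p", "unit"):
        prov = getattr(m, "provenance", type(m).__name__)
        raise PipelineOrderError(
            f"unit_normalize expects the log-transformed matrix, got {prov!r}; "
            "apply log_pseudocount first"
        )
    norms = np.linalg.norm(m.values, axis=1, keepdims=True)
    safe = np.where(norms == 0, 1.0, norms)
    return NormalizedMatrix(
        values=m.values / safe,
        protein_names=list(m.protein_names),
        provenance="unit",
        params=dict(m.params),
    )


def tfidf_minmax(
    raw: IntensityTable,
    lo_pct: float = 0.01,
    hi_pct: float = 99.99,
    labels: np.ndarray | None = None,
) -> NormalizedMatrix:
    """Percentile min-max scaling followed by inverse-abundance weighting.

    Each protein column is scaled to [0, 1] between its ``lo_pct`` and
    ``hi_pct`` percentiles (values outside are clipped), then multiplied
    by ``ln(p_total / p_sum)`` where ``p_sum`` is that protein's scaled
    abundance — aggregated as per-cell-type means when ``labels`` are
    supplied, else summed across all cells — and ``p_total`` is the grand
    total over proteins.  Proteins abundant in every cell type (sticky,
    non-specific antibodies) receive weights near zero.
    """
    if not lo_pct < hi_pct:
        raise ValueError(f"lo_pct must be < hi_pct, got {lo_pct} >= {hi_pct}")
    values = raw.intensities.astype(float).copy()
    lo = np.percentile(values, lo_pct, axis=0)
    hi = np.percentile(values, hi_pct, axis=0)
    span = hi - lo
    constant = span == 0
    if constant.any():
        names = [p for p, c in zip(raw.protein_names, constant) if c]
        warnings.warn(f"constant protein column(s) scaled to zero: {names}")
    safe_span = np.where(constant, 1.0, span)
    scaled = np.clip((values - lo) / safe_span, 0.0, 1.0)
    scaled[:, constant] = 0.0

    if labels is None:
        p_sum = scaled.sum(axis=0)
    else:
        labels = np.asarray(labels)
        groups = np.unique(labels)
        p_sum = np.zeros(scaled.shape[1])
        for g in groups:
            p_sum += scaled[labels == g].mean(axis=0)
    p_total = p_sum.sum()
    zero_sum = p_sum == 0
    if zero_sum.any():
        names = [p for p, z in zip(raw.protein_names, zero_sum) if z]
        warnings.warn(f"protein(s) with zero abundance get weight 0: {names}")
    weight = np.where(zero_sum, 0.0, np.log(p_total / np.where(zero_sum, 1.0, p_sum)))
    return NormalizedMatrix(
        values=scaled * weight,
        protein_names=list(raw.protein_names),
        provenance="tfidf",
        params={
            "lo_pct": float(lo_pct),
            "hi_pct": float(hi_pct),
            "weights": weight,
            "by_label": labels is not None,
        },
    )
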
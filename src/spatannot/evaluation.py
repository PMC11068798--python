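"""Benchmarking utilities.

Three independent ways of judging an annotation without ground truth:

* **Silhouette homogeneity** — how cohesive the protein-expression
  profiles of same-labeled cells are, averaged over repeated random
  subsamples (silhouette is O(n²), so it is evaluated on subsets).
* **Composition concordance** — the symmetrized (minimum-direction) KL
  divergence between two cell-type composition distributions, with a
  fixed discordance cutoff of 0.4 nats.
* **Cluster labeling by differential expression** — the procedure used to
  assign cell-type names to unsupervised clusters: one-vs-rest
  Mann-Whitney U per protein, scored by −log10(p) · log2FC, with the
  top-scoring protein looked up among the positive markers in marker-file
  order.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import rel_entr
from scipy.stats import mannwhitneyu
from sklearn.metrics import silhouette_samples

from .io import IntensityTable, MarkerSpec, UNKNOWN_LABEL

__all__ = [
    "silhouette_benchmark",
    "kl_concordance",
    "label_clusters_by_de",
]


def silhouette_benchmark(
    values: np.ndarray,
    labels: np.ndarray,
    n_cells: int = 50_000,
    n_sets: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-label silhouette mean and sd over random cell subsamples.

    Euclidean distances in the supplied (normalized) space.  A label
    absent from a subsample contributes NaN for that set; labels must be
    at least two per sampled set for the silhouette to be defined.
    Deterministic given ``seed``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=object)
    n = len(labels)
    rng = np.random.default_rng(seed)
    unique = sorted(map(str, set(labels)))
    per_set = np.full((n_sets, len(unique)), np.nan)
    for s in range(n_sets):
        idx = rng.choice(n, size=min(n_cells, n), replace=False)
        sub_labels = labels[idx]
        present = np.unique(sub_labels)
        if len(present) < 2:
            warnings.warn(f"subsample {s} contains a single label; silhouette undefined")
            continue
        sil = silhouette_samples(values[idx], sub_labels.astype(str))
        for j, lab in enumerate(unique):
            mask = sub_labels == lab
            if mask.any():
                per_set[s, j] = sil[mask].mean()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN labels
        out = pd.DataFrame(
            {"mean": np.nanmean(per_set, axis=0), "sd": np.nanstd(per_set, axis=0)},
            index=pd.Index(unique, name="label"),
        )
    return out


def kl_concordance(
    p,
    q,
    threshold: float = 0.4,
    eps: float = 1e-6,
) -> dict:
    """Minimum-direction KL divergence with a discordance decision.

    ``p`` and ``q`` are compositions over the same category set (dicts or
    arrays); both are epsilon-smoothed (``eps`` added, renormalized) so
    empty categories do not make the divergence infinite.  The divergence
    is ``min(KL(p||q), KL(q||p))`` in nats — symmetric in its arguments —
    and the pair is concordant iff it is <= ``threshold``.
    """
    if isinstance(p, dict) or isinstance(q, dict):
        if not isinstance(p, dict) or not isinstance(q, dict):
            raise ValueError("p and q must both be dicts or both arrays")
        cats = sorted(set(p) | set(q))
        p = np.array([p.get(c, 0.0) for c in cats], dtype=float)
        q = np.array([q.get(c, 0.0) for c in cats], dtype=float)
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("compositions must share the category set")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("compositions must be nonnegative")
    ps = (p + eps) / (p + eps).sum()
    qs = (q + eps) / (q + eps).sum()
    kl_pq = float(rel_entr(ps, qs).sum())
    kl_qp = float(rel_entr(qs, ps).sum())
    divergence = min(kl_pq, kl_qp)
    return {"divergence": divergence, "concordant": divergence <= threshold}


def composition_from_labels(labels: np.ndarray, categories: list[str]) -> dict[str, float]:
    """Proportions of each category among the given labels (others ignored)."""
    labels = np.asarray(labels, dtype=object)
    counts = np.array([np.sum(labels == c) for c in categories], dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("no cells from the requested categories")
    return dict(zip(categories, counts / total))


def label_clusters_by_de(
    table: IntensityTable,
    cluster_ids: np.ndarray,
    spec: MarkerSpec,
) -> tuple[dict, pd.DataFrame]:
    """Name unsupervised clusters from one-vs-rest differential expression.

    For each cluster and protein, a two-sided Mann-Whitney U test of the
    cluster's cells against all others gives p, and the log2 fold change
    of (pseudo-count 1) mean intensities gives the direction; the score is
    ``−log10(p) · log2FC``.  Each cluster is assigned the first cell type
    (marker-file order) whose positive markers contain the cluster's
    top-scoring protein, else Unknown.

    Returns ``(cluster -> label, long-format score table)``.
    """
    cluster_ids = np.asarray(cluster_ids)
    clusters = list(pd.unique(cluster_ids))
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    X = table.intensities
    rows = []
    assignment: dict = {}
    tiny = np.finfo(float).tiny
    for cl in clusters:
        mask = cluster_ids == cl
        best_score, best_protein = -np.inf, None
        for j, protein in enumerate(table.protein_names):
            inside, outside = X[mask, j], X[~mask, j]
            if np.ptp(X[:, j]) == 0:
                p_val, fc = 1.0, 0.0
            else:
                p_val = float(mannwhitneyu(inside, outside, alternative="two-sided").pvalue)
                fc = float(np.log2((inside.mean() + 1.0) / (outside.mean() + 1.0)))
            score = -np.log10(max(p_val, tiny)) * fc
            rows.append(
                {"cluster": cl, "protein": protein, "pvalue": p_val,
                 "log2fc": fc, "score": score}
            )
            if score > best_score:
                best_score, best_protein = score, protein
        label = UNKNOWN_LABEL
        for ct in spec.cell_types:  # marker-file order is the assignment order
            if best_protein in spec.positive.get(ct, []):
                label = ct
                break
        assignment[cl] = label
    return assignment, pd.DataFrame(rows)
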
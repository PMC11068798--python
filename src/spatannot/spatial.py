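"""Marked-point-process quantification of inter-cell-type proximity.

Cells inside an ROI are treated as a marked point pattern: locations
``psi_i`` in a rectangular observation window ``W`` carrying categorical
marks ``m_i`` (the annotated cell type).  The dependence between two
types ``a`` and ``b`` at inter-point distance ``r`` is measured by the
mark cross-correlation function

    k_mm(r) = E_{i,j}[ 1(m_i = a) 1(m_j = b) | ‖psi_i − psi_j‖ = r ]
              / (p_a * p_b),

the conditional probability that a pair at distance ``r`` carries the
mark combination (a, b), normalized by its expectation ``p_a p_b`` under
mark independence.  Under random mark labeling ``k_mm(r) ≡ 1``; values
above 1 indicate aggregation of the two types at that distance, values
below 1 repulsion.

The estimator kernel-smooths pair contributions in distance (Epanechnikov
kernel, Stoyan's rule-of-thumb bandwidth ``0.15 / sqrt(lambda)`` with
``lambda = n/|W|`` by default) and applies the translation edge
correction ``|W| / ((x1−x0−|dx|)(y1−y0−|dy|))`` to each pair.  Pairwise
distances are computed densely, so per-ROI patterns up to a few tens of
thousands of points are practical.

Each curve is summarized by the distance at its maximum (smaller under
tighter aggregation) and by ``ln(max_r k / argmax_r k)`` (larger under
tighter aggregation); summaries are compared across cohorts of ROIs by
Kruskal-Wallis followed by pairwise Mann-Whitney U tests.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import kruskal, mannwhitneyu

from .io import UNKNOWN_LABEL, AnnotationTable, IntensityTable, ValidationError

__all__ = [
    "MarkedPointPattern",
    "MarkCrossCorrCurve",
    "CurveSummary",
    "build_pattern",
    "patterns_from_annotations",
    "mark_cross_correlation",
    "random_labeling_mean",
    "summarize_curve",
    "interaction_count",
    "compare_cohorts",
    "write_curves",
    "read_curves",
    "write_pattern",
    "read_pattern",
    "group_marks",
]

DEFAULT_N_R = 512


@dataclass
class MarkedPointPattern:
    """Point locations with categorical marks in a rectangular window."""

    points: np.ndarray  # (n, 2)
    marks: np.ndarray  # (n,) strings
    window: tuple[float, float, float, float]  # x0, x1, y0, y1
    roi_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.marks = np.asarray(self.marks, dtype=object)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValidationError("points must be an (n, 2) array")
        if len(self.points) == 0:
            raise ValidationError("point pattern is empty")
        if len(self.marks) != len(self.points):
            raise ValidationError("marks length does not match points")
        x0, x1, y0, y1 = self.window
        if not (x1 > x0 and y1 > y0):
            raise ValidationError(f"degenerate window {self.window}")
        inside = (
            (self.points[:, 0] >= x0)
            & (self.points[:, 0] <= x1)
            & (self.points[:, 1] >= y0)
            & (self.points[:, 1] <= y1)
        )
        if not inside.all():
            i = int(np.flatnonzero(~inside)[0])
            raise ValidationError(f"point {i} at {tuple(self.points[i])} lies outside the window")

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def area(self) -> float:
        x0, x1, y0, y1 = self.window
        return (x1 - x0) * (y1 - y0)

    @property
    def intensity(self) -> float:
        """Expected points per unit area (the homogeneous estimate n/|W|)."""
        return self.n / self.area

    def mark_fraction(self, mark: str) -> float:
        return float(np.mean(self.marks == mark))

    def default_bandwidth(self) -> float:
        """Stoyan's rule of thumb 0.15 / sqrt(intensity)."""
        return 0.15 / np.sqrt(self.intensity)

    def default_r_grid(self, bandwidth: float | None = None, n_r: int = DEFAULT_N_R) -> np.ndarray:
        x0, x1, y0, y1 = self.window
        h = bandwidth if bandwidth is not None else self.default_bandwidth()
        r_max = min(x1 - x0, y1 - y0) / 4.0
        if r_max <= h:
            r_max = 2 * h
        return np.linspace(h, r_max, n_r)


@dataclass
class MarkCrossCorrCurve:
    type_a: str
    type_b: str
    r: np.ndarray
    k: np.ndarray
    bandwidth: float
    edge_correction: str
    n_pairs: np.ndarray
    roi_id: str = ""


@dataclass
class CurveSummary:
    """Scalar summaries of one estimated curve."""

    argmax_r: float
    max_k: float
    logratio: float  # ln(max_k / argmax_r)


def build_pattern(
    x: np.ndarray,
    y: np.ndarray,
    labels: np.ndarray,
    window: tuple[float, float, float, float] | None = None,
    roi_id: str = "",
    exclude_unknown: bool = True,
) -> MarkedPointPattern:
    """Assemble a marked point pattern from coordinates and labels.

    The window defaults to the axis-aligned bounding box of the points
    (exported cell tables carry no window metadata); an explicit window
    must contain every point.  Unknown-labeled cells are excluded by
    default — they are a residual class, not a biological type.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    labels = np.asarray(labels, dtype=object)
    keep = np.ones(len(x), dtype=bool)
    if exclude_unknown:
        keep = labels != UNKNOWN_LABEL
    if not keep.any():
        raise ValidationError("no cells left after excluding Unknown labels")
    pts = np.column_stack([x[keep], y[keep]])
    if window is None:
        window = (pts[:, 0].min(), pts[:, 0].max(), pts[:, 1].min(), pts[:, 1].max())
    return MarkedPointPattern(points=pts, marks=labels[keep], window=window, roi_id=roi_id)


def patterns_from_annotations(
    table: IntensityTable,
    annotations: AnnotationTable,
    exclude_unknown: bool = True,
    mark_groups: dict[str, str] | None = None,
) -> dict[str, MarkedPointPattern]:
    """One pattern per ROI, joining coordinates with annotation labels.

    ``mark_groups`` optionally maps labels onto composite marks (e.g.
    all endocrine types onto "islet") before pattern construction.
    """
    label_by_cell = dict(zip(annotations.cell_ids, annotations.labels))
    patterns: dict[str, MarkedPointPattern] = {}
    for roi in sorted(set(map(str, table.roi_ids))):
        mask = np.asarray([str(r) == roi for r in table.roi_ids])
        cells = table.cell_ids[mask]
        labels = np.array([label_by_cell.get(c, UNKNOWN_LABEL) for c in cells], dtype=object)
        if mark_groups:
            labels = group_marks(labels, mark_groups)
        try:
            patterns[roi] = build_pattern(
                table.x[mask], table.y[mask], labels, roi_id=roi,
                exclude_unknown=exclude_unknown,
            )
        except ValidationError:
            warnings.warn(f"ROI '{roi}' has no annotated cells; skipped")
    return patterns


def group_marks(labels: np.ndarray, mark_groups: dict[str, str]) -> np.ndarray:
    """Map individual labels onto composite marks (e.g. endocrine -> islet)."""
    return np.array([mark_groups.get(str(l), str(l)) for l in labels], dtype=object)


# ---------------------------------------------------------------------------
# estimator internals
# ---------------------------------------------------------------------------

def _pair_geometry(pattern: MarkedPointPattern, edge_correction: str):
    """Condensed upper-triangle pair distances and edge weights, sorted by
    distance.  Returns (d, w, i_idx, j_idx) in ascending distance order."""
    if edge_correction not in ("translation", "none"):
        raise ValueError(f"unknown edge correction '{edge_correction}'")
    pts = pattern.points
    n = pattern.n
    iu, ju = np.triu_indices(n, k=1)
    dx = pts[iu, 0] - pts[ju, 0]
    dy = pts[iu, 1] - pts[ju, 1]
    d = np.hypot(dx, dy)
    if edge_correction == "translation":
        x0, x1, y0, y1 = pattern.window
        denom = (x1 - x0 - np.abs(dx)) * (y1 - y0 - np.abs(dy))
        # a pair spanning the full window (boundary points) has zero overlap
        # area; its distance exceeds any admissible r, so weight it out
        with np.errstate(divide="ignore"):
            w = np.where(denom > 0, (x1 - x0) * (y1 - y0) / np.where(denom > 0, denom, 1.0), 0.0)
    else:
        w = np.ones_like(d)
    order = np.argsort(d, kind="stable")
    return d[order], w[order], iu[order], ju[order]


def _epanechnikov(u: np.ndarray, h: float) -> np.ndarray:
    return 0.75 * (1.0 - (u / h) ** 2) / h


def _curve_from_pairs(d, kw, z, r_grid, h, pa_pb):
    """Evaluate the kernel estimate on the grid.

    ``kw`` are kernel-ready pair weights (edge correction), ``z`` the
    per-unordered-pair ordered-mark-match counts in {0, 1, 2}.
    """
    k = np.full(len(r_grid), np.nan)
    n_pairs = np.zeros(len(r_grid), dtype=int)
    lo = np.searchsorted(d, r_grid - h, side="right")
    hi = np.searchsorted(d, r_grid + h, side="left")
    for b, r in enumerate(r_grid):
        s = slice(lo[b], hi[b])
        n_pairs[b] = hi[b] - lo[b]
        if n_pairs[b] == 0:
            continue
        kern = _epanechnikov(d[s] - r, h) * kw[s]
        den = 2.0 * kern.sum()
        if den <= 0:
            continue
        k[b] = (kern @ z[s]) / (den * pa_pb)
    return k, n_pairs


def _mark_match(marks_i, marks_j, a, b):
    """Ordered-pair mark matches per unordered pair: 1(m_i=a)1(m_j=b) +
    1(m_j=a)1(m_i=b), an integer in {0, 1, 2}."""
    za = (marks_i == a).astype(np.float64)
    zb = (marks_j == b).astype(np.float64)
    z = za * zb
    z += (marks_j == a).astype(np.float64) * (marks_i == b).astype(np.float64)
    return z


def mark_cross_correlation(
    pattern: MarkedPointPattern,
    a: str,
    b: str,
    r_grid: np.ndarray | None = None,
    bandwidth: float | None = None,
    edge_correction: str = "translation",
) -> MarkCrossCorrCurve:
    """Kernel estimate of the mark cross-correlation function k_mm(r).

    Bins of the distance grid to which no pair contributes are NaN.  If a
    mark is absent from the pattern the whole curve is NaN with a warning.
    """
    if bandwidth is None:
        bandwidth = pattern.default_bandwidth()
    if bandwidth <= 0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth}")
    if r_grid is None:
        r_grid = pattern.default_r_grid(bandwidth)
    r_grid = np.asarray(r_grid, dtype=float)
    if (r_grid <= 0).any():
        raise ValueError("r grid must be strictly positive")

    p_a = pattern.mark_fraction(a)
    p_b = pattern.mark_fraction(b)
    if p_a == 0 or p_b == 0:
        absent = [m for m, p in ((a, p_a), (b, p_b)) if p == 0]
        warnings.warn(f"mark(s) {absent} absent from pattern '{pattern.roi_id}'; curve is NaN")
        return MarkCrossCorrCurve(
            a, b, r_grid, np.full(len(r_grid), np.nan), bandwidth,
            edge_correction, np.zeros(len(r_grid), dtype=int), pattern.roi_id,
        )

    d, w, iu, ju = _pair_geometry(pattern, edge_correction)
    z = _mark_match(pattern.marks[iu], pattern.marks[ju], a, b)
    k, n_pairs = _curve_from_pairs(d, w, z, r_grid, bandwidth, p_a * p_b)
    return MarkCrossCorrCurve(a, b, r_grid, k, bandwidth, edge_correction, n_pairs, pattern.roi_id)


def random_labeling_mean(
    pattern: MarkedPointPattern,
    a: str,
    b: str,
    n_perm: int = 500,
    seed: int = 0,
    r_grid: np.ndarray | None = None,
    bandwidth: float | None = None,
    edge_correction: str = "translation",
):
    """Average k_mm(r) over uniformly random permutations of the marks.

    Monte-Carlo calibration check: under random mark labeling the
    expectation of k_mm is 1 at every distance, so the permutation mean
    should sit near 1 wherever enough pairs contribute.  The pair geometry
    is computed once and reused across permutations.

    Returns ``(r_grid, mean_k, n_pairs)``.
    """
    if bandwidth is None:
        bandwidth = pattern.default_bandwidth()
    if r_grid is None:
        r_grid = pattern.default_r_grid(bandwidth)
    r_grid = np.asarray(r_grid, dtype=float)

    p_a = pattern.mark_fraction(a)
    p_b = pattern.mark_fraction(b)
    if p_a == 0 or p_b == 0:
        raise ValidationError("both marks must be present for the permutation test")

    d, w, iu, ju = _pair_geometry(pattern, edge_correction)
    lo = np.searchsorted(d, r_grid - bandwidth, side="right")
    hi = np.searchsorted(d, r_grid + bandwidth, side="left")
    n_pairs = (hi - lo).astype(int)
    # precompute per-bin kernel*edge weights once
    bin_weights = [
        _epanechnikov(d[lo[i]:hi[i]] - r_grid[i], bandwidth) * w[lo[i]:hi[i]]
        for i in range(len(r_grid))
    ]
    bin_dens = np.array([2.0 * bw.sum() for bw in bin_weights])

    rng = np.random.default_rng(seed)
    total = np.zeros(len(r_grid))
    counts = np.zeros(len(r_grid), dtype=int)
    marks = pattern.marks
    for _ in range(n_perm):
        perm = rng.permutation(pattern.n)
        pm = marks[perm]
        z = _mark_match(pm[iu], pm[ju], a, b)
        for i in range(len(r_grid)):
            if n_pairs[i] == 0 or bin_dens[i] <= 0:
                continue
            total[i] += (bin_weights[i] @ z[lo[i]:hi[i]]) / (bin_dens[i] * p_a * p_b)
            counts[i] += 1
    mean_k = np.where(counts > 0, total / np.maximum(counts, 1), np.nan)
    return r_grid, mean_k, n_pairs


def summarize_curve(curve: MarkCrossCorrCurve) -> CurveSummary:
    """Scalar summaries over the finite part of the curve.

    ``argmax_r`` is the distance at the curve maximum (ties broken toward
    the smallest r); ``logratio = ln(max_k / argmax_r)``.  The former
    decreases and the latter increases with tighter aggregation.
    """
    finite = np.isfinite(curve.k)
    if not finite.any():
        raise ValidationError("no contributing pairs anywhere on the curve")
    k = np.where(finite, curve.k, -np.inf)
    i = int(np.argmax(k))  # first maximum -> smallest r
    max_k = float(curve.k[i])
    argmax_r = float(curve.r[i])
    with np.errstate(divide="ignore", invalid="ignore"):
        logratio = float(np.log(max_k / argmax_r)) if max_k > 0 else -np.inf
    return CurveSummary(argmax_r=argmax_r, max_k=max_k, logratio=logratio)


def interaction_count(
    pattern: MarkedPointPattern,
    a: str,
    b: str,
    k_neighbors: int = 3,
) -> float:
    """Fixed-neighborhood interaction fraction (nearest-neighbor baseline).

    Among type-``a`` cells, the fraction whose ``k_neighbors`` nearest
    cells (any type, self excluded) include at least one type-``b`` cell.
    A single number per ROI, insensitive to the distance scale of the
    interaction — the contrast case for the distance-resolved k_mm(r).
    """
    if pattern.n < k_neighbors + 1:
        raise ValidationError(
            f"need at least {k_neighbors + 1} points for {k_neighbors} neighbors"
        )
    a_mask = pattern.marks == a
    if not a_mask.any():
        warnings.warn(f"no cells of type '{a}' in pattern '{pattern.roi_id}'")
        return float("nan")
    tree = cKDTree(pattern.points)
    _, idx = tree.query(pattern.points[a_mask], k=k_neighbors + 1)
    neighbor_marks = pattern.marks[idx[:, 1:]]  # drop self
    has_b = (neighbor_marks == b).any(axis=1)
    return float(has_b.mean())


def compare_cohorts(summaries: pd.DataFrame, value: str = "value", cohort: str = "cohort"):
    """Kruskal-Wallis across cohorts of per-ROI summaries, then pairwise
    Mann-Whitney U tests.

    ``summaries`` is long-format with one row per ROI.  Cohorts with fewer
    than 2 ROIs are excluded with a warning.  If every observation is
    identical the global test is reported as statistic 0, p = 1.

    Returns a dict with keys ``kruskal`` (statistic, pvalue), ``medians``
    and ``pairwise`` (DataFrame cohort_a, cohort_b, pvalue).
    """
    groups: dict[str, np.ndarray] = {}
    for name, sub in summaries.groupby(cohort):
        vals = sub[value].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2:
            warnings.warn(f"cohort '{name}' has fewer than 2 ROIs; excluded")
            continue
        groups[str(name)] = vals
    if len(groups) < 2:
        raise ValidationError("need at least 2 cohorts with >= 2 ROIs each")

    names = sorted(groups)
    samples = [groups[n] for n in names]
    if np.ptp(np.concatenate(samples)) == 0:
        stat, p = 0.0, 1.0
    else:
        stat, p = kruskal(*samples)
    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            xi, xj = groups[names[i]], groups[names[j]]
            if np.ptp(np.concatenate([xi, xj])) == 0:
                mw_p = 1.0
            else:
                mw_p = float(mannwhitneyu(xi, xj, alternative="two-sided").pvalue)
            pairs.append({"cohort_a": names[i], "cohort_b": names[j], "pvalue": mw_p})
    return {
        "kruskal": {"statistic": float(stat), "pvalue": float(p)},
        "medians": {n: float(np.median(groups[n])) for n in names},
        "pairwise": pd.DataFrame(pairs, columns=["cohort_a", "cohort_b", "pvalue"]),
    }


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_curves(curves: list[MarkCrossCorrCurve], path) -> None:
    """Long CSV: roi_id, type_a, type_b, r, k, n_pairs."""
    rows = []
    for c in curves:
        for r, k, np_ in zip(c.r, c.k, c.n_pairs):
            rows.append(
                {"roi_id": c.roi_id, "type_a": c.type_a, "type_b": c.type_b,
                 "r": r, "k": k, "n_pairs": np_}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_curves(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_pattern(pattern: MarkedPointPattern, path) -> None:
    header = json.dumps({"window": list(pattern.window), "roi_id": pattern.roi_id})
    frame = pd.DataFrame(
        {"x": pattern.points[:, 0], "y": pattern.points[:, 1], "mark": pattern.marks}
    )
    with open(path, "w") as fh:
        fh.write(f"#{header}\n")
        frame.to_csv(fh, index=False)


def read_pattern(path) -> MarkedPointPattern:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValidationError("pattern file lacks the window header line")
        meta = json.loads(first[1:])
        frame = pd.read_csv(fh)
    return MarkedPointPattern(
        points=frame[["x", "y"]].to_numpy(dtype=float),
        marks=frame["mark"].astype(str).to_numpy(),
        window=tuple(meta["window"]),
        roi_id=meta.get("roi_id", ""),
    )
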
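"""Synthetic spatial-proteomics datasets with known ground truth.

The generator emulates the structure of an IMC/CODEX cell table well
enough to exercise every stage of the pipeline:

* continuous, nonnegative, right-skewed intensities — multiplicative
  lognormal noise around a per-(type, protein) ln-scale mean;
* marker structure — each cell type's positive markers get an ln-scale
  mean uplift, negative markers a depression, and a couple of "sticky"
  non-specific channels are elevated in every cell type;
* rare populations — the default panel includes a 0.5%-abundance type
  with a unique marker;
* spatial organization — per-type placement inside a rectangular ROI
  window: ``uniform`` (complete spatial randomness), ``cluster`` (a
  Thomas-style parent/offspring process producing islet-like aggregates)
  or ``infiltrate`` (points seeded near an already-placed target type,
  emulating immune infiltration).

Everything is reproducible from ``GeneratorConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import AnnotationTable, IntensityTable, MarkerSpec, write_marker_spec

__all__ = [
    "SpatialMode",
    "CellTypeConfig",
    "GeneratorConfig",
    "default_config",
    "generate_dataset",
    "generate_marker_file",
    "generate_reference_composition",
    "with_spatial_mode",
]


@dataclass
class SpatialMode:
    """Placement rule for one cell type inside the ROI window."""

    kind: str = "uniform"  # uniform | cluster | infiltrate
    n_parents: int = 5  # cluster: expected parents per ROI
    offspring_sd: float = 40.0  # cluster/infiltrate: Gaussian spread (window units)
    target: str | None = None  # infiltrate: the type whose points attract this one


@dataclass
class CellTypeConfig:
    name: str
    proportion: float
    positive: list[str]
    negative: list[str] = field(default_factory=list)
    spatial: SpatialMode = field(default_factory=SpatialMode)


@dataclass
class GeneratorConfig:
    """Study conditions for one simulated dataset."""

    cell_types: list[CellTypeConfig]
    proteins: list[str]
    n_rois: int = 10
    cells_per_roi: int = 5_000
    window: tuple[float, float, float, float] = (0.0, 1000.0, 0.0, 1000.0)
    marker_uplift: float = 4.0  # ln-scale mean shift of positive markers (~55x linear)
    negative_shift: float = 1.0  # ln-scale depression of negative markers
    sticky_proteins: list[str] = field(default_factory=list)
    sticky_uplift: float = 2.0
    base_log_mean: float = 0.0
    noise_sigma: float = 0.7  # ln-scale cell-to-cell sd
    status_by_roi: dict[str, str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(ct.proportion for ct in self.cell_types)
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"cell-type proportions sum to {total}, expected 1")
        if self.noise_sigma < 0 or self.marker_uplift < 0:
            raise ValueError("scales must be nonnegative")
        x0, x1, y0, y1 = self.window
        span = min(x1 - x0, y1 - y0)
        for ct in self.cell_types:
            if ct.spatial.kind in ("cluster", "infiltrate") and ct.spatial.offspring_sd > span:
                raise ValueError(
                    f"offspring sd {ct.spatial.offspring_sd} of '{ct.name}' exceeds the window"
                )
        names = [ct.name for ct in self.cell_types]
        if len(set(names)) != len(names):
            raise ValueError("duplicate cell type names")

    def marker_spec(self, include_unknown: bool = True) -> MarkerSpec:
        return MarkerSpec(
            cell_types=[ct.name for ct in self.cell_types],
            positive={ct.name: list(ct.positive) for ct in self.cell_types},
            negative={ct.name: list(ct.negative) for ct in self.cell_types},
            include_unknown=include_unknown,
        )


def default_config(seed: int = 0) -> GeneratorConfig:
    """The default 8-type pancreas-like panel.

    Endocrine-like types aggregate into islet-like clusters; the T-cell
    type infiltrates them; exocrine and myeloid types are spatially
    random.  One type ("epsilon") is rare at 0.5% abundance with a unique
    marker.  Two sticky channels (CD99-like, actin-like) are elevated
    everywhere and four channels are pure background.
    """
    islet = lambda: SpatialMode(kind="cluster", n_parents=6, offspring_sd=35.0)
    types = [
        CellTypeConfig("alpha", 0.30, ["GCG"], spatial=islet()),
        CellTypeConfig("acinar", 0.20, ["AMY"], spatial=SpatialMode()),
        CellTypeConfig("beta", 0.20, ["CPEP"], negative=["GCG"], spatial=islet()),
        CellTypeConfig("delta", 0.12, ["SST"], spatial=islet()),
        CellTypeConfig("ductal", 0.10, ["CA2"], spatial=SpatialMode()),
        CellTypeConfig(
            "tcell", 0.05, ["CD8"], negative=["CD68"],
            spatial=SpatialMode(kind="infiltrate", offspring_sd=45.0, target="beta"),
        ),
        CellTypeConfig("macrophage", 0.025, ["CD68"], spatial=SpatialMode()),
        CellTypeConfig("epsilon", 0.005, ["GHRL"], spatial=islet()),
    ]
    proteins = [
        "GCG", "CPEP", "SST", "GHRL", "AMY", "CA2", "CD8", "CD68",
        "CD99", "ACTB",  # sticky / non-specific
        "KI67", "CD4", "HLA", "IAPP",  # background-only channels
    ]
    return GeneratorConfig(
        cell_types=types,
        proteins=proteins,
        sticky_proteins=["CD99", "ACTB"],
        seed=seed,
    )


def _place_points(rng, mode: SpatialMode, n: int, window, anchors: np.ndarray | None):
    x0, x1, y0, y1 = window
    if mode.kind == "uniform" or n == 0:
        pts = np.column_stack(
            [rng.uniform(x0, x1, size=n), rng.uniform(y0, y1, size=n)]
        )
        return pts
    if mode.kind == "cluster":
        n_parents = max(1, rng.poisson(mode.n_parents))
        parents = np.column_stack(
            [rng.uniform(x0, x1, size=n_parents), rng.uniform(y0, y1, size=n_parents)]
        )
        assign = rng.integers(0, n_parents, size=n)
        pts = parents[assign] + rng.normal(0.0, mode.offspring_sd, size=(n, 2))
    elif mode.kind == "infiltrate":
        if anchors is None or len(anchors) == 0:
            # nothing to infiltrate; fall back to random placement
            return _place_points(rng, SpatialMode(), n, window, None)
        assign = rng.integers(0, len(anchors), size=n)
        pts = anchors[assign] + rng.normal(0.0, mode.offspring_sd, size=(n, 2))
    else:
        raise ValueError(f"unknown spatial mode '{mode.kind}'")
    pts[:, 0] = np.clip(pts[:, 0], x0, x1)
    pts[:, 1] = np.clip(pts[:, 1], y0, y1)
    return pts


def generate_dataset(cfg: GeneratorConfig):
    """Draw one dataset.

    Returns ``(IntensityTable, MarkerSpec, truth AnnotationTable)`` with
    truth labels carried as source ``clustered`` annotations.
    """
    rng = np.random.default_rng(cfg.seed)
    proteins = list(cfg.proteins)
    p_index = {p: j for j, p in enumerate(proteins)}
    type_names = [ct.name for ct in cfg.cell_types]
    proportions = np.array([ct.proportion for ct in cfg.cell_types])

    # per-(type, protein) ln-scale means
    log_means = np.full((len(type_names), len(proteins)), cfg.base_log_mean)
    for p in cfg.sticky_proteins:
        log_means[:, p_index[p]] += cfg.sticky_uplift
    for t, ct in enumerate(cfg.cell_types):
        for p in ct.positive:
            log_means[t, p_index[p]] += cfg.marker_uplift
        for p in ct.negative:
            log_means[t, p_index[p]] -= cfg.negative_shift

    # order types so infiltration targets are placed before their infiltrators
    placement_order = []
    remaining = list(range(len(cfg.cell_types)))
    while remaining:
        progressed = False
        for t in list(remaining):
            target = cfg.cell_types[t].spatial.target
            if target is None or target not in type_names or (
                type_names.index(target) in placement_order
            ):
                placement_order.append(t)
                remaining.remove(t)
                progressed = True
        if not progressed:
            raise ValueError("circular infiltration targets")

    cell_ids, roi_ids, xs, ys, labels, statuses = [], [], [], [], [], []
    intensity_blocks = []
    for r in range(cfg.n_rois):
        roi = f"roi{r:02d}"
        counts = rng.multinomial(cfg.cells_per_roi, proportions)
        placed: dict[int, np.ndarray] = {}
        for t in placement_order:
            ct = cfg.cell_types[t]
            anchors = None
            if ct.spatial.target is not None and ct.spatial.target in type_names:
                anchors = placed.get(type_names.index(ct.spatial.target))
            placed[t] = _place_points(rng, ct.spatial, counts[t], cfg.window, anchors)
        for t, ct in enumerate(cfg.cell_types):
            n_t = counts[t]
            if n_t == 0:
                continue
            pts = placed[t]
            noise = rng.normal(0.0, cfg.noise_sigma, size=(n_t, len(proteins)))
            block = np.exp(log_means[t] + noise)
            intensity_blocks.append(block)
            start = len(cell_ids)
            cell_ids.extend(f"{roi}_c{start + i}" for i in range(n_t))
            roi_ids.extend([roi] * n_t)
            xs.extend(pts[:, 0])
            ys.extend(pts[:, 1])
            labels.extend([ct.name] * n_t)
            if cfg.status_by_roi is not None:
                statuses.extend([cfg.status_by_roi.get(roi, "Control")] * n_t)

    table = IntensityTable(
        cell_ids=np.array(cell_ids, dtype=object),
        roi_ids=np.array(roi_ids, dtype=object),
        x=np.array(xs),
        y=np.array(ys),
        intensities=np.vstack(intensity_blocks),
        protein_names=proteins,
        status=np.array(statuses, dtype=object) if statuses else None,
    )
    truth = AnnotationTable(
        cell_ids=table.cell_ids.copy(),
        roi_ids=table.roi_ids.copy(),
        labels=np.array(labels, dtype=object),
        sources=np.array(["clustered"] * len(labels), dtype=object),
    )
    return table, cfg.marker_spec(), truth


def generate_marker_file(cfg: GeneratorConfig, path) -> None:
    """Emit the long-format markers.csv for this configuration."""
    write_marker_spec(cfg.marker_spec(), path)


def generate_reference_composition(
    truth: AnnotationTable,
    categories: list[str],
    path=None,
) -> pd.DataFrame:
    """Per-ROI composition over ``categories`` (rows sum to 1)."""
    rows = []
    for roi in sorted(set(map(str, truth.roi_ids))):
        mask = np.asarray([str(x) == roi for x in truth.roi_ids])
        labels = truth.labels[mask]
        counts = np.array([np.sum(labels == c) for c in categories], dtype=float)
        total = counts.sum()
        if total == 0:
            continue
        row = {"roi_id": roi}
        row.update(dict(zip(categories, counts / total)))
        rows.append(row)
    frame = pd.DataFrame(rows)
    if path is not None:
        frame.to_csv(path, index=False)
    return frame


def with_spatial_mode(cfg: GeneratorConfig, cell_type: str, mode: SpatialMode) -> GeneratorConfig:
    """Copy of the configuration with one type's placement rule replaced."""
    types = [
        replace(ct, spatial=mode) if ct.name == cell_type else ct for ct in cfg.cell_types
    ]
    return replace(cfg, cell_types=types)
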
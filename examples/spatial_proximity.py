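"""Quantify inter-cell-type proximity with mark cross-correlation curves.

Simulates two cohorts of ROIs: in one, a T-cell-like type infiltrates
islet-like clusters; in the other it is spatially random.  The distance
at the k_mm(r) maximum separates the cohorts — it is small under
infiltration (aggregation at short range) and large/noisy otherwise.
"""

import numpy as np
import pandas as pd

from spatannot import (
    CellTypeConfig,
    GeneratorConfig,
    SpatialMode,
    build_pattern,
    compare_cohorts,
    generate_dataset,
    mark_cross_correlation,
    summarize_curve,
    with_spatial_mode,
)


def base_config(seed):
    return GeneratorConfig(
        cell_types=[
            CellTypeConfig("background", 0.55, ["P1"]),
            CellTypeConfig("islet", 0.30, ["P2"],
                           spatial=SpatialMode(kind="cluster", n_parents=5,
                                               offspring_sd=40.0)),
            CellTypeConfig("tcell", 0.15, ["P3"]),
        ],
        proteins=["P1", "P2", "P3", "BG"],
        n_rois=1, cells_per_roi=900,
        window=(0.0, 1000.0, 0.0, 1000.0),
        seed=seed,
    )


rows = []
for cohort, mode in (
    ("infiltrated", SpatialMode(kind="infiltrate", offspring_sd=30.0, target="islet")),
    ("excluded", SpatialMode(kind="uniform")),
):
    for i in range(8):
        cfg = with_spatial_mode(base_config(seed=4000 + i if cohort == "infiltrated"
                                            else 4500 + i), "tcell", mode)
        table, _, truth = generate_dataset(cfg)
        pattern = build_pattern(table.x, table.y, truth.labels, window=cfg.window)
        curve = mark_cross_correlation(pattern, "islet", "tcell",
                                       r_grid=pattern.default_r_grid(n_r=120))
        s = summarize_curve(curve)
        rows.append({"cohort": cohort, "value": s.argmax_r, "max_k": s.max_k})

df = pd.DataFrame(rows)
report = compare_cohorts(df)
for cohort in ("infiltrated", "excluded"):
    sub = df[df["cohort"] == cohort]
    print(f"{cohort:12s} median argmax_r = {report['medians'][cohort]:7.1f} um   "
          f"median max k = {sub['max_k'].median():.2f}")
print(f"Kruskal-Wallis p = {report['kruskal']['pvalue']:.2e}")

# argmax_r is the distance at which the two types are most strongly
# co-aggregated; infiltration pulls it down to the islet length scale
# (tens of micrometres) while k stays near 1 at all distances when the
# T cells ignore the islets, leaving the maximum at an arbitrary distance.
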
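import numpy as np
import pytest

from spatannot import (
    CellTypeConfig,
    GeneratorConfig,
    IntensityTable,
    MarkerSpec,
    SpatialMode,
    generate_dataset,
)


@pytest.fixture
def tiny_table():
    """Five hand-written cells, three proteins."""
    return IntensityTable(
        cell_ids=np.array([f"c{i}" for i in range(5)], dtype=object),
        roi_ids=np.array(["r1", "r1", "r1", "r2", "r2"], dtype=object),
        x=np.array([0.0, 1.0, 2.0, 3.0, 4.0]),
        y=np.array([0.0, 1.0, 0.0, 1.0, 0.0]),
        intensities=np.array(
            [
                [5.0, 0.1, 1.0],
                [0.2, 6.0, 1.0],
                [4.0, 0.3, 2.0],
                [0.1, 5.0, 0.5],
                [3.0, 0.2, 1.5],
            ]
        ),
        protein_names=["GCG", "CPEP", "ACTB"],
    )


@pytest.fixture
def tiny_spec():
    return MarkerSpec(
        cell_types=["alpha", "beta"],
        positive={"alpha": ["GCG"], "beta": ["CPEP"]},
        negative={"alpha": [], "beta": ["GCG"]},
    )


def small_config(seed=0, n_rois=4, cells_per_roi=500, n_types=4):
    """A compact well-separated mixture for fast unit tests."""
    props = {4: [0.5, 0.3, 0.15, 0.05], 2: [0.7, 0.3]}[n_types]
    names = ["t1", "t2", "t3", "t4"][:n_types]
    markers = ["P1", "P2", "P3", "P4"][:n_types]
    types = [
        CellTypeConfig(nm, pr, [mk]) for nm, pr, mk in zip(names, props, markers)
    ]
    return GeneratorConfig(
        cell_types=types,
        proteins=markers + ["BG1", "BG2"],
        n_rois=n_rois,
        cells_per_roi=cells_per_roi,
        seed=seed,
    )


@pytest.fixture
def small_dataset():
    """(table, spec, truth) for a 4-type, 4-ROI, 2,000-cell mixture."""
    return generate_dataset(small_config(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
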
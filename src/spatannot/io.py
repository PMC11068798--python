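"""Readers and writers for the package's external artifacts.

Cell tables, marker files, annotation tables and trained annotator models
all cross the filesystem boundary through this module, with strict
validation on the way in.  The on-disk dialects are deliberately plain:

* ``cells.csv`` — one row per segmented cell with columns ``cell_id``,
  ``roi_id``, ``x``, ``y``, optional ``status``, then one column per
  protein channel (mean pixel intensity per cell, as exported by the
  segmentation pipeline).
* ``markers.csv`` — long format with columns ``cell_type``, ``protein``,
  ``sign`` (``+`` or ``-``); row order fixes the cell-type order used as
  the tie-break order everywhere downstream.
* ``annotations.csv`` — ``cell_id``, ``roi_id``, ``label``, ``source``,
  ``score``.
* model archive — a zip of ``.npy`` payloads plus a ``model.json``
  metadata entry; no pickled code, and byte-identical across repeated
  saves of the same model.
"""

from __future__ import annotations

import io as _io
import json
import warnings
import zipfile
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "IntegrityError",
    "IntensityTable",
    "MarkerSpec",
    "AnnotationTable",
    "TrainedAnnotator",
    "read_intensity_table",
    "write_intensity_table",
    "read_marker_spec",
    "write_marker_spec",
    "marker_spec_from_wide",
    "read_annotations",
    "write_annotations",
    "save_model",
    "load_model",
]

UNKNOWN_LABEL = "Unknown"

#: annotation provenance values
ANNOTATION_SOURCES = ("representative", "clustered", "classified")

_METADATA_COLUMNS = ("cell_id", "roi_id", "x", "y", "status")


class SchemaError(ValueError):
    """A required column or field is missing or malformed."""


class ValidationError(ValueError):
    """Data violate an invariant (negative intensity, NaN coordinate...)."""


class IntegrityError(ValueError):
    """A serialized artifact is corrupt or internally inconsistent."""


# ---------------------------------------------------------------------------
# IntensityTable
# ---------------------------------------------------------------------------

@dataclass
class IntensityTable:
    """Cells x proteins raw channel intensities with per-cell metadata.

    ``intensities`` is dense, nonnegative and finite; ``x``/``y`` are the
    instrument's length units (assumed micrometres, stored as given).
    """

    cell_ids: np.ndarray
    roi_ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    intensities: np.ndarray
    protein_names: list[str]
    status: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.roi_ids = np.asarray(self.roi_ids, dtype=object)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.protein_names = [str(p) for p in self.protein_names]
        if self.status is not None:
            self.status = np.asarray(self.status, dtype=object)

        n = len(self.cell_ids)
        if self.intensities.shape != (n, len(self.protein_names)):
            raise SchemaError(
                f"intensity matrix shape {self.intensities.shape} does not match "
                f"{n} cells x {len(self.protein_names)} proteins"
            )
        for name, arr in (("roi_id", self.roi_ids), ("x", self.x), ("y", self.y)):
            if len(arr) != n:
                raise SchemaError(f"column '{name}' has length {len(arr)}, expected {n}")
        if self.status is not None and len(self.status) != n:
            raise SchemaError(f"column 'status' has length {len(self.status)}, expected {n}")
        if len(set(self.protein_names)) != len(self.protein_names):
            raise ValidationError("protein names are not unique")
        if len(np.unique(self.cell_ids)) != n:
            raise ValidationError("cell_id values are not unique")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            bad = self.cell_ids[~(np.isfinite(self.x) & np.isfinite(self.y))][:1]
            raise ValidationError(f"non-finite coordinate for cell {bad[0]!r}")
        if not np.isfinite(self.intensities).all():
            bad = self.cell_ids[~np.isfinite(self.intensities).all(axis=1)][:1]
            raise ValidationError(f"non-finite intensity for cell {bad[0]!r}")
        if (self.intensities < 0).any():
            bad = self.cell_ids[(self.intensities < 0).any(axis=1)][:1]
            raise ValidationError(f"negative intensity for cell {bad[0]!r}")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_names)

    def subset(self, mask: np.ndarray) -> "IntensityTable":
        """Row subset preserving order (boolean mask or index array)."""
        return IntensityTable(
            cell_ids=self.cell_ids[mask],
            roi_ids=self.roi_ids[mask],
            x=self.x[mask],
            y=self.y[mask],
            intensities=self.intensities[mask],
            protein_names=list(self.protein_names),
            status=None if self.status is None else self.status[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        data = {
            "cell_id": self.cell_ids,
            "roi_id": self.roi_ids,
            "x": self.x,
            "y": self.y,
        }
        if self.status is not None:
            data["status"] = self.status
        frame = pd.DataFrame(data)
        for j, p in enumerate(self.protein_names):
            frame[p] = self.intensities[:, j]
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, schema: dict[str, str] | None = None) -> "IntensityTable":
        schema = dict(schema or {})
        colmap = {f: schema.get(f, f) for f in _METADATA_COLUMNS}
        for f in ("cell_id", "roi_id", "x", "y"):
            if colmap[f] not in frame.columns:
                raise SchemaError(f"missing required column '{colmap[f]}' (field '{f}')")
        has_status = colmap["status"] in frame.columns
        meta_cols = {colmap[f] for f in ("cell_id", "roi_id", "x", "y")}
        if has_status:
            meta_cols.add(colmap["status"])
        proteins = [c for c in frame.columns if c not in meta_cols]
        if not proteins:
            raise SchemaError("no protein columns found")
        return cls(
            cell_ids=frame[colmap["cell_id"]].astype(str).to_numpy(),
            roi_ids=frame[colmap["roi_id"]].astype(str).to_numpy(),
            x=frame[colmap["x"]].to_numpy(dtype=float),
            y=frame[colmap["y"]].to_numpy(dtype=float),
            intensities=frame[proteins].to_numpy(dtype=float),
            protein_names=proteins,
            status=frame[colmap["status"]].astype(str).to_numpy() if has_status else None,
        )


def read_intensity_table(path, schema: dict[str, str] | None = None) -> IntensityTable:
    """Read a ``cells.csv`` table; ``schema`` maps standard field names to
    the file's column names (identity by default)."""
    return IntensityTable.from_frame(pd.read_csv(path), schema=schema)


def write_intensity_table(table: IntensityTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# MarkerSpec
# ---------------------------------------------------------------------------

@dataclass
class MarkerSpec:
    """Per-cell-type positive (M+) and negative (M-) marker protein sets.

    ``cell_types`` preserves file order, which is the deterministic
    tie-break order used downstream (abundance ties, DE label lookup).
    """

    cell_types: list[str]
    positive: dict[str, list[str]]
    negative: dict[str, list[str]]
    include_unknown: bool = True

    def __post_init__(self) -> None:
        if not self.cell_types:
            raise SchemaError("no cell types in marker specification")
        if len(set(self.cell_types)) != len(self.cell_types):
            raise SchemaError("duplicate cell type names")
        for ct in self.cell_types:
            pos = self.positive.get(ct, [])
            neg = self.negative.get(ct, [])
            if not pos:
                raise SchemaError(f"cell type '{ct}' has no positive markers")
            overlap = set(pos) & set(neg)
            if overlap:
                raise SchemaError(
                    f"protein(s) {sorted(overlap)} listed as both positive and "
                    f"negative for cell type '{ct}'"
                )

    @property
    def n_types(self) -> int:
        return len(self.cell_types)

    def labels(self) -> list[str]:
        """Cell-type order plus the Unknown class when enabled."""
        out = list(self.cell_types)
        if self.include_unknown:
            out.append(UNKNOWN_LABEL)
        return out

    def validate_panel(self, protein_names: list[str]) -> None:
        panel = set(protein_names)
        for ct in self.cell_types:
            for marker in list(self.positive.get(ct, [])) + list(self.negative.get(ct, [])):
                if marker not in panel:
                    raise ValidationError(
                        f"marker '{marker}' of cell type '{ct}' not in the measured panel"
                    )


def read_marker_spec(path, include_unknown: bool = True) -> MarkerSpec:
    """Parse a long-format marker file (``cell_type, protein, sign``)."""
    frame = pd.read_csv(path)
    for col in ("cell_type", "protein", "sign"):
        if col not in frame.columns:
            raise SchemaError(f"missing required column '{col}' in marker file")
    if frame.empty:
        raise SchemaError("no cell types in marker specification")
    dup = frame.duplicated(subset=["cell_type", "protein"])
    if dup.any():
        row = frame[dup].iloc[0]
        raise SchemaError(
            f"duplicate marker row ({row['cell_type']}, {row['protein']})"
        )
    bad = ~frame["sign"].isin(["+", "-"])
    if bad.any():
        raise SchemaError(f"marker sign must be '+' or '-', got {frame['sign'][bad].iloc[0]!r}")

    cell_types: list[str] = []
    positive: dict[str, list[str]] = {}
    negative: dict[str, list[str]] = {}
    for _, row in frame.iterrows():
        ct = str(row["cell_type"])
        if ct not in positive:
            cell_types.append(ct)
            positive[ct] = []
            negative[ct] = []
        (positive if row["sign"] == "+" else negative)[ct].append(str(row["protein"]))
    return MarkerSpec(cell_types, positive, negative, include_unknown=include_unknown)


def write_marker_spec(spec: MarkerSpec, path) -> None:
    rows = []
    for ct in spec.cell_types:
        rows.extend({"cell_type": ct, "protein": p, "sign": "+"} for p in spec.positive.get(ct, []))
        rows.extend({"cell_type": ct, "protein": p, "sign": "-"} for p in spec.negative.get(ct, []))
    pd.DataFrame(rows, columns=["cell_type", "protein", "sign"]).to_csv(path, index=False)


def marker_spec_from_wide(frame: pd.DataFrame, include_unknown: bool = True) -> MarkerSpec:
    """Convenience converter for wide marker layouts.

    Each column is a cell type; cells hold protein names, with a trailing
    ``-`` marking a negative marker. Blank entries are ignored.
    """
    cell_types: list[str] = []
    positive: dict[str, list[str]] = {}
    negative: dict[str, list[str]] = {}
    for col in frame.columns:
        ct = str(col)
        cell_types.append(ct)
        positive[ct] = []
        negative[ct] = []
        for entry in frame[col].dropna():
            entry = str(entry).strip()
            if not entry:
                continue
            if entry.endswith("-"):
                negative[ct].append(entry[:-1].strip())
            else:
                positive[ct].append(entry.removesuffix("+").strip())
    return MarkerSpec(cell_types, positive, negative, include_unknown=include_unknown)


# ---------------------------------------------------------------------------
# AnnotationTable
# ---------------------------------------------------------------------------

@dataclass
class AnnotationTable:
    """Per-cell labels with their provenance (``representative`` cells were
    selected by the marker gate, ``clustered`` by the constrained K-means,
    ``classified`` by the trained network)."""

    cell_ids: np.ndarray
    roi_ids: np.ndarray
    labels: np.ndarray
    sources: np.ndarray
    scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.roi_ids = np.asarray(self.roi_ids, dtype=object)
        self.labels = np.asarray(self.labels, dtype=object)
        self.sources = np.asarray(self.sources, dtype=object)
        n = len(self.cell_ids)
        for name, arr in (("roi_id", self.roi_ids), ("label", self.labels), ("source", self.sources)):
            if len(arr) != n:
                raise SchemaError(f"annotation column '{name}' has length {len(arr)}, expected {n}")
        bad = set(np.unique(self.sources)) - set(ANNOTATION_SOURCES)
        if bad:
            raise ValidationError(f"unknown annotation source(s) {sorted(bad)}")
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=float)
            if len(self.scores) != n:
                raise SchemaError("score column length mismatch")

    def __len__(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "roi_id": self.roi_ids,
                "label": self.labels,
                "source": self.sources,
            }
        )
        if self.scores is not None:
            frame["score"] = self.scores
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AnnotationTable":
        for col in ("cell_id", "roi_id", "label", "source"):
            if col not in frame.columns:
                raise SchemaError(f"missing required column '{col}' in annotations")
        return cls(
            cell_ids=frame["cell_id"].astype(str).to_numpy(),
            roi_ids=frame["roi_id"].astype(str).to_numpy(),
            labels=frame["label"].astype(str).to_numpy(),
            sources=frame["source"].astype(str).to_numpy(),
            scores=frame["score"].to_numpy(dtype=float) if "score" in frame.columns else None,
        )


def read_annotations(path) -> AnnotationTable:
    return AnnotationTable.from_frame(pd.read_csv(path))


def write_annotations(ann: AnnotationTable, path) -> None:
    ann.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# TrainedAnnotator
# ---------------------------------------------------------------------------

@dataclass
class TrainedAnnotator:
    """Frozen annotation model.

    Holds the preprocessing parameters, the fixed label order (cell types
    plus optionally the Unknown class), the random-projection input layer
    (``W_in`` of shape proteins x hidden, bias ``b_in``) and the closed-form
    output layer ``W_out`` (hidden x labels), together with provenance.
    Reloading reproduces identical predictions bit-for-bit.
    """

    labels: list[str]
    protein_names: list[str]
    W_in: np.ndarray
    b_in: np.ndarray
    W_out: np.ndarray
    activation: str = "sigmoid"
    pseudo_count: float = 1.0
    unit_norm: bool = True
    seed: int | None = None
    train_rois: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.W_in = np.asarray(self.W_in, dtype=float)
        self.b_in = np.asarray(self.b_in, dtype=float)
        self.W_out = np.asarray(self.W_out, dtype=float)
        p, h = self.W_in.shape
        if p != len(self.protein_names):
            raise IntegrityError(
                f"input weights expect {p} proteins, model lists {len(self.protein_names)}"
            )
        if self.b_in.shape != (h,):
            raise IntegrityError(f"bias shape {self.b_in.shape} does not match {h} hidden units")
        if self.W_out.shape != (h, len(self.labels)):
            raise IntegrityError(
                f"output weights shape {self.W_out.shape} does not match "
                f"{h} hidden units x {len(self.labels)} labels"
            )

    @property
    def n_hidden(self) -> int:
        return self.W_in.shape[1]


def _write_npy(archive: zipfile.ZipFile, name: str, arr: np.ndarray) -> None:
    buf = _io.BytesIO()
    np.save(buf, arr)
    info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
    archive.writestr(info, buf.getvalue())


def save_model(model: TrainedAnnotator, path) -> None:
    """Serialize to a self-describing zip archive (arrays + model.json).

    The archive is byte-identical across repeated saves of the same model
    (fixed timestamps, no pickling).
    """
    meta = {
        "format": "spatannot-model",
        "version": 1,
        "labels": list(model.labels),
        "protein_names": list(model.protein_names),
        "activation": model.activation,
        "pseudo_count": model.pseudo_count,
        "unit_norm": model.unit_norm,
        "seed": model.seed,
        "train_rois": list(model.train_rois),
        "shapes": {
            "W_in": list(model.W_in.shape),
            "b_in": list(model.b_in.shape),
            "W_out": list(model.W_out.shape),
        },
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as archive:
        info = zipfile.ZipInfo("model.json", date_time=(1980, 1, 1, 0, 0, 0))
        archive.writestr(info, json.dumps(meta, sort_keys=True, indent=1))
        _write_npy(archive, "W_in.npy", model.W_in)
        _write_npy(archive, "b_in.npy", model.b_in)
        _write_npy(archive, "W_out.npy", model.W_out)


def load_model(path) -> TrainedAnnotator:
    try:
        with zipfile.ZipFile(path) as archive:
            meta = json.loads(archive.read("model.json"))
            arrays = {
                name: np.load(_io.BytesIO(archive.read(f"{name}.npy")))
                for name in ("W_in", "b_in", "W_out")
            }
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError, ValueError) as exc:
        raise IntegrityError(f"cannot read model archive {path}: {exc}") from exc
    if meta.get("format") != "spatannot-model":
        raise IntegrityError("not a spatannot model archive")
    for name, arr in arrays.items():
        expected = tuple(meta["shapes"][name])
        if arr.shape != expected:
            raise IntegrityError(
                f"array '{name}' has shape {arr.shape}, metadata says {expected}"
            )
    return TrainedAnnotator(
        labels=list(meta["labels"]),
        protein_names=list(meta["protein_names"]),
        W_in=arrays["W_in"],
        b_in=arrays["b_in"],
        W_out=arrays["W_out"],
        activation=meta["activation"],
        pseudo_count=meta["pseudo_count"],
        unit_norm=meta["unit_norm"],
        seed=meta["seed"],
        train_rois=list(meta["train_rois"]),
    )
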
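"""GIFTI I/O for surface signals, label maps and sphere meshes.

Vertex indexing is 0-based throughout, matching GIFTI array semantics.
Reading is lossless: no normalisation happens here (per-channel z-scoring
belongs to the training pipeline).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import nibabel as nib
from nibabel import gifti

__all__ = [
    "SurfaceSignal",
    "LabelMap",
    "read_metric",
    "write_metric",
    "read_labels",
    "write_labels",
    "read_surface",
    "write_surface",
]


@dataclass
class SurfaceSignal:
    """Multi-channel per-vertex scalar signal on a (spherical) mesh.

    ``values`` is (|V|, C); ``mesh_order`` is the icosphere order the signal
    lives on, or the string ``"native"`` for non-icosahedral meshes.
    """

    values: np.ndarray
    channel_names: list[str] = field(default_factory=list)
    mesh_order: int | str = "native"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.ndim != 2 or self.values.shape[1] < 1:
            raise ValueError(f"values must be (|V|, C) with C >= 1, got {self.values.shape}")
        if not self.channel_names:
            self.channel_names = [f"channel_{i}" for i in range(self.values.shape[1])]
        if len(self.channel_names) != self.values.shape[1]:
            raise ValueError("channel_names length must match number of columns")
        if not np.isfinite(self.values).all():
            raise ValueError("signal contains non-finite values")

    @property
    def n_vertices(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_channels(self) -> int:
        return int(self.values.shape[1])


@dataclass
class LabelMap:
    """Integer per-vertex labels plus an id -> (name, rgba) table."""

    labels: np.ndarray
    label_table: dict[int, tuple[str, tuple[float, float, float, float]]]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D integer vector")
        present = np.unique(self.labels)
        if present.size and present.min() < 0:
            raise ValueError("label ids must be non-negative")
        missing = [int(i) for i in present if int(i) not in self.label_table]
        if missing:
            raise ValueError(f"label ids {missing} missing from label table")

    @property
    def n_vertices(self) -> int:
        return int(self.labels.shape[0])

    def region_ids(self) -> list[int]:
        return sorted(self.label_table)


def _load_gifti(path: str | Path) -> gifti.GiftiImage:
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise IOError(f"could not read GIFTI file {path}: {exc}") from exc
    if not isinstance(img, gifti.GiftiImage):
        raise ValueError(f"{path} is not a GIFTI file")
    return img


def read_metric(path: str | Path, expected_vertices: int | None = None) -> SurfaceSignal:
    """Read a GIFTI metric file (.shape.gii / .func.gii) as a SurfaceSignal.

    Each data array becomes one channel; channel names come from the
    per-array ``Name`` metadata when present.  A plain delimited text file
    (one row per vertex) is accepted as a fallback.
    """
    path = Path(path)
    if path.suffix.lower() in (".csv", ".tsv", ".txt"):
        delim = "," if path.suffix.lower() == ".csv" else None
        values = np.loadtxt(path, delimiter=delim, ndmin=2)
        names: list[str] = []
    else:
        img = _load_gifti(path)
        cols, names = [], []
        for i, da in enumerate(img.darrays):
            arr = np.asarray(da.data, dtype=np.float64)
            if arr.ndim != 1:
                arr = arr.reshape(arr.shape[0], -1)[:, 0]
            cols.append(arr)
            names.append(da.meta.get("Name") or f"channel_{i}")
        if not cols:
            raise ValueError(f"{path} contains no data arrays")
        lens = {c.shape[0] for c in cols}
        if len(lens) != 1:
            raise ValueError(f"{path}: data arrays have mismatched lengths {sorted(lens)}")
        values = np.stack(cols, axis=1)
    if expected_vertices is not None and values.shape[0] != expected_vertices:
        raise ValueError(
            f"{path}: expected {expected_vertices} vertices, file has {values.shape[0]}"
        )
    return SurfaceSignal(values=values, channel_names=names)


def write_metric(signal: SurfaceSignal, path: str | Path) -> Path:
    """Write a SurfaceSignal as a GIFTI metric file (one data array per channel)."""
    path = Path(path)
    darrays = []
    for i, name in enumerate(signal.channel_names):
        da = gifti.GiftiDataArray(
            data=signal.values[:, i].astype(np.float32),
            intent="NIFTI_INTENT_SHAPE",
            datatype="NIFTI_TYPE_FLOAT32",
        )
        da.meta = gifti.GiftiMetaData(Name=name)
        darrays.append(da)
    img = gifti.GiftiImage(darrays=darrays)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise IOError(f"could not write {path}: {exc}") from exc
    return path


def read_labels(path: str | Path) -> LabelMap:
    """Read a GIFTI label file (.label.gii)."""
    img = _load_gifti(path)
    if not img.darrays:
        raise ValueError(f"{path} contains no data arrays")
    labels = np.asarray(img.darrays[0].data, dtype=np.int64)
    table = {}
    for lab in img.labeltable.labels:
        table[int(lab.key)] = (lab.label or str(lab.key), (lab.red, lab.green, lab.blue, lab.alpha))
    if not table:
        raise ValueError(f"{path} has no label table")
    return LabelMap(labels=labels, label_table=table)


def write_labels(label_map: LabelMap, path: str | Path) -> Path:
    """Write a LabelMap as a GIFTI label file."""
    path = Path(path)
    table = gifti.GiftiLabelTable()
    for key in sorted(label_map.label_table):
        name, rgba = label_map.label_table[key]
        lab = gifti.GiftiLabel(key=int(key), red=rgba[0], green=rgba[1], blue=rgba[2], alpha=rgba[3])
        lab.label = name
        table.labels.append(lab)
    da = gifti.GiftiDataArray(
        data=label_map.labels.astype(np.int32),
        intent="NIFTI_INTENT_LABEL",
        datatype="NIFTI_TYPE_INT32",
    )
    img = gifti.GiftiImage(darrays=[da], labeltable=table)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise IOError(f"could not write {path}: {exc}") from exc
    return path


def read_surface(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a GIFTI surface (.surf.gii) -> (vertices (V,3) float64, faces (F,3) int64)."""
    from nibabel.nifti1 import intent_codes

    img = _load_gifti(path)
    verts = faces = None
    for da in img.darrays:
        if da.intent == intent_codes["NIFTI_INTENT_POINTSET"]:
            verts = np.asarray(da.data, dtype=np.float64)
        elif da.intent == intent_codes["NIFTI_INTENT_TRIANGLE"]:
            faces = np.asarray(da.data, dtype=np.int64)
    if verts is None or faces is None:
        raise ValueError(f"{path} lacks pointset/triangle arrays")
    return verts, faces


def write_surface(vertices: np.ndarray, faces: np.ndarray, path: str | Path) -> Path:
    """Write a triangulated surface as GIFTI .surf.gii."""
    path = Path(path)
    da_v = gifti.GiftiDataArray(
        data=np.asarray(vertices, dtype=np.float32),
        intent="NIFTI_INTENT_POINTSET",
        datatype="NIFTI_TYPE_FLOAT32",
    )
    da_f = gifti.GiftiDataArray(
        data=np.asarray(faces, dtype=np.int32),
        intent="NIFTI_INTENT_TRIANGLE",
        datatype="NIFTI_TYPE_INT32",
    )
    img = gifti.GiftiImage(darrays=[da_v, da_f])
    nib.save(img, str(path))
    return path
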
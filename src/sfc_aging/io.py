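"""Reading, writing and validation of the formats the pipeline touches.

Volumes travel as NIfTI-1 files; because NIfTI carries no label dictionary,
label semantics (name and anatomical class per integer label) live in a JSON
sidecar written next to the image (``<stem>.labels.json``).  Regional
morphometry and all tabular statistics are tab-separated text with a fixed
covariate header prefix (``id  group  sex  education  age``) followed by one
column per region; the measure kind is recorded on a leading comment line.

Geometry convention: 0-based voxel indices, axis order (x, y, z); all
geometric operations downstream are documented in voxel space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "SchemaError",
    "VolumeGrid",
    "LabelEntry",
    "LabelVolume",
    "SubjectRecord",
    "RegionalTable",
    "NodeTable",
    "read_volume",
    "write_volume",
    "read_regional_table",
    "write_regional_table",
    "build_node_table",
]

GROUPS = ("young", "middle", "elderly")
SEXES = ("M", "F")
MEASURE_KINDS = ("thickness_mm", "normalized_volume_mm3")

#: label classes a voxel may belong to
LABEL_CLASSES = (
    "background",
    "ventricle",
    "caudate_left",
    "caudate_right",
    "cortical_parcel",
    "subcortical_parcel",
)
CAUDATE_CLASSES = ("caudate_left", "caudate_right")
#: classes whose voxels become graph nodes (grey matter; ventricle is CSF)
NODE_CLASSES = ("caudate_left", "caudate_right", "cortical_parcel", "subcortical_parcel")


class FormatError(ValueError):
    """A file could not be parsed as the expected format."""


class SchemaError(ValueError):
    """A parsed file violates the domain schema (enums, required columns...)."""


@dataclass
class VolumeGrid:
    """A scalar 3D voxel map with physical voxel size (mm) and origin."""

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (5.0, 5.0, 5.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise FormatError(f"volume must be 3D with all dims >= 1, got shape {self.values.shape}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise FormatError(f"voxel size must be positive, got {self.voxel_size_mm}")


@dataclass(frozen=True)
class LabelEntry:
    name: str
    label_class: str

    def __post_init__(self) -> None:
        if self.label_class not in LABEL_CLASSES:
            raise SchemaError(f"unknown label class {self.label_class!r}")


@dataclass
class LabelVolume:
    """Integer-labelled voxel grid plus a dictionary of label semantics.

    Label 0 is background and never appears in the dictionary; every nonzero
    label present in the array must be described.  Caudate and ventricle labels
    are disjoint by the class taxonomy.
    """

    labels: np.ndarray
    dictionary: dict[int, LabelEntry]
    voxel_size_mm: tuple[float, float, float] = (5.0, 5.0, 5.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 or min(self.labels.shape) < 1:
            raise FormatError(f"label volume must be 3D with all dims >= 1, got {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError(f"label volume must be integer-typed, got {self.labels.dtype}")
        if self.labels.min() < 0:
            raise SchemaError("labels must be non-negative")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.dictionary)
        if missing:
            raise SchemaError(f"labels present in volume but absent from dictionary: {sorted(missing)}")
        if 0 in self.dictionary:
            raise SchemaError("label 0 is reserved for background")

    def labels_of_class(self, *classes: str) -> list[int]:
        return sorted(l for l, e in self.dictionary.items() if e.label_class in classes)

    def mask_of_class(self, *classes: str) -> np.ndarray:
        wanted = set(self.labels_of_class(*classes))
        return np.isin(self.labels, sorted(wanted))

    def region_names(self, *classes: str) -> list[str]:
        return [self.dictionary[l].name for l in self.labels_of_class(*classes)]


@dataclass(frozen=True)
class SubjectRecord:
    id: str
    group: str
    sex: str
    education_years: float
    age_years: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise SchemaError(f"unknown group {self.group!r} for subject {self.id!r}")
        if self.sex not in SEXES:
            raise SchemaError(f"unknown sex {self.sex!r} for subject {self.id!r}")
        if self.education_years < 0:
            raise SchemaError(f"negative education for subject {self.id!r}")
        if self.age_years is not None:
            a = self.age_years
            if a <= 0:
                raise SchemaError(f"non-positive age for subject {self.id!r}")
            ok = (
                (self.group == "young" and a <= 35)
                or (self.group == "middle" and 36 <= a <= 60)
                or (self.group == "elderly" and a >= 60)
            )
            if not ok:
                raise SchemaError(
                    f"age {a} inconsistent with group {self.group!r} for subject {self.id!r} "
                    "(young <= 35, middle 36-60, elderly >= 60)"
                )


COVARIATE_COLUMNS = ["id", "group", "sex", "education", "age"]


@dataclass
class RegionalTable:
    """Per-subject, per-region morphometry of one measure kind.

    ``values`` is a DataFrame indexed by subject id with one column per region
    (cortical thickness in mm, or head-size-normalized GM volume in mm^3).
    """

    subjects: list[SubjectRecord]
    values: pd.DataFrame
    measure_kind: str

    def __post_init__(self) -> None:
        if self.measure_kind not in MEASURE_KINDS:
            raise SchemaError(f"unknown measure kind {self.measure_kind!r}")
        regions = list(self.values.columns)
        if len(set(regions)) != len(regions):
            raise SchemaError("duplicated region names in table")
        ids = [s.id for s in self.subjects]
        if list(self.values.index) != ids:
            raise SchemaError("table rows do not match subject records")
        vals = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise SchemaError("non-finite values in regional table")
        if self.measure_kind == "thickness_mm" and np.any(vals <= 0):
            raise SchemaError("cortical thickness must be strictly positive")

    @property
    def regions(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, group: str) -> "RegionalTable":
        subs = [s for s in self.subjects if s.group == group]
        return RegionalTable(subs, self.values.loc[[s.id for s in subs]], self.measure_kind)

    @property
    def group_labels(self) -> pd.Series:
        return pd.Series([s.group for s in self.subjects], index=self.values.index)


# ---------------------------------------------------------------------------
# volumes

def _sidecar_path(path: Path) -> Path:
    stem = path.name
    for suf in (".nii.gz", ".nii"):
        if stem.endswith(suf):
            stem = stem[: -len(suf)]
            break
    return path.with_name(stem + ".labels.json")


def write_volume(volume: VolumeGrid | LabelVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1; a LabelVolume also gets a JSON label sidecar."""
    path = Path(path)
    if isinstance(volume, LabelVolume):
        data = volume.labels.astype(np.int32)
    else:
        data = np.asarray(volume.values, dtype=np.float64)
    affine = np.diag(list(volume.voxel_size_mm) + [1.0])
    affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(data, affine), str(path))
    if isinstance(volume, LabelVolume):
        sidecar = {
            str(l): {"name": e.name, "class": e.label_class} for l, e in sorted(volume.dictionary.items())
        }
        _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_volume(path: str | Path) -> VolumeGrid | LabelVolume:
    """Load a NIfTI-1 volume; integer data with a label sidecar -> LabelVolume.

    4D inputs are rejected: time series enter the pipeline via tables, not
    volumes.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # truncated / not NIfTI
        raise FormatError(f"could not read {path} as NIfTI-1: {exc}") from exc
    while data.ndim > 3 and data.shape[-1] == 1:  # drop trailing singleton dims only
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(
            f"{path} is {data.ndim}D; only 3D volumes are supported "
            "(per-node time series enter via tables, not 4D images)"
        )
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    sidecar = _sidecar_path(path)
    if np.issubdtype(data.dtype, np.integer) and sidecar.exists():
        raw = json.loads(sidecar.read_text())
        dictionary = {int(k): LabelEntry(v["name"], v["class"]) for k, v in raw.items()}
        return LabelVolume(data.astype(np.int32), dictionary, zooms, origin)
    return VolumeGrid(data.astype(np.float64), zooms, origin)


# ---------------------------------------------------------------------------
# regional tables

def write_regional_table(table: RegionalTable, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "id": [s.id for s in table.subjects],
            "group": [s.group for s in table.subjects],
            "sex": [s.sex for s in table.subjects],
            "education": [s.education_years for s in table.subjects],
            "age": [s.age_years if s.age_years is not None else np.nan for s in table.subjects],
        }
    )
    df = pd.concat([df, table.values.reset_index(drop=True)], axis=1)
    with open(path, "w") as fh:
        fh.write(f"# measure_kind={table.measure_kind}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
    return path


def read_regional_table(path: str | Path, measure_kind: str | None = None) -> RegionalTable:
    """Parse a TSV regional table (covariate prefix + one column per region)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("# measure_kind="):
        kind = first.split("=", 1)[1].strip()
        skip = 1
    elif measure_kind is not None:
        kind = measure_kind
    else:
        raise SchemaError(f"{path} has no measure_kind header and none was supplied")
    if measure_kind is not None:
        kind = measure_kind
    df = pd.read_csv(path, sep="\t", skiprows=skip, dtype=str)
    missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path} is missing covariate column(s) {missing}")
    region_cols = [c for c in df.columns if c not in COVARIATE_COLUMNS]
    if not region_cols:
        raise SchemaError(f"{path} has no region columns")
    subjects = []
    for i, row in df.iterrows():
        age = row["age"]
        age_val = None if (pd.isna(age) or str(age) == "") else float(age)
        subjects.append(
            SubjectRecord(str(row["id"]), str(row["group"]), str(row["sex"]), float(row["education"]), age_val)
        )
    values = np.empty((len(df), len(region_cols)))
    for j, col in enumerate(region_cols):
        for i, raw in enumerate(df[col]):
            try:
                values[i, j] = float(raw)
            except (TypeError, ValueError) as exc:
                raise FormatError(
                    f"{path}: non-numeric measure {raw!r} at row {i + 1}, column {col!r}"
                ) from exc
    frame = pd.DataFrame(values, index=[s.id for s in subjects], columns=region_cols)
    return RegionalTable(subjects, frame, kind)


# ---------------------------------------------------------------------------
# node table: the voxel <-> graph-node correspondence

@dataclass
class NodeTable:
    """Mapping between graph node indices and atlas voxels.

    Nodes are the grey-matter voxels of the atlas (caudate plus cortical and
    subcortical parcels); ventricle and background voxels carry no signal and
    are excluded.  ``coords`` is (n_nodes, 3) voxel indices in array order,
    ``labels`` the atlas label of each node.
    """

    coords: np.ndarray
    labels: np.ndarray
    atlas: LabelVolume

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def nodes_with_label(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    def nodes_of_class(self, *classes: str) -> np.ndarray:
        wanted = self.atlas.labels_of_class(*classes)
        return np.flatnonzero(np.isin(self.labels, wanted))

    def index_of_voxel(self) -> dict[tuple[int, int, int], int]:
        return {tuple(c): i for i, c in enumerate(self.coords)}


def build_node_table(atlas: LabelVolume, classes: Sequence[str] = NODE_CLASSES) -> NodeTable:
    mask = atlas.mask_of_class(*classes)
    coords = np.argwhere(mask)
    labels = atlas.labels[mask]
    return NodeTable(coords, labels, atlas)
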
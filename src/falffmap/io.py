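"""Spatial container types and on-disk formats.

Volumes, masks, parcellations and statistic maps are NIfTI-1 files handled
through nibabel; subject tables and expression bundles are delimited text
through pandas; gene-category annotations use a GMT-like format (one category
per line: id, aspect/description, tab-separated gene symbols).

Conventions: voxel indices are 0-based; world coordinates are MNI millimetres
obtained through the image affine; all sphere/distance computations are in mm.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Volume4D",
    "StatMap",
    "BrainMask",
    "Parcellation",
    "SubjectRecord",
    "read_volume4d",
    "write_volume4d",
    "read_statmap",
    "write_statmap",
    "read_mask",
    "write_mask",
    "read_parcellation",
    "write_parcellation",
    "load_subject_table",
    "read_gmt",
    "write_gmt",
    "voxel_to_world",
    "world_to_voxel",
]

STATMAP_KINDS = ("falff_z", "fc_z", "tmap", "receptor", "gm_prob")
SUBJECT_COLUMNS = (
    "subject_id",
    "group",
    "age",
    "education",
    "tiv",
    "bai",
    "bdi",
    "ee",
    "dp",
    "pa",
)
GROUPS = ("burnout", "control")


@dataclasses.dataclass
class Volume4D:
    """A subject's BOLD grid: X*Y*Z*T data, voxel->MNI affine, TR in seconds."""

    data: np.ndarray
    affine: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got {self.data.ndim}D")
        if self.data.shape[3] < 8:
            raise ValueError(f"need at least 8 timepoints, got {self.data.shape[3]}")
        if not self.tr > 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclasses.dataclass
class StatMap:
    """A 3D scalar map (fALFF z, FC z, group t, receptor density, GM prob)."""

    data: np.ndarray
    affine: np.ndarray
    kind: str = "tmap"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got {self.data.ndim}D")
        if self.kind not in STATMAP_KINDS:
            raise ValueError(f"unknown map kind {self.kind!r}; one of {STATMAP_KINDS}")


@dataclasses.dataclass
class BrainMask:
    """Boolean inclusion grid sharing the analysis space."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D mask, got {self.data.ndim}D")
        if not self.data.any():
            raise ValueError("mask contains no voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclasses.dataclass
class Parcellation:
    """Integer label grid (0 = background) with region ids and optional names."""

    labels: np.ndarray
    affine: np.ndarray
    region_ids: Sequence[int] = None
    names: Mapping[int, str] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).astype(int)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.labels.ndim != 3:
            raise ValueError(f"expected 3D labels, got {self.labels.ndim}D")
        present = sorted(int(v) for v in np.unique(self.labels) if v != 0)
        if self.region_ids is None:
            self.region_ids = present
        self.region_ids = [int(r) for r in self.region_ids]
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValueError("region_ids must be distinct")
        if any(r <= 0 for r in self.region_ids):
            raise ValueError("region_ids must be positive")
        extra = set(present) - set(self.region_ids)
        if extra:
            raise ValueError(f"labels {sorted(extra)} missing from region_ids")
        if self.names is None:
            self.names = {r: f"region_{r}" for r in self.region_ids}


@dataclasses.dataclass
class SubjectRecord:
    subject_id: str
    group: str
    age: float
    education: float
    tiv: float
    bai: float
    bdi: float
    ee: float
    dp: float
    pa: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        for field in ("bai", "bdi", "ee", "dp", "pa"):
            if getattr(self, field) < 0:
                raise ValueError(f"{field} must be non-negative")


# ---------------------------------------------------------------------------
# coordinate helpers

def voxel_to_world(affine: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    """Map 0-based voxel indices to MNI mm through the affine."""
    ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
    xyz = ijk @ np.asarray(affine)[:3, :3].T + np.asarray(affine)[:3, 3]
    return xyz


def world_to_voxel(affine: np.ndarray, xyz: np.ndarray) -> np.ndarray:
    """Map MNI mm to (fractional) 0-based voxel indices."""
    inv = np.linalg.inv(np.asarray(affine))
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    return xyz @ inv[:3, :3].T + inv[:3, 3]


# ---------------------------------------------------------------------------
# NIfTI I/O

def _load_nifti(path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return nib.load(str(path))


def read_volume4d(path) -> Volume4D:
    """Read a 4D NIfTI-1 BOLD image; TR is taken from the header (pixdim[4])."""
    img = _load_nifti(path)
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"expected 4D image, got {data.ndim}D: {path}")
    tr = float(img.header.get_zooms()[3])
    if tr <= 0:
        raise ValueError(f"header pixdim[4] (TR) must be > 0, got {tr}: {path}")
    return Volume4D(data=data, affine=img.affine, tr=tr)


def write_volume4d(vol: Volume4D, path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = vol.tr
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_statmap(path, kind: str = "tmap") -> StatMap:
    img = _load_nifti(path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected 3D image, got {data.ndim}D: {path}")
    return StatMap(data=data, affine=img.affine, kind=kind)


def write_statmap(statmap: StatMap, path) -> None:
    img = nib.Nifti1Image(np.asarray(statmap.data, dtype=np.float32), statmap.affine)
    nib.save(img, str(path))


def read_mask(path) -> BrainMask:
    img = _load_nifti(path)
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D mask, got {data.ndim}D: {path}")
    return BrainMask(data=data > 0, affine=img.affine)


def write_mask(mask: BrainMask, path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


def read_parcellation(path, names: Mapping[int, str] | None = None) -> Parcellation:
    img = _load_nifti(path)
    labels = np.asarray(img.dataobj)
    if labels.ndim != 3:
        raise ValueError(f"expected 3D parcellation, got {labels.ndim}D: {path}")
    return Parcellation(labels=np.rint(labels).astype(int), affine=img.affine, names=names)


def write_parcellation(parc: Parcellation, path) -> None:
    img = nib.Nifti1Image(parc.labels.astype(np.int16), parc.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# tables

def load_subject_table(path) -> list[SubjectRecord]:
    """Read a delimited subject table into records.

    Requires a header with the ten named columns (subject_id, group, age,
    education, tiv, bai, bdi, ee, dp, pa); the delimiter (comma or tab) is
    sniffed by pandas.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"subject table missing column(s): {', '.join(missing)}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject_id(s): {dupes}")
    records = []
    for _, row in df.iterrows():
        try:
            numeric = {c: float(row[c]) for c in SUBJECT_COLUMNS[2:]}
        except (TypeError, ValueError) as exc:
            raise ValueError(f"unparseable numeric value in row {row['subject_id']!r}: {exc}")
        records.append(
            SubjectRecord(subject_id=str(row["subject_id"]), group=str(row["group"]), **numeric)
        )
    return records


def save_subject_table(records: Sequence[SubjectRecord], path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT-like gene-category annotations

def read_gmt(path) -> dict[str, tuple[str, list[str]]]:
    """Read category annotations: ``category_id<TAB>aspect<TAB>gene...`` per line."""
    out: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: need id, aspect and at least one gene")
            cat, aspect, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if cat in out:
                raise ValueError(f"line {lineno}: duplicate category {cat!r}")
            out[cat] = (aspect, genes)
    return out


def write_gmt(annotations: Mapping[str, tuple[str, Sequence[str]]], path) -> None:
    with open(path, "w") as fh:
        for cat, (aspect, genes) in annotations.items():
            fh.write("\t".join([cat, aspect, *genes]) + "\n")
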
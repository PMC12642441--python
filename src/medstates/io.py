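"""Readers/writers and basic containers for the volumetric pipeline.

Volumes travel as NIfTI-1/2 (via nibabel), tables as CSV/TSV (via pandas),
meshes as ASCII OFF (via trimesh).  Time indices are 0-based, half-open
[start, end), matching array slicing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

#: Closed condition vocabulary: eight ordered meditative absorption states,
#: two non-meditative control tasks, and an afterglow tag that is parsed but
#: ignored by the analyses.
STATES: tuple[str, ...] = tuple(f"J{i}" for i in range(1, 9))
CONTROLS: tuple[str, ...] = ("counting", "memory")
CONDITIONS: tuple[str, ...] = STATES + CONTROLS + ("afterglow",)

#: Label used for the composite (counting+memory averaged) control.
COMPOSITE_CONTROL = "control"


class FormatError(ValueError):
    """Raised when a file is not in the expected on-disk format."""


class DimensionError(ValueError):
    """Raised for arrays with an unsupported number of axes."""


class SchemaError(ValueError):
    """Raised for malformed tables (duplicate/missing headers, bad vocabulary)."""


@dataclass
class VoxelImage:
    """A 3D map or 4D run with voxel geometry and an analysis mask.

    Parameters
    ----------
    data : ndarray
        3D spatial array or 4D array with time on the last axis.
    voxel_size : tuple of float
        Millimetres per spatial axis; strictly positive.
    mask : ndarray of bool
        Aligned to the spatial shape of ``data``.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise DimensionError(f"expected 3D or 4D data, got {self.data.ndim}D")
        if self.data.ndim == 4 and self.data.shape[-1] < 2:
            raise DimensionError("4D data needs at least 2 time points")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be strictly positive")
        if self.mask is None:
            self.mask = default_mask(self.data)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.spatial_shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != spatial shape {self.spatial_shape}"
            )

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3] if self.data.ndim == 4 else 1


def default_mask(data: np.ndarray) -> np.ndarray:
    """Finite voxels; for 4D additionally require nonzero temporal variance."""
    if data.ndim == 4:
        finite = np.isfinite(data).all(axis=-1)
        var = np.zeros(data.shape[:3])
        var[finite] = data[finite].var(axis=-1)
        return finite & (var > 0)
    return np.isfinite(data)


@dataclass
class Parcellation:
    """Integer label volume (0 = background) with parcel names and networks."""

    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)
    networks: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise DimensionError("parcellation labels must be 3D")
        if (self.labels < 0).any():
            raise ValueError("labels must be nonnegative")
        present = self.parcel_ids
        if not self.names:
            self.names = {int(l): f"parcel_{int(l)}" for l in present}
        missing = [int(l) for l in present if int(l) not in self.names]
        if missing:
            raise ValueError(f"labels without names: {missing}")

    @property
    def parcel_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


SEGMENT_COLUMNS = ("participant", "session", "condition", "start", "end")


@dataclass
class SegmentTable:
    """Rows of (participant, session, condition, start, end) with half-open bounds."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.rows)
        missing = set(SEGMENT_COLUMNS) - set(df.columns)
        if missing:
            raise SchemaError(f"segment table missing columns: {sorted(missing)}")
        bad = set(df["condition"]) - set(CONDITIONS)
        if bad:
            raise SchemaError(f"unknown conditions: {sorted(bad)}")
        if (df["start"].astype(int) >= df["end"].astype(int)).any():
            raise ValueError("segment start must be < end")
        self.rows = df.reset_index(drop=True)
        # non-overlap within each run (optional `run` column separates
        # acquisitions sharing a session)
        run_keys = ["participant", "session"] + (["run"] if "run" in df else [])
        for _, grp in df.groupby(run_keys):
            g = grp.sort_values("start")
            if (g["start"].values[1:] < g["end"].values[:-1]).any():
                raise ValueError("overlapping segments within a run")

    def __len__(self) -> int:
        return len(self.rows)

    def analysis_rows(self) -> pd.DataFrame:
        """Rows excluding afterglow segments, which are parsed but not analysed."""
        return self.rows[self.rows["condition"] != "afterglow"].reset_index(drop=True)


def read_volume(path: str | Path) -> VoxelImage:
    """Read a NIfTI-1/2 volume into a :class:`VoxelImage`.

    The default mask keeps finite voxels (3D) or finite, nonzero-variance
    voxels (4D).
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise FormatError(f"not a readable NIfTI volume: {path}") from exc
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim not in (3, 4):
        raise DimensionError(f"expected 3D/4D NIfTI, got {data.ndim}D: {path}")
    zooms = img.header.get_zooms()[:3]
    return VoxelImage(data=data, voxel_size=tuple(float(z) for z in zooms))


def write_volume(image: VoxelImage, path: str | Path) -> None:
    """Write a :class:`VoxelImage` as NIfTI (float32 storage)."""
    path = Path(path)
    affine = np.diag(list(image.voxel_size) + [1.0])
    img = nib.Nifti1Image(image.data.astype(np.float32), affine)
    img.header.set_zooms(image.voxel_size + ((1.0,) if image.data.ndim == 4 else ()))
    nib.save(img, str(path))


def read_labels(path: str | Path, names: dict[int, str] | None = None,
                networks: dict[int, str] | None = None) -> Parcellation:
    """Read an integer label volume as a :class:`Parcellation`."""
    img = read_volume(path)
    if img.data.ndim != 3:
        raise DimensionError("label volume must be 3D")
    return Parcellation(labels=np.rint(img.data).astype(int), names=names or {},
                        networks=networks)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited text table (CSV or TSV inferred from content).

    Missing cells become NaN; duplicate column names raise :class:`SchemaError`.
    A file whose header row parses as all-numeric is treated as headerless and
    rejected.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    cols = list(df.columns)
    if len(set(cols)) != len(cols) or any(c.endswith(".1") for c in cols):
        raise SchemaError(f"duplicate column names in {path}")
    numericish = sum(_parses_as_number(c) for c in cols)
    if cols and numericish == len(cols):
        raise SchemaError(f"{path} appears to have no header row")
    return df


def _parses_as_number(token: str) -> bool:
    try:
        float(token)
        return True
    except (TypeError, ValueError):
        return False


def read_segments(path: str | Path) -> SegmentTable:
    return SegmentTable(read_table(path))


def extract_segments(image: VoxelImage, segments: SegmentTable) -> list[VoxelImage]:
    """Slice a 4D run into per-segment 4D images, order preserved.

    Bounds are 0-based half-open ``[start, end)``.
    """
    if image.data.ndim != 4:
        raise DimensionError("extract_segments requires a 4D image")
    T = image.data.shape[-1]
    out: list[VoxelImage] = []
    for _, row in segments.rows.iterrows():
        start, end = int(row["start"]), int(row["end"])
        if start < 0 or end > T:
            raise IndexError(f"segment [{start},{end}) outside run of {T} volumes")
        out.append(VoxelImage(data=image.data[..., start:end],
                              voxel_size=image.voxel_size,
                              mask=image.mask))
    return out


def read_mesh(path: str | Path):
    """Read a surface mesh (ASCII OFF / PLY / anything trimesh handles)."""
    import trimesh

    mesh = trimesh.load_mesh(str(path), process=False)
    return mesh
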
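"""Reading and writing the formats the pipeline touches.

NIfTI images carry the 4D BOLD runs, binary ROI masks and integer label
volumes; participant metadata travels as TSV; realignment parameters as
6-column whitespace-delimited text (3 translations in mm, 3 rotations in
radians). Everything downstream works on the in-memory containers defined
here, so file formats appear only in this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "BoldRun",
    "RoiMask",
    "VoxelTimecourses",
    "ParticipantRecord",
    "load_bold",
    "make_mask",
    "load_mask",
    "extract_roi_timecourses",
    "write_label_volume",
    "load_participants",
    "load_motion",
]

GROUPS = ("control", "ltle", "rtle")
MTS_CODES = ("mts", "no_mts", "possible", "n/a")


@dataclass
class BoldRun:
    """A 4D BOLD acquisition: intensity grid, repetition time and affine."""

    data: np.ndarray  # (x, y, z, t)
    tr_seconds: float
    affine: np.ndarray  # 4x4 voxel -> world (mm)
    run_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD run must be 4D, got {self.data.ndim}D")
        if self.data.shape[3] < 3:
            raise ValueError("BOLD run needs at least 3 timepoints")
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class RoiMask:
    """Boolean ROI on the run grid with a fixed, reproducible voxel order.

    Voxels are ordered lexicographically by (i, j, k) index; ``world_mm``
    holds the matching voxel-center coordinates in mm through the affine.
    """

    grid: np.ndarray  # bool, 3D
    hemisphere: str  # "left" | "right"
    affine: np.ndarray
    voxel_index: np.ndarray = field(init=False)  # (n, 3) int
    world_mm: np.ndarray = field(init=False)  # (n, 3) float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid).astype(bool)
        if self.grid.ndim != 3:
            raise ValueError("mask grid must be 3D")
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")
        self.affine = np.asarray(self.affine, dtype=float)
        idx = np.argwhere(self.grid)  # argwhere is already lexicographic
        if idx.shape[0] == 0:
            raise ValueError("empty ROI mask")
        self.voxel_index = idx
        self.world_mm = nib.affines.apply_affine(self.affine, idx)

    @property
    def n_voxels(self) -> int:
        return self.voxel_index.shape[0]


@dataclass
class VoxelTimecourses:
    """ROI time series, one row per mask voxel in the mask ordering."""

    values: np.ndarray  # (voxels, timepoints)
    mask_ref: RoiMask
    tr_seconds: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("timecourses must be a 2D (voxels x time) matrix")
        if self.values.shape[0] != self.mask_ref.n_voxels:
            raise ValueError("row count does not match mask voxel count")
        if not np.isfinite(self.values).all():
            raise ValueError("timecourses contain non-finite values")


@dataclass
class ParticipantRecord:
    pid: str
    group: str  # control | ltle | rtle
    mts: str = "n/a"  # mts | no_mts | possible | n/a
    verbal_memory: float = np.nan
    visuospatial_memory: float = np.nan
    epi_hemisphere: str = "n/a"  # left | right | n/a

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.mts not in MTS_CODES:
            raise ValueError(f"unknown MTS code {self.mts!r}")
        if self.group == "control" and self.epi_hemisphere != "n/a":
            warnings.warn(
                f"control {self.pid} has epi_hemisphere set; coercing to n/a",
                stacklevel=2,
            )
            self.epi_hemisphere = "n/a"
        if self.group == "ltle" and self.epi_hemisphere == "n/a":
            self.epi_hemisphere = "left"
        if self.group == "rtle" and self.epi_hemisphere == "n/a":
            self.epi_hemisphere = "right"


def load_bold(path, tr_override: float | None = None, run_id: str = "") -> BoldRun:
    """Load a 4D NIfTI image as a :class:`BoldRun`.

    TR precedence: ``tr_override`` (config) wins over the header; a zero or
    missing header TR without an override is an error rather than a guess.
    """
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"expected a 4D image, got {img.ndim}D: {path}")
    header_tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    tr = float(tr_override) if tr_override is not None else header_tr
    if not tr > 0:
        raise ValueError(f"no usable TR in header of {path} and no override given")
    return BoldRun(
        data=np.asanyarray(img.dataobj, dtype=float),
        tr_seconds=tr,
        affine=img.affine,
        run_id=run_id or str(path),
    )


def make_mask(grid: np.ndarray, hemisphere: str, affine: np.ndarray) -> RoiMask:
    return RoiMask(grid=grid, hemisphere=hemisphere, affine=affine)


def load_mask(path, hemisphere: str | None = None) -> RoiMask:
    """Load a binary NIfTI mask; hemisphere defaults to the sign of mean world x
    (RAS+ assumed: negative x is left)."""
    img = nib.load(str(path))
    grid = np.asanyarray(img.dataobj) > 0
    if hemisphere is None:
        idx = np.argwhere(grid)
        if idx.shape[0] == 0:
            raise ValueError(f"empty mask: {path}")
        mean_x = nib.affines.apply_affine(img.affine, idx)[:, 0].mean()
        hemisphere = "left" if mean_x < 0 else "right"
    return RoiMask(grid=grid, hemisphere=hemisphere, affine=img.affine)


def extract_roi_timecourses(run: BoldRun, mask: RoiMask) -> VoxelTimecourses:
    """Gather the run's time series at the mask voxels (pure gather, fixed order)."""
    if mask.grid.shape != run.shape3d:
        raise ValueError(
            f"mask grid {mask.grid.shape} does not match run grid {run.shape3d}"
        )
    i, j, k = mask.voxel_index.T
    values = run.data[i, j, k, :]
    return VoxelTimecourses(values=values, mask_ref=mask, tr_seconds=run.tr_seconds)


def write_label_volume(labels: np.ndarray, mask: RoiMask, path) -> None:
    """Write per-voxel integer labels as a NIfTI volume (0 outside the mask)."""
    labels = np.asarray(labels)
    if labels.shape[0] != mask.n_voxels:
        raise ValueError(
            f"{labels.shape[0]} labels for a {mask.n_voxels}-voxel mask"
        )
    vol = np.zeros(mask.grid.shape, dtype=np.int16)
    i, j, k = mask.voxel_index.T
    vol[i, j, k] = labels
    nib.save(nib.Nifti1Image(vol, mask.affine), str(path))


def read_label_volume(path, mask: RoiMask) -> np.ndarray:
    img = nib.load(str(path))
    vol = np.asanyarray(img.dataobj)
    i, j, k = mask.voxel_index.T
    return vol[i, j, k].astype(int)


_REQUIRED_COLUMNS = ("pid", "group", "mts", "verbal_memory", "visuospatial_memory", "epi_hemisphere")


def load_participants(path) -> list[ParticipantRecord]:
    """Read participants.tsv into records.

    Unknown MTS status ("possible abnormality") is coded ``possible``;
    controls with a stray epileptogenic hemisphere are coerced to ``n/a``
    with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"participants file missing columns: {missing}")
    if df["pid"].duplicated().any():
        dups = df.loc[df["pid"].duplicated(), "pid"].tolist()
        raise ValueError(f"duplicate participant ids: {dups}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ParticipantRecord(
                pid=row.pid,
                group=str(row.group).lower(),
                mts=str(row.mts).lower() if str(row.mts).lower() != "nan" else "n/a",
                verbal_memory=_to_float(row.verbal_memory),
                visuospatial_memory=_to_float(row.visuospatial_memory),
                epi_hemisphere=(
                    str(row.epi_hemisphere).lower()
                    if str(row.epi_hemisphere).lower() != "nan"
                    else "n/a"
                ),
            )
        )
    return records


def participants_to_frame(records: list[ParticipantRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def write_participants(records: list[ParticipantRecord], path) -> None:
    participants_to_frame(records).to_csv(path, sep="\t", index=False)


def load_motion(path) -> np.ndarray:
    """Read a 6-column realignment trace (t x 6): translations mm, rotations rad."""
    arr = np.loadtxt(path)
    if arr.ndim == 1:
        arr = arr.reshape(1, -1)
    if arr.shape[1] != 6:
        raise ValueError(f"expected 6 motion columns, got {arr.shape[1]}")
    return arr


def _to_float(x) -> float:
    try:
        v = float(x)
    except (TypeError, ValueError):
        return np.nan
    return v
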
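"""Volume and point-table I/O and the voxel<->world coordinate contract.

The world frame is RAS-like throughout the package: +x is ML toward the
animal's right, +y is AP toward anterior, +z is DV toward dorsal.  Voxel
indices are 0-based and the affine maps voxel *centers* to world mm
(NIfTI convention), so fractional indices are meaningful everywhere.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import DimensionalityError, FormatError, InputError

__all__ = [
    "Modality",
    "Volume3D",
    "read_volume",
    "write_volume",
    "read_point_table",
    "write_point_table",
    "make_point_table",
]


class Modality(str, enum.Enum):
    MRI = "MRI"
    CT = "CT"
    LABEL = "LABEL"
    MASK = "MASK"


@dataclass
class Volume3D:
    """A 3D scalar grid plus its voxel-index -> world-mm affine.

    Parameters
    ----------
    data
        3D array of intensities (arbitrary units) or integer labels.
    affine
        4x4 matrix mapping homogeneous 0-based voxel indices (centers)
        to world coordinates in mm.
    modality
        One of :class:`Modality`; LABEL/MASK volumes must hold
        non-negative integers.
    """

    data: np.ndarray
    affine: np.ndarray
    modality: Modality = Modality.MRI

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D volume, got {self.data.ndim} dimensions"
            )
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise FormatError("affine upper-left 3x3 block is singular")
        self.modality = Modality(self.modality)
        if self.modality in (Modality.LABEL, Modality.MASK):
            if not np.issubdtype(self.data.dtype, np.integer) and not np.issubdtype(
                self.data.dtype, np.bool_
            ):
                raise FormatError("label/mask volumes must be integer-typed")
            if self.data.size and self.data.min() < 0:
                raise FormatError("label/mask volumes must be >= 0")

    # -- geometry ---------------------------------------------------------
    @property
    def voxel_sizes(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the 3x3 block)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_to_world(self, index: np.ndarray) -> np.ndarray:
        """Map (possibly fractional, possibly out-of-grid) voxel indices to
        world mm.  ``index`` is (3,) or (N, 3)."""
        idx = np.atleast_2d(np.asarray(index, dtype=float))
        out = idx @ self.affine[:3, :3].T + self.affine[:3, 3]
        return out[0] if np.asarray(index).ndim == 1 else out

    def world_to_voxel(self, point: np.ndarray) -> np.ndarray:
        """Exact inverse of :meth:`voxel_to_world`."""
        pts = np.atleast_2d(np.asarray(point, dtype=float))
        inv = np.linalg.inv(self.affine)
        out = pts @ inv[:3, :3].T + inv[:3, 3]
        return out[0] if np.asarray(point).ndim == 1 else out

    def world_bounds(self) -> np.ndarray:
        """(2, 3) array of min/max world coordinates of the grid corners."""
        n = np.array(self.shape) - 1
        corners = np.array(
            [[i * n[0], j * n[1], k * n[2]] for i in (0, 1) for j in (0, 1) for k in (0, 1)],
            dtype=float,
        )
        w = self.voxel_to_world(corners)
        return np.vstack([w.min(axis=0), w.max(axis=0)])


def read_volume(path: str | Path, modality: Modality | str | None = None) -> Volume3D:
    """Read a NIfTI-1 volume.

    Raises :class:`DimensionalityError` for non-3D images and
    :class:`FormatError` for unreadable files or singular affines.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise FormatError(f"not a readable NIfTI image: {path}: {exc}") from exc
    shape = img.shape
    if len(shape) == 4 and shape[3] == 1:
        # tolerate trailing singleton (some writers emit them)
        data = np.asanyarray(img.dataobj)[..., 0]
    elif len(shape) != 3:
        raise DimensionalityError(f"{path}: expected 3 spatial dims, got shape {shape}")
    else:
        data = np.asanyarray(img.dataobj)
    affine = img.affine
    if affine is None:
        raise FormatError(f"{path}: missing affine")
    if modality is None:
        modality = Modality.MASK if np.issubdtype(data.dtype, np.integer) else Modality.MRI
    return Volume3D(data=data, affine=np.asarray(affine, float), modality=modality)


def write_volume(vol: Volume3D, path: str | Path) -> Path:
    """Write as NIfTI-1; integer data round-trips bit-identically."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(vol.data, vol.affine)
    img.to_filename(str(path))
    return path


# -- point tables ---------------------------------------------------------

POINT_COLUMNS = ["id", "x", "y", "z", "source"]


def make_point_table(
    ids: list[str], points: np.ndarray, source: str = ""
) -> pd.DataFrame:
    """Build a point table (columns id, x, y, z, source; world mm)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(ids) != len(points):
        raise InputError("ids and points length mismatch")
    df = pd.DataFrame(
        {"id": ids, "x": points[:, 0], "y": points[:, 1], "z": points[:, 2],
         "source": source}
    )
    _validate_point_table(df)
    return df


def _validate_point_table(df: pd.DataFrame) -> None:
    missing = [c for c in POINT_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"point table missing columns: {missing}")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise InputError(f"duplicate point ids: {dups}")
    coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        raise InputError("non-finite coordinates in point table")


def read_point_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV point table (header row required)."""
    df = pd.read_csv(path, sep="\t")
    _validate_point_table(df)
    return df


def write_point_table(df: pd.DataFrame, path: str | Path) -> Path:
    _validate_point_table(df)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path
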
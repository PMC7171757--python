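"""Image, mask and table I/O.

Axis convention: arrays are indexed ``(z, y, x)`` and ``voxel_spacing_mm``
is given in the same order. Volumes and masks are required to be
pre-aligned on the same grid; no world-coordinate resampling is performed.
Feature tables are CSV files with one row per patient and columns named
``<structure>_<sequence>_<family>_<feature>``; missing feature values are
written as empty cells and read back as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import EmptyRoiError, GeometryError

__all__ = [
    "ImageVolume",
    "RoiMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_feature_table",
    "write_feature_table",
    "read_outcomes",
    "write_outcomes",
    "check_geometry",
]

SEQUENCES = ("T1CE", "T2")
STRUCTURES = ("tumor", "node")


@dataclass
class ImageVolume:
    """A single 3D MR volume with voxel spacing in millimetres."""

    intensities: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]
    sequence_label: str = "T1CE"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise GeometryError(
                f"volume must be 3D, got shape {self.intensities.shape}"
            )
        spacing = tuple(float(s) for s in self.voxel_spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise GeometryError(f"voxel spacing must be 3 positive values, got {spacing}")
        self.voxel_spacing_mm = spacing
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("volume contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class RoiMask:
    """A binary 3D mask for one structure, aligned to an :class:`ImageVolume`."""

    voxels: np.ndarray
    structure_label: str = "tumor"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels) > 0.5
        if self.voxels.ndim != 3:
            raise GeometryError(f"mask must be 3D, got shape {self.voxels.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


def check_geometry(volume: ImageVolume, mask: RoiMask, *, require_nonempty: bool = True,
                   volume_name: str = "volume", mask_name: str = "mask") -> None:
    """Validate that *mask* is usable with *volume*.

    Raises
    ------
    GeometryError
        If the shapes differ.
    EmptyRoiError
        If ``require_nonempty`` and the mask has no foreground voxel.
    """
    if volume.shape != mask.shape:
        raise GeometryError(
            f"shape mismatch between {volume_name} {volume.shape} and "
            f"{mask_name} {mask.shape}"
        )
    if require_nonempty and mask.n_voxels == 0:
        raise EmptyRoiError(f"{mask_name} has no foreground voxels")


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def write_volume(volume: ImageVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.intensities.astype(np.float32), _affine(volume.voxel_spacing_mm))
    img.header.set_zooms(volume.voxel_spacing_mm)
    nib.save(img, str(path))


def read_volume(path: str | Path, sequence_label: str = "T1CE") -> ImageVolume:
    """Read a NIfTI volume; spacing is taken from the header zooms."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(data, spacing, sequence_label)


def write_mask(mask: RoiMask, spacing: tuple[float, float, float], path: str | Path) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine(spacing))
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path, structure_label: str = "tumor") -> RoiMask:
    """Read a NIfTI mask; values are binarized at > 0.5."""
    img = nib.load(str(path))
    return RoiMask(np.asarray(img.dataobj, dtype=np.float64), structure_label)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a patients x features table as CSV (index = patient_id)."""
    if table.index.duplicated().any():
        dup = table.index[table.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate patient_id in feature table: {dup}")
    table.to_csv(path, index_label="patient_id")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature-table CSV; values are matched by column name."""
    table = pd.read_csv(path, index_col="patient_id")
    if table.index.duplicated().any():
        dup = table.index[table.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate patient_id in feature table: {dup}")
    return table


OUTCOME_COLUMNS = ["patient_id", "endpoint", "time_months", "event"]


def write_outcomes(outcomes: pd.DataFrame, path: str | Path) -> None:
    """Write the long-format outcome table (one row per patient per endpoint)."""
    missing = [c for c in OUTCOME_COLUMNS if c not in outcomes.columns]
    if missing:
        raise ValueError(f"outcome table missing columns: {missing}")
    outcomes[OUTCOME_COLUMNS].to_csv(path, index=False)


def read_outcomes(path: str | Path) -> pd.DataFrame:
    out = pd.read_csv(path)
    missing = [c for c in OUTCOME_COLUMNS if c not in out.columns]
    if missing:
        raise ValueError(f"outcome table missing columns: {missing}")
    out["event"] = out["event"].astype(int)
    return out
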
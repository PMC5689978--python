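"""Oriented voxel grids in the LPS patient frame.

All geometry in this package uses one convention: the DICOM patient
coordinate system (LPS: +x left, +y posterior, +z superior), millimetres,
and voxel-*center* addressing.  Arrays are indexed ``[k, j, i]`` where ``i``
runs along +x (columns), ``j`` along +y (rows) and ``k`` along +z (slices)
for the axis-aligned axial volumes this package supports.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

__all__ = ["CTVolume", "DoseGrid"]

HU_MIN, HU_MAX = -1024, 3071


def _check_geometry(origin, spacing, row_dir, col_dir):
    origin = np.asarray(origin, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    row_dir = np.asarray(row_dir, dtype=float)
    col_dir = np.asarray(col_dir, dtype=float)
    if origin.shape != (3,) or spacing.shape != (3,):
        raise InputError("origin and spacing must be length-3 vectors")
    if not (spacing > 0).all():
        raise InputError(f"spacing must be strictly positive, got {spacing}")
    for v in (row_dir, col_dir):
        if abs(np.linalg.norm(v) - 1.0) > 1e-6:
            raise InputError("orientation vectors must be unit length")
    if abs(row_dir @ col_dir) > 1e-6:
        raise InputError("orientation vectors must be orthogonal")
    return origin, spacing, row_dir, col_dir


@dataclass
class _Grid3D:
    """Shared geometry of CT and dose grids (axis-aligned, axial)."""

    origin: np.ndarray        # (3,) mm, center of voxel [0, 0, 0]
    spacing: np.ndarray       # (dx, dy, dz) mm = (column, row, slice) pitch
    row_dir: np.ndarray = field(default_factory=lambda: np.array([1.0, 0, 0]))
    col_dir: np.ndarray = field(default_factory=lambda: np.array([0, 1.0, 0]))

    @property
    def slice_dir(self) -> np.ndarray:
        return np.cross(self.row_dir, self.col_dir)

    @property
    def shape(self):
        return self._array().shape

    def axes(self):
        """Physical coordinates of voxel centers: 1D arrays (x, y, z) mm."""
        nz, ny, nx = self._array().shape
        x = self.origin[0] + self.spacing[0] * np.arange(nx)
        y = self.origin[1] + self.spacing[1] * np.arange(ny)
        z = self.origin[2] + self.spacing[2] * np.arange(nz)
        return x, y, z

    def center(self) -> np.ndarray:
        """Physical center of the volume, mm."""
        nz, ny, nx = self._array().shape
        return self.origin + self.spacing * (np.array([nx, ny, nz]) - 1) / 2.0

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def _array(self) -> np.ndarray:
        raise NotImplementedError


@dataclass
class CTVolume(_Grid3D):
    """A CT series as one oriented Hounsfield-unit cube.

    ``hu`` already has the rescale slope/intercept applied; ``rescale``
    records the (slope, intercept) seen on read, (1, 0) for synthetic
    volumes.
    """

    hu: np.ndarray = None
    rescale: tuple = (1.0, 0.0)

    def __post_init__(self):
        self.origin, self.spacing, self.row_dir, self.col_dir = \
            _check_geometry(self.origin, self.spacing, self.row_dir, self.col_dir)
        self.hu = np.asarray(self.hu)
        if self.hu.ndim != 3:
            raise InputError("hu must be a 3D array")
        if self.hu.min() < HU_MIN or self.hu.max() > HU_MAX:
            raise InputError(
                f"HU outside [{HU_MIN}, {HU_MAX}]: "
                f"range [{self.hu.min()}, {self.hu.max()}]")

    def _array(self):
        return self.hu


@dataclass
class DoseGrid(_Grid3D):
    """A 3D absorbed-dose cube in Gy, same patient frame as :class:`CTVolume`.

    Grid axes must be parallel to the CT axes; oblique grids are rejected
    upstream by the DICOM reader.
    """

    values: np.ndarray = None

    def __post_init__(self):
        self.origin, self.spacing, self.row_dir, self.col_dir = \
            _check_geometry(self.origin, self.spacing, self.row_dir, self.col_dir)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise InputError("dose values must be a 3D array")
        if (self.values < 0).any():
            raise InputError("dose values must be non-negative")

    def _array(self):
        return self.values
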
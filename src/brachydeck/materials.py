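"""CT-to-material conversion: calibration, truncation, binning, tissues.

The voxelized transport model needs, per voxel, a mass density and an
elemental composition.  Density comes from a piecewise-linear Hounsfield
-unit calibration and is truncated (toward zero) to two significant
digits; an optional binning scheme then collapses the density cube onto a
small set of representative values (54 by default) so the transport code
sees few distinct cell definitions.  Composition is looked up from a
23-row density-partitioned human-tissue table in the style of the
Schneider CT-segmentation approach.
"""
from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .grids import CTVolume

__all__ = [
    "HUCalibration", "BinningScheme", "TissueTable", "MaterialModel",
    "hu_to_density", "truncate_density", "bin_density", "assign_tissue",
    "downsample_inplane", "build_material_model",
]

_DATA = os.path.join(os.path.dirname(__file__), "data")

# element symbol -> atomic number, order matches the tissue CSV columns
ELEMENT_Z = {"H": 1, "C": 6, "N": 7, "O": 8, "Na": 11, "Mg": 12, "P": 15,
             "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20}


@dataclass
class HUCalibration:
    """Piecewise-linear HU -> mass density (g/cm3) curve.

    Outside the anchor range the end densities are used (clamping is the
    contract, not an error).
    """

    anchors_hu: np.ndarray
    anchors_density: np.ndarray

    def __post_init__(self):
        self.anchors_hu = np.asarray(self.anchors_hu, dtype=float)
        self.anchors_density = np.asarray(self.anchors_density, dtype=float)
        if (np.diff(self.anchors_hu) <= 0).any():
            raise InputError("calibration HU anchors must strictly increase")
        if (self.anchors_density <= 0).any():
            raise InputError("calibration densities must be positive")
        for hu, dens in [(-1000.0, None), (0.0, 1.00)]:
            if hu not in self.anchors_hu:
                raise InputError(f"calibration must anchor HU={hu:g}")
            if dens is not None:
                got = self.anchors_density[self.anchors_hu == hu][0]
                if abs(got - dens) > 1e-9:
                    raise InputError(
                        f"calibration must map HU=0 to 1.00 g/cm3, got {got}")

    @classmethod
    def from_csv(cls, path) -> "HUCalibration":
        arr = np.genfromtxt(path, delimiter=",", skip_header=1)
        return cls(arr[:, 0], arr[:, 1])

    @classmethod
    def default(cls) -> "HUCalibration":
        return cls.from_csv(os.path.join(_DATA, "hu_density_default.csv"))

    @property
    def air_density(self) -> float:
        return float(self.anchors_density[self.anchors_hu == -1000.0][0])


def hu_to_density(hu, cal: HUCalibration):
    """Interpolate HU to mass density; clamps beyond the anchor range."""
    return np.interp(hu, cal.anchors_hu, cal.anchors_density)


def truncate_density(d):
    """Truncate toward zero to two significant digits (1.789 -> 1.7).

    Truncation, not rounding: digits past the second significant one are
    dropped.  A small epsilon guards against representation error flipping
    an exactly-representable value down a step.
    """
    d = np.asarray(d, dtype=float)
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    if (d < 0).any():
        raise InputError("densities must be non-negative")
    out = np.zeros_like(d)
    pos = d > 0
    e = np.floor(np.log10(d[pos]) + 1e-12)
    scale = 10.0 ** (e - 1)
    out[pos] = np.floor(d[pos] / scale + 1e-6) * scale
    return float(out[0]) if scalar else out


@dataclass
class BinningScheme:
    """Density bins with one representative density per bin.

    Bins are half-open [low, high) with the last bin closed; inputs below
    the first edge or above the last clamp to the end bins.  The default
    scheme has 54 bins whose representatives all lie on the
    two-significant-digit grid, so truncation leaves them unchanged.
    """

    edges: np.ndarray            # (n+1,)
    representatives: np.ndarray  # (n,)

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        self.representatives = np.asarray(self.representatives, dtype=float)
        if len(self.edges) != len(self.representatives) + 1:
            raise InputError("need len(edges) == len(representatives) + 1")
        if (np.diff(self.edges) <= 0).any():
            raise InputError("bin edges must strictly increase")
        lo, hi = self.edges[:-1], self.edges[1:]
        inside = (self.representatives >= lo) & (self.representatives <= hi)
        if not inside.all():
            raise InputError("representatives must lie within their bins")

    @classmethod
    def from_csv(cls, path) -> "BinningScheme":
        arr = np.genfromtxt(path, delimiter=",", skip_header=1)
        return cls(np.append(arr[:, 0], arr[-1, 1]), arr[:, 2])

    @classmethod
    def default(cls) -> "BinningScheme":
        return cls.from_csv(os.path.join(_DATA, "density_bins_54.csv"))

    @property
    def n_bins(self) -> int:
        return len(self.representatives)


def bin_density(d, scheme: BinningScheme):
    """Map densities to their bin representative; end bins clamp."""
    d = np.asarray(d, dtype=float)
    idx = np.searchsorted(scheme.edges[1:-1], d, side="right")
    out = scheme.representatives[idx]
    return float(out) if d.ndim == 0 else out


@dataclass
class TissueTable:
    """Density-partitioned elemental compositions (23 rows by default).

    Ranges are half-open [low, high), last closed; each row's mass
    fractions sum to 1 within 1e-6.
    """

    names: list
    lows: np.ndarray
    highs: np.ndarray
    fractions: np.ndarray        # (n_rows, n_elements)
    elements: list = field(default_factory=lambda: list(ELEMENT_Z))

    def __post_init__(self):
        self.lows = np.asarray(self.lows, dtype=float)
        self.highs = np.asarray(self.highs, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if not np.allclose(self.lows[1:], self.highs[:-1], atol=1e-9):
            raise InputError("tissue ranges must partition without gaps")
        sums = self.fractions.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-6:
            raise InputError("tissue mass fractions must sum to 1 +- 1e-6")

    @classmethod
    def from_csv(cls, path) -> "TissueTable":
        with open(path, newline="") as f:
            rows = list(csv.reader(f))
        header = rows[0]
        elements = header[3:]
        names, lows, highs, fr = [], [], [], []
        for r in rows[1:]:
            names.append(r[0])
            lows.append(float(r[1]))
            highs.append(float(r[2]))
            fr.append([float(v) for v in r[3:]])
        return cls(names, np.array(lows), np.array(highs), np.array(fr),
                   elements)

    @classmethod
    def default(cls) -> "TissueTable":
        return cls.from_csv(os.path.join(_DATA, "tissues_23.csv"))

    @property
    def n_rows(self) -> int:
        return len(self.names)


def assign_tissue(d, table: TissueTable):
    """Index of the tissue row whose density range contains d.

    Boundary densities go to the upper row (half-open [low, high)
    ranges); values outside the table clamp to the end rows.
    """
    d = np.asarray(d, dtype=float)
    idx = np.searchsorted(table.highs[:-1], d, side="right")
    return int(idx) if d.ndim == 0 else idx


def downsample_inplane(ct: CTVolume, factor: int) -> CTVolume:
    """Block-average HU over factor x factor in-plane blocks.

    The slice count is unchanged and in-plane spacing scales by `factor`.
    Matrices not divisible by the factor are padded with air (-1000 HU)
    on the high-index side first.  Pooled HU is kept at float precision
    so the volume mean is conserved exactly under exact divisibility.
    """
    if factor not in (2, 4, 8):
        raise InputError(f"down-sampling factor must be 2, 4 or 8, "
                         f"got {factor}")
    hu = np.asarray(ct.hu, dtype=np.float64)
    nz, ny, nx = hu.shape
    py, px = (-ny) % factor, (-nx) % factor
    if py or px:
        hu = np.pad(hu, ((0, 0), (0, py), (0, px)), constant_values=-1000.0)
    nz, ny, nx = hu.shape
    pooled = hu.reshape(nz, ny // factor, factor, nx // factor, factor)
    pooled = pooled.mean(axis=(2, 4))
    new_spacing = ct.spacing * np.array([factor, factor, 1.0])
    # origin shifts so pooled voxel centers sit at block centers
    shift = (factor - 1) / 2.0
    new_origin = ct.origin + shift * np.array(
        [ct.spacing[0], ct.spacing[1], 0.0])
    return CTVolume(origin=new_origin, spacing=new_spacing,
                    row_dir=ct.row_dir.copy(), col_dir=ct.col_dir.copy(),
                    hu=pooled, rescale=ct.rescale)


@dataclass
class MaterialModel:
    """Per-voxel density and tissue index plus provenance of the tables."""

    density: np.ndarray          # g/cm3, truncated (and binned if enabled)
    material_index: np.ndarray   # rows into `table`
    origin: np.ndarray
    spacing: np.ndarray
    calibration: HUCalibration = None
    scheme: BinningScheme | None = None
    table: TissueTable = None

    def __post_init__(self):
        if self.density.shape != self.material_index.shape:
            raise InputError("density / material_index shape mismatch")

    @property
    def shape(self):
        return self.density.shape

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.density.shape))

    def pairs(self):
        """Distinct (material_index, density) pairs present, sorted."""
        ud, inv = np.unique(self.density.ravel(), return_inverse=True)
        code = self.material_index.ravel().astype(np.int64) * len(ud) + inv
        codes = np.unique(code)
        return [(int(c // len(ud)), float(ud[c % len(ud)])) for c in codes]


def build_material_model(ct: CTVolume, cal: HUCalibration | None = None,
                         scheme: BinningScheme | None = None,
                         table: TissueTable | None = None) -> MaterialModel:
    """Calibrate -> truncate -> (optionally) bin, then assign tissues.

    One lattice element per CT voxel: the model arrays are congruent with
    the HU cube.  Pass ``scheme=None`` to skip density binning.
    """
    cal = cal or HUCalibration.default()
    table = table or TissueTable.default()
    density = hu_to_density(np.asarray(ct.hu, dtype=float), cal)
    density = truncate_density(density)
    if scheme is not None:
        density = bin_density(density, scheme)
    material = assign_tissue(density, table)
    return MaterialModel(density=density, material_index=material,
                         origin=ct.origin.copy(), spacing=ct.spacing.copy(),
                         calibration=cal, scheme=scheme, table=table)
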
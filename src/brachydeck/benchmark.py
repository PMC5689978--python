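"""Dose-comparison computations for treatment-planning QA.

Percentage-difference maps and histograms between a test dose grid (a
planning-system export) and a reference (a transport calculation), TG43
parameter extraction from rendered dose cubes via the line-source
approximation, cumulative dose-volume histograms from contoured
structures, and a morphological skin surrogate for structures that were
never contoured.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as MplPath
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .errors import InputError
from .grids import DoseGrid
from .plan import Structure
from .sources import RigidTransform
from .tg43 import R0_CM, THETA0_DEG, geometry_factor

__all__ = [
    "ComparisonMap", "DVHCurve", "diff_map", "diff_histogram",
    "extract_g", "extract_F", "compute_dvh", "derive_skin",
    "rasterize_structure",
]


@dataclass
class ComparisonMap:
    """Voxel-wise percentage dose differences, 100 * (test - ref) / ref."""

    diff: np.ndarray          # %, NaN outside the mask
    mask: np.ndarray          # bool, compared voxels
    summary: dict = field(init=False)

    def __post_init__(self):
        vals = self.diff[self.mask]
        self.summary = {
            "min_pct": float(vals.min()) if vals.size else np.nan,
            "max_pct": float(vals.max()) if vals.size else np.nan,
            "fraction_within_2pct": float((np.abs(vals) <= 2.0).mean())
            if vals.size else np.nan,
            "n_compared": int(vals.size),
        }


def _resample_like(test: DoseGrid, ref: DoseGrid) -> np.ndarray:
    """Trilinear resampling of test onto ref's voxel centers."""
    tx, ty, tz = test.axes()
    interp = RegularGridInterpolator((tz, ty, tx), test.values,
                                     bounds_error=False, fill_value=0.0)
    rx, ry, rz = ref.axes()
    Z, Y, X = np.meshgrid(rz, ry, rx, indexing="ij")
    return interp(np.stack([Z, Y, X], axis=-1))


def diff_map(test: DoseGrid, ref: DoseGrid, body_mask=None,
             density=None, air_threshold: float = 0.05) -> ComparisonMap:
    """Percentage difference of two dose grids on comparable voxels.

    Voxels where the reference is zero are never compared; a body mask
    and/or a density cube (voxels below `air_threshold` g/cm3 are treated
    as air) further restrict the comparison, mirroring the usual practice
    of ignoring points outside the patient or in air.  Grids with matching
    physical extents but different spacing are resampled trilinearly onto
    the reference.
    """
    if test.values.shape == ref.values.shape and \
            np.allclose(test.origin, ref.origin, atol=1e-6) and \
            np.allclose(test.spacing, ref.spacing, atol=1e-9):
        tv = test.values
    else:
        ext_t = test.origin + test.spacing * (np.array(
            test.values.shape)[::-1] - 1)
        ext_r = ref.origin + ref.spacing * (np.array(
            ref.values.shape)[::-1] - 1)
        if not (np.allclose(test.origin, ref.origin, atol=0.5)
                and np.allclose(ext_t, ext_r, atol=0.5)):
            raise InputError("dose grids are not congruent and their "
                             "extents differ; cannot compare")
        tv = _resample_like(test, ref)
    mask = ref.values > 0
    if body_mask is not None:
        if body_mask.shape != ref.values.shape:
            raise InputError("body mask shape mismatch")
        mask &= body_mask
    if density is not None:
        if density.shape != ref.values.shape:
            raise InputError("density cube shape mismatch")
        mask &= density >= air_threshold
    diff = np.full(ref.values.shape, np.nan)
    diff[mask] = 100.0 * (tv[mask] - ref.values[mask]) / ref.values[mask]
    return ComparisonMap(diff, mask)


def diff_histogram(cmap: ComparisonMap, bin_width: float = 0.5):
    """(bin_edges %, counts) over the compared voxels; counts sum to the
    mask size."""
    vals = cmap.diff[cmap.mask]
    lo = np.floor(vals.min() / bin_width) * bin_width
    hi = np.ceil(vals.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(vals, bins=edges)
    return edges, counts


def _sample_dose(dose: DoseGrid):
    x, y, z = dose.axes()
    return RegularGridInterpolator((z, y, x), dose.values,
                                   bounds_error=True)


def _dose_at(interp, points_mm):
    pts = np.asarray(points_mm, dtype=float)
    return interp(pts[..., ::-1])   # (x,y,z) -> (z,y,x)


def extract_g(dose: DoseGrid, pose: RigidTransform, L: float,
              r_values_cm) -> np.ndarray:
    """Radial dose function from a dose grid via the line-source model.

    g_L(r) = [D(r,90) / D(1 cm,90)] * [G_L(1 cm,90) / G_L(r,90)], with the
    dose sampled trilinearly on the transverse plane and averaged over the
    two opposite transverse directions.  Returns g values aligned with
    `r_values_cm`; g(1 cm) = 1 exactly by construction.
    """
    r = np.asarray(r_values_cm, dtype=float)
    interp = _sample_dose(dose)
    ex = pose.apply_vector([1.0, 0.0, 0.0])   # transverse unit vector
    center = pose.translation

    def transverse_dose(radii_cm):
        mm = np.asarray(radii_cm)[:, None] * 10.0
        d1 = _dose_at(interp, center + mm * ex)
        d2 = _dose_at(interp, center - mm * ex)
        return 0.5 * (d1 + d2)

    D = transverse_dose(r)
    D0 = transverse_dose(np.array([R0_CM]))[0]
    G = geometry_factor(r, THETA0_DEG, L)
    G0 = geometry_factor(R0_CM, THETA0_DEG, L)
    return (D / D0) * (G0 / G)


def extract_F(dose: DoseGrid, pose: RigidTransform, L: float, r_cm: float,
              theta_values_deg) -> np.ndarray:
    """2D anisotropy function at radius r from a dose grid.

    F(r,theta) = [D(r,theta) / D(r,90)] * [G_L(r,90) / G_L(r,theta)];
    angles measured from the source +z (tip) axis.  F(r, 90) = 1 exactly.
    """
    theta = np.asarray(theta_values_deg, dtype=float)
    interp = _sample_dose(dose)
    th = np.deg2rad(theta)
    # local (sin t, 0, cos t) * r mapped to the patient frame
    local = np.stack([np.sin(th), np.zeros_like(th), np.cos(th)],
                     axis=-1) * (r_cm * 10.0)
    pts = local @ pose.rotation.T + pose.translation
    D = _dose_at(interp, pts)
    local0 = np.array([r_cm * 10.0, 0.0, 0.0])
    D0 = _dose_at(interp, (pose.rotation @ local0 + pose.translation)[None])[0]
    G = geometry_factor(np.full_like(theta, r_cm), theta, L)
    G0 = geometry_factor(r_cm, THETA0_DEG, L)
    return (D / D0) * (G0 / G)


def rasterize_structure(structure: Structure, grid) -> np.ndarray:
    """Voxel-center rasterization of per-slice contours (even-odd rule).

    Each contour polygon toggles membership of the voxel centers it
    encloses on its slice, so holes and islands behave as in planar
    even-odd filling.
    """
    x, y, z = grid.axes()
    nz = len(z)
    mask = np.zeros(grid.shape, dtype=bool)
    X, Y = np.meshgrid(x, y, indexing="xy")   # (ny, nx)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    dz = grid.spacing[2]
    for poly in structure.contours:
        zc = float(np.mean(poly[:, 2]))
        k = int(round((zc - grid.origin[2]) / dz))
        if k < 0 or k >= nz or abs(z[k] - zc) > dz / 2 + 1e-6:
            continue
        inside = MplPath(poly[:, :2]).contains_points(pts)
        mask[k] ^= inside.reshape(X.shape)
    return mask


@dataclass
class DVHCurve:
    """Cumulative DVH: % of structure volume receiving >= dose."""

    structure: str
    dose_bins: np.ndarray          # Gy, left edges
    cumulative_volume: np.ndarray  # %
    voxel_count: int
    voxel_volume_mm3: float

    @property
    def volume_cm3(self) -> float:
        return self.voxel_count * self.voxel_volume_mm3 / 1000.0


def compute_dvh(dose: DoseGrid, structure: Structure,
                bin_width: float = 0.1) -> DVHCurve:
    """Cumulative DVH of a contoured structure on the dose grid."""
    mask = rasterize_structure(structure, dose)
    n = int(mask.sum())
    if n == 0:
        raise InputError(f"structure {structure.name!r} covers no voxel "
                         "of the dose grid")
    doses = dose.values[mask]
    top = doses.max() + 2 * bin_width
    bins = np.arange(0.0, top, bin_width)
    cumulative = 100.0 * (doses[None, :] >= bins[:, None]).mean(axis=1)
    return DVHCurve(structure.name, bins, cumulative, n,
                    dose.voxel_volume_mm3())


def derive_skin(body_mask: np.ndarray) -> np.ndarray:
    """Skin surrogate: dilation minus erosion, one pass each, per slice.

    Uses the 3x3 cross (city-block) structuring element applied in 2D
    slice by slice, because contours are per-slice planar objects.
    """
    body_mask = np.asarray(body_mask, dtype=bool)
    cross = np.zeros((1, 3, 3), dtype=bool)
    cross[0] = [[0, 1, 0], [1, 1, 1], [0, 1, 0]]
    dil = ndimage.binary_dilation(body_mask, structure=cross)
    ero = ndimage.binary_erosion(body_mask, structure=cross)
    return dil & ~ero
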
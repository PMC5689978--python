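"""Synthetic phantoms, plans and structures for end-to-end testing.

The reference fixture is a 15 cm-radius water sphere in air rendered as an
axial CT series (340 mm field of view, 256 x 256 matrix, 1 mm slices) with
a single central source dwell — the geometry under which the TG43 dose
formalism is exact, so a TG43-rendered dose grid is directly comparable
with any transport result in the same model.  A synthetic multicatheter
breast-like plan (32 Gy prescription) exercises the multi-dwell machinery.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .errors import InputError
from .grids import CTVolume
from .plan import PlanModel, Structure, StructureSet
from .sources import Catheter, DwellPosition

__all__ = [
    "PhantomSpec", "make_water_sphere_ct", "make_single_dwell_plan",
    "make_multicatheter_plan", "make_tg43_conditions", "make_structures",
]

HU_WATER = 0
HU_AIR = -1000


@dataclass
class PhantomSpec:
    """Geometry of a generated phantom CT."""

    kind: str = "water_sphere"
    radius: float = 150.0          # mm
    fov: float = 340.0             # mm
    matrix: int = 256
    slice_thickness: float = 1.0   # mm
    n_slices: int = 320
    hu_inside: int = HU_WATER
    hu_outside: int = HU_AIR

    def __post_init__(self):
        if self.kind == "water_sphere" and \
                self.n_slices * self.slice_thickness < 2 * self.radius:
            raise InputError(
                f"sphere (diameter {2 * self.radius} mm) does not fit in "
                f"{self.n_slices} x {self.slice_thickness} mm slices")

    @property
    def pixel(self) -> float:
        return self.fov / self.matrix


def _centered_volume(spec: PhantomSpec):
    """Empty HU cube centered on the patient-frame origin."""
    dp = spec.pixel
    n, ns = spec.matrix, spec.n_slices
    spacing = np.array([dp, dp, spec.slice_thickness])
    origin = -spacing * (np.array([n, n, ns]) - 1) / 2.0
    hu = np.full((ns, n, n), spec.hu_outside, dtype=np.int16)
    return origin, spacing, hu


def make_water_sphere_ct(spec: PhantomSpec | None = None) -> CTVolume:
    """Binary water-in-air sphere; inside/outside decided at voxel centers."""
    spec = spec or PhantomSpec()
    if 2 * spec.radius > spec.fov:
        raise InputError(f"sphere (diameter {2 * spec.radius} mm) exceeds "
                         f"the {spec.fov} mm field of view")
    origin, spacing, hu = _centered_volume(spec)
    x = origin[0] + spacing[0] * np.arange(spec.matrix)
    y = origin[1] + spacing[1] * np.arange(spec.matrix)
    z = origin[2] + spacing[2] * np.arange(spec.n_slices)
    r2 = (z[:, None, None] ** 2 + y[None, :, None] ** 2
          + x[None, None, :] ** 2)
    hu[r2 <= spec.radius ** 2] = spec.hu_inside
    return CTVolume(origin=origin, spacing=spacing, hu=hu)


def _straight_catheter(cid, center, direction, half_reach=15.0, step=5.0):
    """Control points at center +/- k*step along `direction`, tip first.

    The dwell center itself is deliberately not a control point, so plan
    round trips through the DICOM dialect are exact.
    """
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    ks = np.arange(half_reach, -half_reach - step / 2, -step)
    ks = ks[np.abs(ks) > 1e-9]
    return Catheter(cid, np.asarray(center, dtype=float)
                    + np.outer(ks, direction))


def make_single_dwell_plan(center=(0.0, 0.0, 0.0), time: float = 300.0,
                           source_id: str = "mHDR-v2") -> PlanModel:
    """One straight catheter along +z with a single dwell at `center`."""
    cath = _straight_catheter(1, center, (0, 0, 1))
    dwell = DwellPosition(1, np.asarray(center, dtype=float), time, 0)
    return PlanModel(source_id, [cath], [dwell])


def make_multicatheter_plan(n_catheters: int = 6,
                            dwells_per_catheter: int = 10,
                            spacing: float = 5.0,
                            time_profile: str = "random",
                            prescription: float = 32.0,
                            seed: int = 0,
                            source_id: str = "mHDR-v2",
                            pitch: float = 15.0) -> PlanModel:
    """Synthetic breast-like implant: parallel catheters on an xy grid.

    Catheters run along +z (tip superior), arranged on a `pitch`-mm grid;
    dwells step by `spacing` mm.  Dwell times are 10 s each
    (``time_profile="uniform"``) or drawn uniformly from 5-20 s
    (``"random"``, reproducible under `seed`).
    """
    rng = np.random.default_rng(seed)
    ncols = int(np.ceil(np.sqrt(n_catheters)))
    span = (dwells_per_catheter - 1) * spacing
    catheters, dwells = [], []
    idx = 0
    for c in range(n_catheters):
        gx, gy = c % ncols, c // ncols
        x0 = (gx - (ncols - 1) / 2) * pitch
        y0 = (gy - (np.ceil(n_catheters / ncols) - 1) / 2) * pitch
        zs = -span / 2 + spacing * np.arange(dwells_per_catheter)
        # path points offset half a step from the dwells (plus end margins)
        pz = np.arange(zs[-1] + spacing / 2 + spacing,
                       zs[0] - spacing / 2 - 1.5 * spacing, -spacing)
        cath = Catheter(c + 1, np.column_stack(
            [np.full_like(pz, x0), np.full_like(pz, y0), pz]))
        catheters.append(cath)
        if time_profile == "uniform":
            times = np.full(dwells_per_catheter, 10.0)
        elif time_profile == "random":
            times = rng.uniform(5.0, 20.0, dwells_per_catheter)
        else:
            raise InputError(f"unknown time profile {time_profile!r}")
        for z, t in zip(zs[::-1], times):   # tip-most dwell first
            dwells.append(DwellPosition(c + 1, np.array([x0, y0, z]),
                                        float(t), idx))
            idx += 1
    return PlanModel(source_id, catheters, dwells,
                     prescription_dose=prescription)


def make_tg43_conditions(ct: CTVolume, plan: PlanModel,
                         radius: float = 150.0) -> CTVolume:
    """Overwrite a CT with the two-valued TG43 benchmarking geometry.

    Voxels within `radius` mm of the (unweighted) centroid of the dwell
    distribution become water (HU 0), everything else air (HU -1000), so
    the transport geometry matches the uniform-water assumption of the
    TG43 formalism.  Idempotent.
    """
    if not plan.dwells:
        raise InputError("plan has no dwell positions")
    centroid = plan.dwell_coordinates().mean(axis=0)
    x, y, z = ct.axes()
    r2 = ((z[:, None, None] - centroid[2]) ** 2
          + (y[None, :, None] - centroid[1]) ** 2
          + (x[None, None, :] - centroid[0]) ** 2)
    hu = np.where(r2 <= radius ** 2, HU_WATER, HU_AIR).astype(np.int16)
    return CTVolume(origin=ct.origin.copy(), spacing=ct.spacing.copy(),
                    row_dir=ct.row_dir.copy(), col_dir=ct.col_dir.copy(),
                    hu=hu)


def _mask_contours(mask2d, x, y, z_mm):
    """Closed polygons (mm) tracing a binary slice at the half level."""
    polys = []
    padded = np.pad(mask2d.astype(float), 1)
    for c in measure.find_contours(padded, 0.5):
        rows, cols = c[:, 0] - 1, c[:, 1] - 1
        # row index -> y, column index -> x; linear because axes are uniform
        px = np.interp(cols, np.arange(len(x)), x)
        py = np.interp(rows, np.arange(len(y)), y)
        if np.hypot(px[0] - px[-1], py[0] - py[-1]) < 1e-9:
            px, py = px[:-1], py[:-1]   # keep polygons open-ended (closed implicitly)
        if len(px) < 3:
            continue
        polys.append(np.column_stack([px, py, np.full_like(px, z_mm)]))
    return polys


def make_structures(ct: CTVolume, plan: PlanModel,
                    ptv_margin: float = 10.0,
                    body_threshold: float = -500.0) -> StructureSet:
    """BODY (phantom surface) and PTV (dwell positions + margin) contours."""
    x, y, z = ct.axes()
    body_mask = np.asarray(ct.hu) > body_threshold
    centers = plan.dwell_coordinates()
    ptv_mask = np.zeros(ct.hu.shape, dtype=bool)
    for c in centers:
        r2 = ((z[:, None, None] - c[2]) ** 2 + (y[None, :, None] - c[1]) ** 2
              + (x[None, None, :] - c[0]) ** 2)
        ptv_mask |= r2 <= ptv_margin ** 2
    structures = []
    for name, mask, color in [("BODY", body_mask, (0, 255, 0)),
                              ("PTV", ptv_mask, (255, 0, 0))]:
        contours = []
        for k in range(mask.shape[0]):
            if mask[k].any():
                contours.extend(_mask_contours(mask[k], x, y, z[k]))
        structures.append(Structure(name, contours, color))
    return StructureSet(structures)
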
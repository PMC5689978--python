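"""TG43 line-source dose engine.

The AAPM TG43 formalism expresses the dose rate in water around a sealed
photon source as

    Ddot(r, theta) = Sk * Lambda * [G_L(r,theta) / G_L(r0,theta0)]
                     * g_L(r) * F(r,theta)

with Sk the air-kerma strength (U), Lambda the dose-rate constant
(cGy h-1 U-1), G_L the line-source geometry factor, g_L the radial dose
function and F the 2D anisotropy function, normalized at r0 = 1 cm,
theta0 = 90 deg.  theta is measured from the source long axis (+z,
tip side); theta = 180 deg faces the cable.

This engine renders reference RT Dose grids (the in-repo stand-in for a
planning system's TG43 export) and supplies the geometry factor used when
benchmark extraction inverts a dose grid back to g_L and F tables.
"""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .errors import InputError
from .grids import DoseGrid
from .plan import PlanModel
from .sources import dwell_transform

__all__ = ["TG43SourceData", "geometry_factor", "dose_rate", "render_rtdose"]

log = logging.getLogger(__name__)

_DATA = os.path.join(os.path.dirname(__file__), "data")

R0_CM = 1.0
THETA0_DEG = 90.0
_SIN_EPS = 1e-6


@dataclass
class TG43SourceData:
    """Consensus-style source dosimetry parameters and tables.

    The bundled default tables are smooth synthetic curves for testing;
    published consensus data can be dropped in as CSV.
    """

    Lambda: float                 # cGy / (h U)
    L: float                      # active length, cm
    Sk: float = 1.0               # air-kerma strength, U
    g_r: np.ndarray = None        # (n,) radii, cm
    g_values: np.ndarray = None   # (n,)
    F_r: np.ndarray = None        # (m,) radii, cm
    F_theta: np.ndarray = None    # (k,) degrees
    F_values: np.ndarray = None   # (m, k)

    def __post_init__(self):
        self.g_r = np.asarray(self.g_r, dtype=float)
        self.g_values = np.asarray(self.g_values, dtype=float)
        self.F_r = np.asarray(self.F_r, dtype=float)
        self.F_theta = np.asarray(self.F_theta, dtype=float)
        self.F_values = np.asarray(self.F_values, dtype=float)
        for r in (self.g_r, self.F_r, self.F_theta):
            if (np.diff(r) <= 0).any():
                raise InputError("table abscissae must strictly increase")
        i0 = np.searchsorted(self.g_r, R0_CM)
        if not (self.g_r[i0] == R0_CM and abs(self.g_values[i0] - 1) < 1e-9):
            raise InputError("g_L table must contain g(1 cm) = 1")
        j0 = np.flatnonzero(self.F_theta == THETA0_DEG)
        if not j0.size or np.abs(self.F_values[:, j0[0]] - 1).max() > 1e-9:
            raise InputError("F table must satisfy F(r, 90 deg) = 1")
        self._g_interp = None
        self._F_interp = None

    @classmethod
    def synthetic(cls, Lambda: float = 1.109, L: float = 0.36,
                  Sk: float = 1.0) -> "TG43SourceData":
        """Bundled smooth test tables (mHDR-v2-like active length)."""
        g = np.genfromtxt(os.path.join(_DATA, "tg43_g_synthetic.csv"),
                          delimiter=",", skip_header=1)
        with open(os.path.join(_DATA, "tg43_F_synthetic.csv")) as f:
            header = f.readline().strip().split(",")
        theta = np.array([float(v) for v in header[1:]])
        F = np.genfromtxt(os.path.join(_DATA, "tg43_F_synthetic.csv"),
                          delimiter=",", skip_header=1)
        return cls(Lambda=Lambda, L=L, Sk=Sk, g_r=g[:, 0], g_values=g[:, 1],
                   F_r=F[:, 0], F_theta=theta, F_values=F[:, 1:])

    def g(self, r):
        """g_L(r), linear in log r; clamps outside the table with a warning."""
        r = np.asarray(r, dtype=float)
        if (r < self.g_r[0]).any() or (r > self.g_r[-1]).any():
            log.warning("g_L(r) clamped outside [%g, %g] cm",
                        self.g_r[0], self.g_r[-1])
        return np.interp(np.log(np.clip(r, self.g_r[0], self.g_r[-1])),
                         np.log(self.g_r), self.g_values)

    def F(self, r, theta):
        """F(r, theta) by bilinear interpolation; clamps outside the table."""
        if self._F_interp is None:
            self._F_interp = RegularGridInterpolator(
                (self.F_r, self.F_theta), self.F_values, method="linear")
        r = np.clip(np.asarray(r, dtype=float), self.F_r[0], self.F_r[-1])
        theta = np.clip(np.asarray(theta, dtype=float), self.F_theta[0],
                        self.F_theta[-1])
        shape = np.broadcast(r, theta).shape
        pts = np.column_stack([np.broadcast_to(r, shape).ravel(),
                               np.broadcast_to(theta, shape).ravel()])
        out = self._F_interp(pts)
        return out.reshape(shape) if shape else float(out[0])


def geometry_factor(r, theta, L):
    """Line-source geometry factor G_L(r, theta), cm^-2.

    G_L = beta / (L r sin(theta)) with beta the angle subtended by the
    active line at the point, computed in the numerically stable
    two-arctangent difference form; on the long axis (sin(theta) below
    1e-6) the closed form 1/(r^2 - L^2/4) is used, which requires the
    point to lie outside the source (r > L/2).  L = 0 reduces to the
    point-source 1/r^2.
    """
    r, theta_deg = np.broadcast_arrays(np.asarray(r, dtype=float),
                                       np.asarray(theta, dtype=float))
    scalar = r.ndim == 0
    r = np.atleast_1d(r).astype(float)
    theta_deg = np.atleast_1d(theta_deg).astype(float)
    if (r <= 0).any():
        raise InputError("geometry factor requires r > 0")
    if L == 0:
        out = 1.0 / r ** 2
        return float(out[0]) if scalar else out
    th = np.deg2rad(theta_deg)
    sin_t, cos_t = np.sin(th), np.cos(th)
    on_axis = np.abs(sin_t) < _SIN_EPS
    if (on_axis & (r <= L / 2)).any():
        raise InputError("point on the long axis inside the source "
                         f"(r <= L/2 = {L / 2:g} cm)")
    # off axis: beta from the two-angle arctangent difference
    y = r * sin_t
    x = r * cos_t
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.arctan2(x + L / 2, y) - np.arctan2(x - L / 2, y)
        out = np.where(on_axis, 0.0, beta / (L * np.where(on_axis, 1.0, y)))
    out = np.where(on_axis, 1.0 / np.maximum(r ** 2 - L ** 2 / 4, 1e-300),
                   out)
    return float(out[0]) if scalar else out


def dose_rate(r, theta, data: TG43SourceData):
    """TG43 dose rate (cGy/h) at polar coordinates in the source frame."""
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta, dtype=float)
    G = geometry_factor(r, theta, data.L)
    G0 = geometry_factor(R0_CM, THETA0_DEG, data.L)
    return data.Sk * data.Lambda * (G / G0) * data.g(r) * data.F(r, theta)


def render_rtdose(plan: PlanModel, data: TG43SourceData,
                  origin, spacing, shape, r_min_cm: float = 0.2) -> DoseGrid:
    """Sum the TG43 dose of every dwell over a grid; result in Gy.

    Voxel centers are transformed into each dwell's source frame through
    its rigid placement transform.  Radii below `r_min_cm` (points inside
    or on the source capsule) are clamped to `r_min_cm` so the few voxels
    containing the source stay finite.  Plan times are seconds and TG43
    dose rates cGy/h: the 1/3600 h/s and 1/100 cGy/Gy conversions are
    applied here, once.
    """
    origin = np.asarray(origin, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    nz, ny, nx = shape
    x = origin[0] + spacing[0] * np.arange(nx)
    y = origin[1] + spacing[1] * np.arange(ny)
    z = origin[2] + spacing[2] * np.arange(nz)
    dose = np.zeros(shape, dtype=np.float64)
    for dwell in plan.dwells:
        if dwell.time == 0:
            continue
        T = dwell_transform(dwell, plan.catheter(dwell.catheter_id))
        # local coordinates of all voxel centers: R^T (p - t)
        R, t = T.rotation, T.translation
        dx = x - t[0]
        dy = y - t[1]
        dz = z - t[2]
        lx = (R[0, 0] * dx[None, None, :] + R[1, 0] * dy[None, :, None]
              + R[2, 0] * dz[:, None, None])
        ly = (R[0, 1] * dx[None, None, :] + R[1, 1] * dy[None, :, None]
              + R[2, 1] * dz[:, None, None])
        lz = (R[0, 2] * dx[None, None, :] + R[1, 2] * dy[None, :, None]
              + R[2, 2] * dz[:, None, None])
        r_cm = np.sqrt(lx ** 2 + ly ** 2 + lz ** 2) / 10.0
        r_cm = np.maximum(r_cm, r_min_cm)
        theta = np.rad2deg(np.arccos(np.clip(lz / (10.0 * r_cm), -1.0, 1.0)))
        dose += dose_rate(r_cm, theta, data) * dwell.time / 3600.0 / 100.0
    return DoseGrid(origin=origin, spacing=spacing, values=dose)
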
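"""Source kinematics and phase-space handling.

An HDR afterloader drives a single stepping source through implanted
catheters.  The plan stores only the source *center* at each dwell
position; the source orientation there is reconstructed from the catheter
trajectory, using the two catheter control points closest to the dwell.
Photons are replayed from a precalculated phase-space file recorded in the
source-local frame (origin at the source center, +z along the source long
axis toward the catheter tip) and mapped into the patient frame by a rigid
transform per dwell, chosen per photon with probability equal to the
dwell's share of the total irradiation time.
"""
from __future__ import annotations

import os
import struct
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, ValidationError

__all__ = [
    "Catheter", "DwellPosition", "RigidTransform", "SamplingTable",
    "PhaseSpace", "dwell_transform", "sampling_table", "sample_dwells",
    "read_phase_space", "write_phase_space", "toy_phase_space",
    "transform_record", "ir192_spectrum",
]

E_MAX_MEV = 1.4


@dataclass
class Catheter:
    """Ordered catheter reconstruction points, tip first, mm."""

    id: int
    control_points: np.ndarray   # (N, 3)

    def __post_init__(self):
        self.control_points = np.asarray(self.control_points, dtype=float)
        if self.control_points.ndim != 2 or self.control_points.shape[1] != 3:
            raise InputError("control_points must be (N, 3)")
        if len(self.control_points) < 2:
            raise InputError(f"catheter {self.id}: need >= 2 control points")
        steps = np.linalg.norm(np.diff(self.control_points, axis=0), axis=1)
        if (steps < 1e-9).any():
            raise InputError(
                f"catheter {self.id}: consecutive control points coincide")


@dataclass
class DwellPosition:
    catheter_id: int
    center: np.ndarray   # (3,) mm
    time: float          # s
    index: int = 0

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if self.time < 0:
            raise InputError(f"dwell {self.index}: negative time {self.time}")


@dataclass
class RigidTransform:
    """x_patient = R @ x_local + t."""

    rotation: np.ndarray      # (3, 3)
    translation: np.ndarray   # (3,) mm

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        R = self.rotation
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-9:
            raise ValidationError("rotation not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValidationError("rotation determinant != +1")

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T,
                              -self.rotation.T @ self.translation)

    def apply_point(self, p):
        return np.asarray(p, dtype=float) @ self.rotation.T + self.translation

    def apply_vector(self, v):
        return np.asarray(v, dtype=float) @ self.rotation.T


def _rotation_from_z_to(d: np.ndarray) -> np.ndarray:
    """Minimal rotation taking (0,0,1) onto unit vector d (Rodrigues).

    The rotation axis is z x d; rotation about the source's own long axis
    is left unconstrained because the source is axisymmetric.
    """
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.clip(z @ d, -1.0, 1.0))
    axis = np.cross(z, d)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about x
        return np.diag([1.0, -1.0, -1.0])
    axis = axis / s
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def dwell_transform(dwell: DwellPosition, cath: Catheter) -> RigidTransform:
    """Rigid placement of the source at a dwell position.

    The source long axis (+z, tip-ward) is aligned with the unit vector
    from the higher-index to the lower-index of the two catheter control
    points nearest the dwell center (control points are ordered tip
    first, so lower index = closer to the tip).  Distance ties are broken
    toward the tip.
    """
    pts = cath.control_points
    dist = np.linalg.norm(pts - dwell.center, axis=1)
    order = np.lexsort((np.arange(len(pts)), np.round(dist, 9)))
    i0, i1 = sorted(order[:2])
    d = pts[i0] - pts[i1]
    n = np.linalg.norm(d)
    if n < 1e-9:
        raise InputError(
            f"catheter {cath.id}: nearest control points to dwell "
            f"{dwell.index} coincide")
    return RigidTransform(_rotation_from_z_to(d / n),
                          np.asarray(dwell.center, dtype=float))


@dataclass
class SamplingTable:
    """Per-dwell replay probabilities p_i = t_i / sum(t)."""

    probabilities: np.ndarray
    cumulative: np.ndarray = field(init=False)

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValidationError(f"probabilities sum to {p.sum()!r}, not 1")
        if (p < 0).any():
            raise ValidationError("negative probability")
        self.probabilities = p
        self.cumulative = np.cumsum(p)


def sampling_table(dwells) -> SamplingTable:
    """Dwell-selection distribution: each dwell's fraction of total time."""
    t = np.array([d.time for d in dwells], dtype=float)
    total = t.sum()
    if total <= 0:
        raise InputError("all dwell times are zero")
    p = t / total
    # remove float residue so the table invariant holds exactly
    p[np.argmax(p)] += 1.0 - p.sum()
    return SamplingTable(p)


def sample_dwells(table: SamplingTable, n: int, rng) -> np.ndarray:
    """Draw n dwell indices from the replay distribution."""
    return np.searchsorted(table.cumulative, rng.random(n), side="right")


@dataclass
class PhaseSpace:
    """Photon records in the source-local frame.

    ``n_emitted`` is the number of photons initially emitted when the file
    was scored; ``records`` holds the survivors as rows
    (E MeV, x, y, z mm, u, v, w).
    """

    source_id: str
    n_emitted: int
    records: np.ndarray   # (N, 7) float32

    def __post_init__(self):
        self.records = np.asarray(self.records, dtype=np.float32)
        if self.records.ndim != 2 or self.records.shape[1] != 7:
            raise InputError("records must be (N, 7)")
        if len(self.records) > self.n_emitted:
            raise InputError("more records than initially emitted photons")
        E = self.records[:, 0]
        if len(E) and (E <= 0).any() or (E > E_MAX_MEV).any():
            raise InputError(f"photon energies outside (0, {E_MAX_MEV}] MeV")
        norms = np.linalg.norm(self.records[:, 4:7], axis=1)
        if len(norms) and np.abs(norms - 1.0).max() > 1e-6:
            raise InputError("directions not unit vectors")

    @property
    def n_records(self) -> int:
        return len(self.records)


_MAGIC = "PHSP1"


def write_phase_space(ps: PhaseSpace, path) -> str:
    """One text header line, then little-endian float32 x 7 per record."""
    with open(path, "wb") as f:
        f.write(f"{_MAGIC} {ps.source_id} {ps.n_records} "
                f"{ps.n_emitted}\n".encode("ascii"))
        f.write(np.ascontiguousarray(
            ps.records, dtype="<f4").tobytes())
    return str(path)


def read_phase_space(path) -> PhaseSpace:
    with open(path, "rb") as f:
        header = f.readline().decode("ascii").split()
        if len(header) != 4 or header[0] != _MAGIC:
            raise InputError(f"{path}: not a {_MAGIC} phase-space file")
        source_id, n_records, n_emitted = header[1], int(header[2]), int(header[3])
        payload = f.read()
    expected = n_records * 7 * 4
    if len(payload) != expected:
        found = len(payload) // (7 * 4)
        raise InputError(
            f"{path}: truncated phase space: header promises {n_records} "
            f"records, found {found}")
    rec = np.frombuffer(payload, dtype="<f4").reshape(n_records, 7)
    return PhaseSpace(source_id, n_emitted, rec.copy())


def ir192_spectrum(path=None):
    """(energies MeV, normalized intensities) of the Ir-192 gamma lines."""
    if path is None:
        path = os.path.join(os.path.dirname(__file__), "data",
                            "ir192_spectrum.csv")
    arr = np.genfromtxt(path, delimiter=",", skip_header=1)
    e, w = arr[:, 0], arr[:, 1]
    return e, w / w.sum()


def toy_phase_space(source_id: str, n_emitted: int, seed: int,
                    diameter_mm: float = 0.9, length_mm: float = 3.6,
                    spectrum=None) -> PhaseSpace:
    """Simplified surface-emission phase space for testing the pipeline.

    Photons start uniformly on the lateral surface of the active-core
    cylinder (default 0.9 mm diameter x 3.6 mm length), fly isotropically,
    and carry energies drawn from the Ir-192 line spectrum.  No capsule
    attenuation is modeled, so every emitted photon is recorded.
    """
    rng = np.random.default_rng(seed)
    if spectrum is None:
        spectrum = ir192_spectrum()
    energies_tab, probs = spectrum
    E = rng.choice(energies_tab, size=n_emitted, p=probs)
    phi = rng.uniform(0, 2 * np.pi, n_emitted)
    rad = diameter_mm / 2.0
    pos = np.column_stack([rad * np.cos(phi), rad * np.sin(phi),
                           rng.uniform(-length_mm / 2, length_mm / 2,
                                       n_emitted)])
    # isotropic directions
    w = rng.uniform(-1.0, 1.0, n_emitted)
    psi = rng.uniform(0, 2 * np.pi, n_emitted)
    s = np.sqrt(1.0 - w * w)
    dirs = np.column_stack([s * np.cos(psi), s * np.sin(psi), w])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    records = np.column_stack([E, pos, dirs]).astype(np.float32)
    # float32 direction rows renormalized to keep |d| = 1 within 1e-6
    d32 = records[:, 4:7].astype(np.float64)
    records[:, 4:7] = (d32 / np.linalg.norm(d32, axis=1, keepdims=True)
                       ).astype(np.float32)
    return PhaseSpace(source_id, n_emitted, records)


def transform_record(rec, T: RigidTransform):
    """Map one or more (E, x, y, z, u, v, w) records into the patient frame."""
    rec = np.atleast_2d(np.asarray(rec, dtype=float))
    out = rec.copy()
    out[:, 1:4] = rec[:, 1:4] @ T.rotation.T + T.translation
    out[:, 4:7] = rec[:, 4:7] @ T.rotation.T
    return out[0] if out.shape[0] == 1 else out
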
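"""Treatment-plan and structure-set domain objects."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .sources import Catheter, DwellPosition

__all__ = ["PlanModel", "Structure", "StructureSet"]


@dataclass
class PlanModel:
    """An HDR brachytherapy plan: catheters, dwell positions and times.

    The afterloader steps the source through each catheter, pausing at the
    planned dwell positions; per-dwell times (seconds) carry the plan's
    optimization result.  ``total_time`` is always the sum of dwell times.
    """

    source_id: str
    catheters: list          # of Catheter
    dwells: list             # of DwellPosition
    prescription_dose: float | None = None   # Gy

    def __post_init__(self):
        ids = {c.id for c in self.catheters}
        for d in self.dwells:
            if d.catheter_id not in ids:
                raise InputError(
                    f"dwell {d.index} references unknown catheter "
                    f"{d.catheter_id!r}")

    @property
    def total_time(self) -> float:
        """Total irradiation time in seconds."""
        return float(sum(d.time for d in self.dwells))

    def catheter(self, cid) -> Catheter:
        for c in self.catheters:
            if c.id == cid:
                return c
        raise KeyError(cid)

    def dwell_coordinates(self) -> np.ndarray:
        return np.array([d.center for d in self.dwells], dtype=float)


@dataclass
class Structure:
    """One contoured structure: closed planar polygons, vertices in mm."""

    name: str
    contours: list = field(default_factory=list)   # of (N, 3) float arrays
    color: tuple = (255, 0, 0)

    def __post_init__(self):
        clean = []
        for c in self.contours:
            c = np.asarray(c, dtype=float)
            if c.ndim != 2 or c.shape[1] != 3 or c.shape[0] < 3:
                raise InputError(
                    f"contour of {self.name!r} must be (N>=3, 3), "
                    f"got {c.shape}")
            if np.ptp(c[:, 2]) > 0.1:
                raise InputError(
                    f"contour of {self.name!r} not coplanar with its slice "
                    f"(z spread {np.ptp(c[:, 2]):.3f} mm)")
            clean.append(c)
        self.contours = clean


@dataclass
class StructureSet:
    structures: list = field(default_factory=list)

    def __getitem__(self, name: str) -> Structure:
        for s in self.structures:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self):
        return [s.name for s in self.structures]
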
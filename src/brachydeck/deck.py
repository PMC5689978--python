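"""MCNP-style input-deck generation and validation.

The voxel model is encoded as a rectangular lattice (LAT=1) whose element
size equals the CT voxel size and whose outer dimensions coincide with the
CT volume, so the lattice has exactly one element per CT voxel.  Each
distinct (tissue, density) pair present in the material model becomes one
filling universe; densities ride on the universe cells (negative = g/cm3)
while material cards carry only mass fractions (negative-signed, MCNP
convention).

Two tallies are emitted: a photon-heating F6 tally over the full lattice
(collisional kerma to medium in medium) and a mesh tally of photon energy
fluence restricted to the extent of the RT Dose grid, weighted by the mass
energy-absorption coefficients of water to yield water kerma in medium.
No variance-reduction cards are written.

The phase-space source cannot be inlined (millions of records), so the
deck points at a ``.phsp`` sidecar plus a CSV table of per-dwell rigid
transforms and replay probabilities; the companion-file convention is
documented in the deck's comment block.
"""
from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, ValidationError
from .grids import DoseGrid
from .materials import ELEMENT_Z, MaterialModel
from .plan import PlanModel

__all__ = ["MCDeck", "MuEnTable", "build_materials", "write_deck",
           "validate_deck", "write_transform_csv"]

_DATA = os.path.join(os.path.dirname(__file__), "data")

MAX_COLUMNS = 80
CONTINUATION = "     "   # 5-space continuation per the deck dialect


@dataclass
class MuEnTable:
    """Mass energy-absorption coefficients of water, cm2/g vs MeV."""

    energies: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if (np.diff(self.energies) <= 0).any():
            raise InputError("mu_en energies must strictly increase")
        if (self.values <= 0).any():
            raise InputError("mu_en values must be positive")

    @classmethod
    def default(cls) -> "MuEnTable":
        arr = np.genfromtxt(os.path.join(_DATA, "muen_water.csv"),
                            delimiter=",", skip_header=1)
        return cls(arr[:, 0], arr[:, 1])


@dataclass
class Manifest:
    n_lattice_elements: int
    fill_dims: tuple
    n_materials: int
    n_universes: int
    tally_ids: tuple
    nps: int


@dataclass
class MCDeck:
    title: str
    cell_block: str
    surface_block: str
    data_block: str
    manifest: Manifest = None

    @property
    def text(self) -> str:
        return "\n\n".join([self.title + "\n" + self.cell_block,
                            self.surface_block, self.data_block]) + "\n"


def _wrap(card: str) -> str:
    """Wrap a card at 80 columns using 5-space continuation lines."""
    words = card.split()
    lines, cur = [], words[0]
    for w in words[1:]:
        if len(cur) + 1 + len(w) <= MAX_COLUMNS:
            cur += " " + w
        else:
            lines.append(cur)
            cur = CONTINUATION + w
    lines.append(cur)
    return "\n".join(lines)


def _fmt_density(d: float) -> str:
    return f"{d:.6g}"


def build_materials(model: MaterialModel):
    """One material card per distinct tissue row present in the model.

    Mass fractions are negative-signed; the printed fractions are
    adjusted on the largest element so each card sums to exactly -1 at
    the printed precision.
    """
    present = np.unique(model.material_index)
    cards = {}
    for m in present:
        fr = model.table.fractions[int(m)]
        nz_el = np.flatnonzero(fr > 0)
        printed = np.round(fr[nz_el], 8)
        printed[np.argmax(printed)] += 1.0 - printed.sum()
        entries = " ".join(
            f"{ELEMENT_Z[model.table.elements[e]]}000 -{v:.8f}"
            for e, v in zip(nz_el, printed))
        cards[int(m)] = _wrap(
            f"m{int(m) + 1} {entries} $ {model.table.names[int(m)]}")
    return cards


def _rle(flat: np.ndarray):
    """(values, run_lengths) of a flat array."""
    change = np.flatnonzero(flat[1:] != flat[:-1])
    starts = np.concatenate([[0], change + 1])
    lengths = np.diff(np.concatenate([starts, [len(flat)]]))
    return flat[starts], lengths


def _fill_tokens(universe_map: np.ndarray):
    """MCNP repeat-syntax FILL entries, x fastest, then y, then z."""
    vals, lengths = _rle(universe_map.ravel())   # C order: x fastest
    toks = []
    for v, n in zip(vals, lengths):
        toks.append(f"{v}" if n == 1 else f"{v} {n - 1}r")
    return toks


def write_transform_csv(transforms, table, path) -> str:
    """Per-dwell rotation (row-major), translation and replay probability."""
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["dwell_index"]
                   + [f"r{i}{j}" for i in range(3) for j in range(3)]
                   + ["tx_mm", "ty_mm", "tz_mm", "probability"])
        for i, (T, p) in enumerate(zip(transforms, table.probabilities)):
            w.writerow([i] + [f"{v:.9f}" for v in T.rotation.ravel()]
                       + [f"{v:.6f}" for v in T.translation]
                       + [f"{p:.12f}"])
    return str(path)


def write_deck(model: MaterialModel, plan: PlanModel, transforms,
               sampling, dose_grid: DoseGrid | None = None,
               nps: int = 10 ** 6, phsp_name: str = "source.phsp",
               muen: MuEnTable | None = None,
               title: str = "brachydeck voxel model") -> MCDeck:
    """Assemble the full deck from model, plan and source placement."""
    if len(transforms) != len(plan.dwells):
        raise InputError(f"{len(transforms)} transforms for "
                         f"{len(plan.dwells)} dwells")
    muen = muen or MuEnTable.default()
    nz, ny, nx = model.shape
    dx, dy, dz = model.spacing / 10.0   # cm
    ox, oy, oz = model.origin / 10.0    # cm, first voxel center

    # universes: one per distinct (material, density) pair
    ud, dens_inv = np.unique(model.density, return_inverse=True)
    code = (model.material_index.ravel().astype(np.int64) * len(ud)
            + dens_inv.ravel())
    ucodes, umap = np.unique(code, return_inverse=True)
    umap = (umap + 2).reshape(model.shape)   # universes 2..; 1 = lattice
    u_mat = (ucodes // len(ud)).astype(int)
    u_dens = ud[ucodes % len(ud)]

    cells = ["c cell block"]
    cells.append("1 0 -10 fill=1 imp:p=1 $ container = CT volume extent")
    fill = (f"2 0 -11 lat=1 u=1 imp:p=1 fill=0:{nx - 1} 0:{ny - 1} "
            f"0:{nz - 1}")
    cells.append(_wrap(" ".join([fill] + _fill_tokens(umap))))
    cells.append("c fill order: x fastest, then y, then z "
                 "(one entry per CT voxel)")
    for u, (m, d) in enumerate(zip(u_mat, u_dens), start=2):
        cells.append(f"{u + 100} {m + 1} -{_fmt_density(d)} -99 u={u} "
                     f"imp:p=1")
    cells.append("999 0 10 imp:p=0 $ outside world")
    cell_block = "\n".join(cells)

    # surfaces: box faces at voxel boundaries (centers -+ half spacing)
    x0, x1 = ox - dx / 2, ox + (nx - 0.5) * dx
    y0, y1 = oy - dy / 2, oy + (ny - 0.5) * dy
    z0, z1 = oz - dz / 2, oz + (nz - 0.5) * dz
    surfaces = [
        "c surface block",
        f"10 rpp {x0:.6f} {x1:.6f} {y0:.6f} {y1:.6f} {z0:.6f} {z1:.6f}",
        _wrap(f"11 rpp {-dx / 2:.6f} {dx / 2:.6f} {-dy / 2:.6f} "
              f"{dy / 2:.6f} {-dz / 2:.6f} {dz / 2:.6f} "
              "$ one lattice element = one CT voxel"),
        "99 so 1.0e4",
    ]
    surface_block = "\n".join(surfaces)

    data = ["c data block", "mode p"]
    data.extend(card for _, card in sorted(build_materials(model).items()))
    data.append("c source: replay phase-space sidecar; per-photon dwell")
    data.append(f"c   phsp file: {phsp_name}")
    data.append(f"c   transform table: {os.path.splitext(phsp_name)[0]}"
                "_transforms.csv")
    data.append("c   (per-dwell rotation, translation and probability)")
    data.append(f"c   dwells: {len(plan.dwells)}, total time "
                f"{plan.total_time:.3f} s")
    data.append("f6:p 1 $ collisional kerma to medium in medium")
    tally_ids = [6, 14]
    if dose_grid is not None:
        gx, gy, gz = dose_grid.axes()
        gsp = dose_grid.spacing / 10.0
        fmesh = (f"*fmesh14:p geom=xyz origin="
                 f"{(gx[0] - dose_grid.spacing[0] / 2) / 10:.4f} "
                 f"{(gy[0] - dose_grid.spacing[1] / 2) / 10:.4f} "
                 f"{(gz[0] - dose_grid.spacing[2] / 2) / 10:.4f} "
                 f"imesh={(gx[-1] + dose_grid.spacing[0] / 2) / 10:.4f} "
                 f"iints={len(gx)} "
                 f"jmesh={(gy[-1] + dose_grid.spacing[1] / 2) / 10:.4f} "
                 f"jints={len(gy)} "
                 f"kmesh={(gz[-1] + dose_grid.spacing[2] / 2) / 10:.4f} "
                 f"kints={len(gz)}")
        data.append(_wrap(fmesh))
        data.append("c energy fluence within the RT dose grid extent,")
        data.append("c weighted to water kerma via mu_en/rho of water")
        data.append(_wrap("de14 " + " ".join(f"{e:.3f}"
                                             for e in muen.energies)))
        data.append(_wrap("df14 " + " ".join(f"{v:.5g}"
                                             for v in muen.values)))
    else:
        tally_ids = [6]
    data.append(f"nps {int(nps)}")
    data_block = "\n".join(data)

    manifest = Manifest(
        n_lattice_elements=nx * ny * nz, fill_dims=(nx, ny, nz),
        n_materials=len(np.unique(model.material_index)),
        n_universes=len(ucodes), tally_ids=tuple(tally_ids), nps=int(nps))
    return MCDeck(title, cell_block, surface_block, data_block, manifest)


def _unwrap(block: str):
    """Rejoin continuation lines; yields full logical cards."""
    cards = []
    for line in block.splitlines():
        if line.startswith(CONTINUATION) and cards:
            cards[-1] += " " + line.strip()
        else:
            cards.append(line.rstrip())
    return cards


def validate_deck(text: str) -> Manifest:
    """Re-parse a deck and verify its structural invariants.

    Checks the three-block layout, expands FILL repeat syntax and
    verifies the entry count against the declared lattice dimensions,
    confirms every filling universe has a cell and every referenced
    material a card with mass fractions summing to -1 within 1e-6.
    """
    parts = [p for p in text.split("\n\n")]
    if len(parts) != 3:
        raise ValidationError(
            f"deck must have 3 blank-line-separated blocks, found "
            f"{len(parts)}")
    cell_part, surface_part, data_part = parts
    if not data_part.strip():
        raise ValidationError("empty data block")
    if not surface_part.strip():
        raise ValidationError("empty surface block")

    fill_dims = None
    fill_count = 0
    fill_universes = set()
    universe_cells = set()
    cell_materials = set()
    for card in _unwrap(cell_part):
        tok = card.split("$")[0].split()
        if not tok or tok[0].lower() == "c" or not tok[0].isdigit():
            continue
        low = [t.lower() for t in tok]
        if any(t.startswith("fill=0:") for t in low) and "lat=1" in low:
            i = next(i for i, t in enumerate(low) if t.startswith("fill=0:"))
            dims = []
            for spec in (low[i][5:], low[i + 1], low[i + 2]):
                a, b = spec.split(":")
                dims.append(int(b) - int(a) + 1)
            fill_dims = tuple(dims)
            for t in tok[i + 3:]:
                if t.lower().endswith("r"):
                    fill_count += int(t[:-1])
                else:
                    fill_count += 1
                    fill_universes.add(int(t))
        else:
            for t in low:
                if t.startswith("u="):
                    universe_cells.add(int(t[2:]))
                    if int(tok[1]) > 0:
                        cell_materials.add(int(tok[1]))

    if fill_dims is None:
        raise ValidationError("no lattice FILL card found")
    expected = int(np.prod(fill_dims))
    if fill_count != expected:
        raise ValidationError(
            f"FILL entry count {fill_count} != lattice size {expected} "
            f"(dims {fill_dims})")
    missing = fill_universes - universe_cells - {1}
    if missing:
        raise ValidationError(f"FILL references undefined universes "
                              f"{sorted(missing)}")

    materials = {}
    tally_ids = []
    nps = None
    for card in _unwrap(data_part):
        tok = card.split("$")[0].split()
        if not tok:
            continue
        key = tok[0].lower()
        if key.startswith("m") and key[1:].isdigit():
            fr = [float(v) for v in tok[2::2]]
            materials[int(key[1:])] = sum(fr)
        elif ":" in key:
            k = key.lstrip("*")
            num = None
            if k.startswith("fmesh"):
                num = k[5:].split(":")[0]
            elif k.startswith("f"):
                num = k[1:].split(":")[0]
            if num and num.isdigit():
                tally_ids.append(int(num))
        elif key == "nps":
            nps = int(tok[1])
    for m, s in materials.items():
        if abs(s + 1.0) > 1e-6:
            raise ValidationError(
                f"material m{m} mass fractions sum to {s:.8f}, not -1")
    referenced = cell_materials - set(materials)
    if referenced:
        raise ValidationError(f"cells reference undefined materials "
                              f"{sorted(referenced)}")
    if nps is None:
        raise ValidationError("no NPS card")
    return Manifest(n_lattice_elements=expected, fill_dims=fill_dims,
                    n_materials=len(materials),
                    n_universes=len(universe_cells - {1}),
                    tally_ids=tuple(sorted(tally_ids)), nps=nps)
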
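"""Regenerate the CSV data files bundled with brachydeck."""
import numpy as np

import os
OUT = os.path.join(os.path.dirname(__file__), "..", "src", "brachydeck", "data")


def sig2_floor(x):
    """Largest value on the 2-significant-digit grid <= x."""
    e = int(np.floor(np.log10(x) + 1e-12))
    scale = 10.0 ** (e - 1)
    return np.floor(x / scale + 1e-6) * scale


def sig2_ceil_grid(low):
    """Smallest 2-significant-digit value >= low."""
    e = int(np.floor(np.log10(low) + 1e-12))
    g = 10.0 ** (e - 1)
    v = np.ceil(low / g - 1e-9) * g
    return v


# ---- 54-bin density scheme -------------------------------------------------
edges = [0.0012]
edges += list(np.round(np.linspace(0.05, 0.85, 26), 6))          # 25 bins
edges += list(np.round(np.arange(0.87, 1.0101, 0.02), 6))        # 8 bins -> 1.01
edges += list(np.round(1.01 + 0.1 * np.arange(1, 20), 6))        # 19 bins -> 2.91
edges += [3.0]                                                   # 1 bin
edges = np.array(edges)
nbins = len(edges) - 1
assert nbins == 54, nbins

reps = []
for lo, hi in zip(edges[:-1], edges[1:]):
    if lo <= 1.0 < hi:
        r = 1.0          # water bin representative is exactly 1.00
    else:
        r = sig2_ceil_grid(lo)
    assert lo <= r < hi or (hi == edges[-1] and lo <= r <= hi), (lo, r, hi)
    reps.append(r)
reps = np.round(np.array(reps), 6)
assert len(np.unique(reps)) == 54
# representative must be a truncation fixed point
for r in reps:
    assert abs(sig2_floor(r) - r) < 1e-9, r
# bin containing a representative is its own bin (idempotence)
idx = np.clip(np.searchsorted(edges[1:-1], reps, side="right"), 0, 53)
assert (idx == np.arange(54)).all()

with open(f"{OUT}/density_bins_54.csv", "w") as f:
    f.write("low,high,representative\n")
    for lo, hi, r in zip(edges[:-1], edges[1:], reps):
        f.write(f"{lo:.6g},{hi:.6g},{r:.6g}\n")

# ---- 23-row tissue table ---------------------------------------------------
ELEMENTS = ["H", "C", "N", "O", "Na", "Mg", "P", "S", "Cl", "Ar", "K", "Ca"]

def comp(**kw):
    v = np.array([kw.get(e, 0.0) for e in ELEMENTS])
    return v / v.sum()

air = comp(C=0.000124, N=0.755268, O=0.231781, Ar=0.012827)
lung = comp(H=0.103, C=0.105, N=0.031, O=0.749, Na=0.002, P=0.002, S=0.003,
            Cl=0.003, K=0.002)
adipose = comp(H=0.114, C=0.598, N=0.007, O=0.278, Na=0.001, S=0.001, Cl=0.001)
breast = comp(H=0.109, C=0.506, N=0.023, O=0.358, Na=0.001, P=0.001, S=0.001,
              Cl=0.001)
soft = comp(H=0.112, O=0.888)                      # water-equivalent soft tissue
muscle = comp(H=0.102, C=0.143, N=0.034, O=0.710, Na=0.001, P=0.002, S=0.003,
              Cl=0.001, K=0.004)
liver = comp(H=0.102, C=0.139, N=0.030, O=0.716, Na=0.002, P=0.003, S=0.003,
             Cl=0.002, K=0.003)
cartilage = comp(H=0.096, C=0.099, N=0.022, O=0.744, Na=0.005, P=0.022,
                 S=0.009, Cl=0.003)
marrow_bone = comp(H=0.085, C=0.404, N=0.058, O=0.367, Na=0.001, Mg=0.001,
                   P=0.034, S=0.002, Cl=0.002, K=0.001, Ca=0.045)
cortical = comp(H=0.034, C=0.155, N=0.042, O=0.435, Na=0.001, Mg=0.002,
                P=0.103, S=0.003, Ca=0.225)

rows = [
    ("air", 0.0, 0.05, air),
    ("lung", 0.05, 0.60, lung),
    ("adipose", 0.60, 0.93, adipose),
    ("breast", 0.93, 0.97, breast),
    ("soft_tissue", 0.97, 1.01, soft),
    ("muscle", 1.01, 1.04, muscle),
    ("liver", 1.04, 1.06, liver),
    ("cartilage", 1.06, 1.10, cartilage),
]
# 13 graded skeletal rows 1.10 -> 1.75, then dense bone rows
bone_edges = list(np.round(np.arange(1.10, 1.7501, 0.05), 6))
for lo, hi in zip(bone_edges[:-1], bone_edges[1:]):
    d = 0.5 * (lo + hi)
    t = np.clip((d - 1.10) / (1.92 - 1.10), 0.0, 1.0)
    c = (1 - t) * marrow_bone + t * cortical
    rows.append((f"skeletal_d{d:.3f}", lo, hi, c / c.sum()))
rows.append(("dense_bone", 1.75, 2.00, (0.25 * marrow_bone + 0.75 * cortical)))
rows.append(("cortical_bone", 2.00, 3.00, cortical))
assert len(rows) == 23, len(rows)

with open(f"{OUT}/tissues_23.csv", "w") as f:
    f.write("name,low,high," + ",".join(ELEMENTS) + "\n")
    for name, lo, hi, c in rows:
        c = np.round(c / c.sum(), 6)
        c[np.argmax(c)] += np.round(1.0 - c.sum(), 6)
        assert abs(c.sum() - 1.0) < 1e-9
        f.write(f"{name},{lo:.6g},{hi:.6g}," +
                ",".join(f"{x:.6f}" for x in c) + "\n")

# ---- default HU-density calibration ---------------------------------------
with open(f"{OUT}/hu_density_default.csv", "w") as f:
    f.write("hu,density\n")
    for hu, d in [(-1000, 0.0012), (-700, 0.30), (0, 1.00), (300, 1.20),
                  (1200, 1.85), (3000, 2.70)]:
        f.write(f"{hu},{d}\n")

# ---- Ir-192 gamma line spectrum (principal lines, rel. intensity) ----------
spectrum = [
    (0.136343, 0.00199), (0.201311, 0.00473), (0.205794, 0.0334),
    (0.283267, 0.00266), (0.295957, 0.2871), (0.308455, 0.2970),
    (0.316506, 0.8286), (0.374485, 0.00726), (0.416469, 0.00670),
    (0.468069, 0.4781), (0.484575, 0.03189), (0.489060, 0.00438),
    (0.588581, 0.04517), (0.604411, 0.0820), (0.612462, 0.05340),
    (0.884537, 0.00292), (1.061480, 0.000530),
]
with open(f"{OUT}/ir192_spectrum.csv", "w") as f:
    f.write("energy_mev,intensity\n")
    for e, i in spectrum:
        f.write(f"{e:.6f},{i:.6g}\n")

# ---- mass energy-absorption coefficients of water (NIST) -------------------
muen = [
    (0.010, 4.944), (0.015, 1.374), (0.020, 0.5503), (0.030, 0.1557),
    (0.040, 0.06947), (0.050, 0.04223), (0.060, 0.03190), (0.080, 0.02597),
    (0.100, 0.02546), (0.150, 0.02764), (0.200, 0.02967), (0.300, 0.03192),
    (0.400, 0.03279), (0.500, 0.03299), (0.600, 0.03284), (0.800, 0.03206),
    (1.000, 0.03103), (1.250, 0.02965), (1.500, 0.02833),
]
with open(f"{OUT}/muen_water.csv", "w") as f:
    f.write("energy_mev,muen_over_rho\n")
    for e, v in muen:
        f.write(f"{e:.3f},{v:.6g}\n")

# ---- synthetic smooth TG43 test tables -------------------------------------
r_nodes = np.array([0.1, 0.15, 0.2, 0.25, 0.3, 0.4, 0.5, 0.6, 0.8, 1.0, 1.25,
                    1.5, 1.75, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 6.0, 7.0,
                    8.0, 10.0, 12.0, 15.0, 18.0])
g = 1.0 + 0.009 * (r_nodes - 1.0) - 0.0035 * (r_nodes - 1.0) ** 2
assert (g > 0).all()
with open(f"{OUT}/tg43_g_synthetic.csv", "w") as f:
    f.write("r_cm,g\n")
    for r, gv in zip(r_nodes, g):
        f.write(f"{r:.4g},{gv:.6f}\n")

rF = np.array([0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 7.0, 10.0, 15.0, 18.0])
th = np.arange(0.0, 180.1, 5.0)
c = 0.15 + 0.02 * np.log(rF)
F = 1.0 - np.outer(c, np.abs(np.cos(np.deg2rad(th))) ** 2.5)
F[:, th == 90.0] = 1.0
assert (F > 0).all()
with open(f"{OUT}/tg43_F_synthetic.csv", "w") as f:
    f.write("r_cm\\theta_deg," + ",".join(f"{t:g}" for t in th) + "\n")
    for r, row in zip(rF, F):
        f.write(f"{r:g}," + ",".join(f"{v:.6f}" for v in row) + "\n")

print("wrote all data files")
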
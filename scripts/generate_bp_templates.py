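"""One-time generation of the idealized base-pair template geometry.

Base heavy atoms use the standard base-pair reference frame convention
(idealized planar bases, helix axis = +z, pair pseudo-dyad = x, strand-I
C1' side = +y).  The generic sugar-phosphate backbone for strand I is
solved by least squares over standard nucleic-acid bond lengths, bond
angles and B-form torsion priors, under the helix symmetry
x -> Rz(2*pi/10.4) x + 3.4 z so that O3'(i)-P(i+1) is a proper bond.
Strand II is the dyad image (x, -y, -z).

Writes src/dnaxis/_bp_geometry.py with frozen literal coordinates and
prints a geometry report (bonds, angles, torsions, continuity, clashes).
"""

import numpy as np
from scipy.optimize import least_squares

RISE = 3.4
OMEGA = 2 * np.pi / 10.4

# standard-reference-frame base heavy atoms (x, y, z in Angstrom)
BASES = {
    "A": [
        ("N9", -1.291, 4.498, 0.000), ("C8", 0.024, 4.897, 0.000),
        ("N7", 0.877, 3.902, 0.000), ("C5", 0.071, 2.771, 0.000),
        ("C6", 0.369, 1.398, 0.000), ("N6", 1.611, 0.909, 0.000),
        ("N1", -0.668, 0.532, 0.000), ("C2", -1.912, 1.023, 0.000),
        ("N3", -2.320, 2.290, 0.000), ("C4", -1.267, 3.124, 0.000),
    ],
    "G": [
        ("N9", -1.289, 4.551, 0.000), ("C8", 0.023, 4.962, 0.000),
        ("N7", 0.870, 3.969, 0.000), ("C5", 0.071, 2.833, 0.000),
        ("C6", 0.424, 1.460, 0.000), ("O6", 1.554, 0.955, 0.000),
        ("N1", -0.700, 0.641, 0.000), ("C2", -1.999, 1.087, 0.000),
        ("N2", -2.949, 0.139, -0.001), ("N3", -2.342, 2.364, 0.001),
        ("C4", -1.265, 3.177, 0.000),
    ],
    "C": [
        ("N1", -1.285, 4.542, 0.000), ("C2", -1.472, 3.158, 0.000),
        ("O2", -2.628, 2.709, 0.001), ("N3", -0.391, 2.344, 0.000),
        ("C4", 0.837, 2.868, 0.000), ("N4", 1.875, 2.027, 0.001),
        ("C5", 1.056, 4.275, 0.000), ("C6", -0.023, 5.068, 0.000),
    ],
    "T": [
        ("N1", -1.284, 4.500, 0.000), ("C2", -1.462, 3.135, 0.000),
        ("O2", -2.562, 2.608, 0.000), ("N3", -0.298, 2.407, 0.000),
        ("C4", 0.994, 2.897, 0.000), ("O4", 1.944, 2.119, 0.000),
        ("C5", 1.106, 4.338, 0.000), ("C7", 2.466, 4.961, 0.001),
        ("C6", -0.024, 5.057, 0.000),
    ],
}

# fixed anchors (generic over the four bases)
C1P = np.array([-2.480, 5.346, 0.0])
NGLY = np.array([-1.288, 4.521, 0.0])   # N9 (purine) / N1 (pyrimidine)
CBASE = np.array([-1.370, 3.140, 0.0])  # C4 (purine) / C2 (pyrimidine), for chi

ATOMS = ["P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'"]
IDX = {a: i for i, a in enumerate(ATOMS)}

BONDS = [
    ("P", "OP1", 1.485), ("P", "OP2", 1.485), ("P", "O5'", 1.593),
    ("O5'", "C5'", 1.440), ("C5'", "C4'", 1.510), ("C4'", "C3'", 1.528),
    ("C4'", "O4'", 1.453), ("C3'", "C2'", 1.525), ("C3'", "O3'", 1.423),
]
FIXED_BONDS = [("O4'", C1P, 1.414), ("C2'", C1P, 1.521)]

ANGLES = [  # (a, b, c, degrees) angle at b
    ("OP1", "P", "OP2", 119.6), ("OP1", "P", "O5'", 108.1),
    ("OP2", "P", "O5'", 108.3), ("P", "O5'", "C5'", 120.9),
    ("O5'", "C5'", "C4'", 110.2), ("C5'", "C4'", "C3'", 114.7),
    ("C5'", "C4'", "O4'", 109.4), ("C3'", "C4'", "O4'", 105.6),
    ("C4'", "C3'", "C2'", 102.7), ("C4'", "C3'", "O3'", 110.3),
    ("C2'", "C3'", "O3'", 110.6),
]


def rz(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def angle(a, b, c):
    v1, v2 = a - b, c - b
    cs = np.dot(v1, v2) / np.linalg.norm(v1) / np.linalg.norm(v2)
    return np.degrees(np.arccos(np.clip(cs, -1, 1)))


def torsion(p1, p2, p3, p4):
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return np.degrees(np.arctan2(np.dot(m, n2), np.dot(n1, n2)))


def wrap(d):
    return (d + 180.0) % 360.0 - 180.0


def residuals(x):
    pos = x.reshape(-1, 3)

    def g(name):
        return pos[IDX[name]]

    R = rz(OMEGA)
    p_next = R @ g("P") + np.array([0, 0, RISE])
    o5_next = R @ g("O5'") + np.array([0, 0, RISE])
    o3_prev = rz(-OMEGA) @ (g("O3'") - np.array([0, 0, RISE]))

    res = []
    for a, b, d in BONDS:
        res.append((np.linalg.norm(g(a) - g(b)) - d) * 5.0)
    for a, p, d in FIXED_BONDS:
        res.append((np.linalg.norm(g(a) - p) - d) * 5.0)
    # inter-residue O3'-P bond through the helix symmetry
    res.append((np.linalg.norm(p_next - g("O3'")) - 1.607) * 5.0)
    for a, b, c, deg in ANGLES:
        res.append(np.radians(angle(g(a), g(b), g(c)) - deg) * 2.0)
    # angles with fixed anchors
    res.append(np.radians(angle(g("C4'"), g("O4'"), C1P) - 109.7) * 2.0)
    res.append(np.radians(angle(g("O4'"), C1P, g("C2'")) - 106.1) * 2.0)
    res.append(np.radians(angle(C1P, g("C2'"), g("C3'")) - 102.5) * 2.0)
    res.append(np.radians(angle(g("O4'"), C1P, NGLY) - 108.2) * 2.0)
    res.append(np.radians(angle(g("C2'"), C1P, NGLY) - 113.7) * 2.0)
    res.append(np.radians(angle(o3_prev, g("P"), g("O5'")) - 104.0) * 2.0)
    res.append(np.radians(angle(g("C3'"), g("O3'"), p_next) - 119.7) * 2.0)
    # B-form torsion priors (weak: select the conformational basin)
    tors = [
        (torsion(o3_prev, g("P"), g("O5'"), g("C5'")), -41.0),   # alpha
        (torsion(g("P"), g("O5'"), g("C5'"), g("C4'")), 136.0),  # beta
        (torsion(g("O5'"), g("C5'"), g("C4'"), g("C3'")), 38.0), # gamma
        (torsion(g("C5'"), g("C4'"), g("C3'"), g("O3'")), 139.0),# delta
        (torsion(g("C4'"), g("C3'"), g("O3'"), p_next), -133.0), # epsilon
        (torsion(g("C3'"), g("O3'"), p_next, o5_next), -157.0),  # zeta
        (torsion(g("O4'"), C1P, NGLY, CBASE), -102.0),           # chi
    ]
    for val, tgt in tors:
        res.append(np.radians(wrap(val - tgt)) * 0.4)
    # weak placement priors: phosphate radius/height of fiber-like B-DNA
    res.append((np.linalg.norm(g("P")[:2]) - 8.9) * 0.1)
    res.append((g("P")[2] + 1.9) * 0.1)
    return np.array(res)


GUESS = {
    "P": (-4.0, 8.0, -2.1), "OP1": (-4.5, 9.3, -1.8), "OP2": (-2.6, 8.0, -2.5),
    "O5'": (-4.9, 7.0, -1.9), "C5'": (-5.0, 7.0, -0.5), "C4'": (-4.6, 6.1, 0.45),
    "O4'": (-3.38, 5.85, 1.0), "C3'": (-4.4, 6.0, -0.6), "O3'": (-4.6, 7.3, 0.7),
    "C2'": (-3.23, 5.95, -1.2),
}


def solve():
    x0 = np.array([GUESS[a] for a in ATOMS], dtype=float).ravel()
    best = None
    for seed in range(8):
        rng = np.random.default_rng(seed)
        start = x0 + (rng.standard_normal(x0.shape) * 0.15 if seed else 0.0)
        sol = least_squares(residuals, start, xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
    return best


def report(pos):
    def g(name):
        return pos[IDX[name]]

    R = rz(OMEGA)
    p_next = R @ g("P") + np.array([0, 0, RISE])
    o5_next = R @ g("O5'") + np.array([0, 0, RISE])
    o3_prev = rz(-OMEGA) @ (g("O3'") - np.array([0, 0, RISE]))
    print("== bonds ==")
    for a, b, d in BONDS:
        print(f"  {a:>4}-{b:<4} {np.linalg.norm(g(a)-g(b)):6.3f} (target {d})")
    for a, p, d in FIXED_BONDS:
        print(f"  {a:>4}-C1' {np.linalg.norm(g(a)-p):6.3f} (target {d})")
    d_o3p = np.linalg.norm(p_next - g("O3'"))
    print(f"  O3'-P(next) {d_o3p:6.3f} (target 1.607)")
    print("== angles ==")
    for a, b, c, deg in ANGLES:
        print(f"  {a:>4}-{b}-{c:<4} {angle(g(a), g(b), g(c)):7.2f} (target {deg})")
    print("== torsions ==")
    names = ["alpha", "beta", "gamma", "delta", "epsilon", "zeta", "chi"]
    vals = [
        torsion(o3_prev, g("P"), g("O5'"), g("C5'")),
        torsion(g("P"), g("O5'"), g("C5'"), g("C4'")),
        torsion(g("O5'"), g("C5'"), g("C4'"), g("C3'")),
        torsion(g("C5'"), g("C4'"), g("C3'"), g("O3'")),
        torsion(g("C4'"), g("C3'"), g("O3'"), p_next),
        torsion(g("C3'"), g("O3'"), p_next, o5_next),
        torsion(g("O4'"), C1P, NGLY, CBASE),
    ]
    for nm, v in zip(names, vals):
        print(f"  {nm:>8} {v:8.2f}")
    print("== radii / heights ==")
    for a in ATOMS:
        r = np.linalg.norm(g(a)[:2])
        print(f"  {a:>4} r={r:6.3f}  z={g(a)[2]:7.3f}")
    # clash checks: backbone vs its own base atoms and vs the helix neighbor
    bonded = {frozenset((a, b)) for a, b, _ in BONDS}
    bonded |= {frozenset(("O4'", "C1'")), frozenset(("C2'", "C1'"))}
    min_self = 9e9
    coords = {a: g(a) for a in ATOMS}
    coords["C1'"] = C1P
    keys = list(coords)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            if frozenset((keys[i], keys[j])) in bonded:
                continue
            d = np.linalg.norm(coords[keys[i]] - coords[keys[j]])
            min_self = min(min_self, d)
    print(f"min nonbonded backbone self-distance: {min_self:.3f}")
    # strand I backbone vs strand II backbone (dyad image)
    flip = np.diag([1.0, -1.0, -1.0])
    min_x = min(
        np.linalg.norm(coords[a] - flip @ coords[b])
        for a in keys for b in keys
    )
    print(f"min strand-I vs strand-II backbone distance: {min_x:.3f}")
    # backbone vs base atoms (all four bases), excluding the glycosidic bond
    min_base = 9e9
    for base, atoms in BASES.items():
        for nm, x, y, z in atoms:
            p = np.array([x, y, z])
            for a in ATOMS:
                d = np.linalg.norm(coords[a] - p)
                min_base = min(min_base, d)
    print(f"min backbone-to-base distance: {min_base:.3f}")


def emit(pos):
    lines = []
    lines.append('"""Frozen idealized base-pair template coordinates.')
    lines.append("")
    lines.append("Synthetic idealized geometry, generated once by")
    lines.append("``scripts/generate_bp_templates.py``: planar base heavy atoms in the")
    lines.append("standard base-pair reference frame (helix axis = +z, pseudo-dyad = x,")
    lines.append("strand-I backbone side = +y) plus a generic C2'-endo sugar-phosphate")
    lines.append("backbone solved by least squares over standard bond lengths, angles")
    lines.append("and B-form torsion priors under the 10.4 bp/turn, 3.4 A-rise helix")
    lines.append("symmetry.  Strand II is the dyad image (x, -y, -z).  Heavy atoms only.")
    lines.append('"""')
    lines.append("")
    lines.append("# fmt: off")
    lines.append("BASE_ATOMS = {")
    for base, atoms in BASES.items():
        lines.append(f"    {base!r}: [")
        for nm, x, y, z in atoms:
            lines.append(f"        ({nm!r}, {x: .4f}, {y: .4f}, {z: .4f}),")
        lines.append("    ],")
    lines.append("}")
    lines.append("")
    lines.append("# generic strand-I sugar-phosphate backbone (C1' anchors the base)")
    lines.append("BACKBONE_ATOMS = [")
    order = ["P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'"]
    for a in order:
        p = pos[IDX[a]]
        lines.append(f"    ({a!r}, {p[0]: .4f}, {p[1]: .4f}, {p[2]: .4f}),")
    lines.append(f"    (\"C1'\", {C1P[0]: .4f}, {C1P[1]: .4f}, {C1P[2]: .4f}),")
    lines.append("]")
    lines.append("# fmt: on")
    lines.append("")
    with open("src/dnaxis/_bp_geometry.py", "w") as fh:
        fh.write("\n".join(lines))
    print("wrote src/dnaxis/_bp_geometry.py")


if __name__ == "__main__":
    sol = solve()
    pos = sol.x.reshape(-1, 3)
    print(f"final cost: {sol.cost:.6e}")
    report(pos)
    emit(pos)
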
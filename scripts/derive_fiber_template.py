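"""Re-derive the fiber B-DNA backbone template frozen in helixread.synthetic.

The repeating sugar-phosphate unit is obtained in two stages:

1. an exact C2'-endo deoxyribose ring (standard bond lengths/angles,
   pseudorotation phase 162 deg, amplitude 35 deg) with substituent
   directions chirality-matched to the wwPDB chemical component
   dictionary entry for DA (via biotite's bundled CCD);
2. a four-parameter torsion-space fit (chi, gamma, beta and the helix
   axis offset) under the helical symmetry 36 deg twist / 3.38 Å rise,
   targeting B_I phosphodiester torsions (epsilon - zeta = -90 deg),
   canonical connectivity (O3'-P 1.607 Å) and the regular-B-DNA
   minor-groove calibration (cross-strand P-P of 11.75 Å at offsets
   -3/-4), with hinge penalties keeping all other cross-strand
   phosphate distances above 11 Å.

Run:  python scripts/derive_fiber_template.py
It prints the template dictionary and the implied constant slide; the
values in src/helixread/synthetic.py are this script's frozen output.
"""

import numpy as np
from scipy.optimize import least_squares

import biotite.structure.info as ccd
from helixread.bases import RING_ATOMS, STANDARD_BASES
from helixread.geom import dihedral, rotation_about_axis, superpose, wrap_angle

TWIST, RISE = 36.0, 3.38
RZ = rotation_about_axis([0, 0, 1], TWIST)
FLIP = np.diag([1.0, -1.0, -1.0])
C1P = np.array([-2.479, 5.350, 0.0])
NG = np.array([-1.287, 4.523, 0.0])     # glycosidic N (purine/pyrimidine mean)
CREF = np.array([-1.266, 3.150, 0.0])   # purine C4 (chi reference)

RING = ["O4'", "C1'", "C2'", "C3'", "C4'"]
RING_BONDS = {("O4'", "C1'"): 1.420, ("C1'", "C2'"): 1.519, ("C2'", "C3'"): 1.516,
              ("C3'", "C4'"): 1.529, ("C4'", "O4'"): 1.446}
RING_ANGLES = [("C4'", "O4'", "C1'", 109.7), ("O4'", "C1'", "C2'", 106.1),
               ("C1'", "C2'", "C3'", 102.5), ("C2'", "C3'", "C4'", 102.6),
               ("C3'", "C4'", "O4'", 105.7)]
PHASE, AMPLITUDE = 162.0, 35.0


def nu(j):
    return AMPLITUDE * np.cos(np.radians(PHASE + 144.0 * (j - 2)))


RING_TORSIONS = [(("C4'", "O4'", "C1'", "C2'"), nu(0)), (("O4'", "C1'", "C2'", "C3'"), nu(1)),
                 (("C1'", "C2'", "C3'", "C4'"), nu(2)), (("C2'", "C3'", "C4'", "O4'"), nu(3)),
                 (("C3'", "C4'", "O4'", "C1'"), nu(4))]


def solve_ring():
    res = ccd.residue("DA")
    cc = {n: c.astype(float) for n, c in zip(res.atom_name, res.coord)}
    x0 = np.concatenate([cc[n] for n in RING])

    def resid(x):
        a = {n: x[3 * i:3 * i + 3] for i, n in enumerate(RING)}
        rr = [30 * (np.linalg.norm(a[p] - a[q]) - t) for (p, q), t in RING_BONDS.items()]
        for p, q, s, t in RING_ANGLES:
            u, v = a[p] - a[q], a[s] - a[q]
            ang = np.degrees(np.arccos(np.clip(
                np.dot(u, v) / np.linalg.norm(u) / np.linalg.norm(v), -1, 1)))
            rr.append(10 * np.radians(ang - t))
        for quad, t in RING_TORSIONS:
            rr.append(10 * np.radians(wrap_angle(dihedral(*[a[q] for q in quad]) - t)))
        return np.array(rr)

    sol = least_squares(resid, x0, xtol=1e-15, ftol=1e-15, max_nfev=50000)
    return {n: sol.x[3 * i:3 * i + 3] for i, n in enumerate(RING)}, cc


def substituent(center, ref1, ref2, ang1, ang2, bond, sign):
    u1 = (ref1 - center) / np.linalg.norm(ref1 - center)
    u2 = (ref2 - center) / np.linalg.norm(ref2 - center)
    c1, c2 = np.cos(np.radians(ang1)), np.cos(np.radians(ang2))
    dot12 = np.dot(u1, u2)
    ab = np.linalg.solve(np.array([[1.0, dot12], [dot12, 1.0]]), [c1, c2])
    w = np.cross(u1, u2)
    rem = max(1.0 - (ab[0] ** 2 + ab[1] ** 2 + 2 * ab[0] * ab[1] * dot12), 0.0)
    d = ab[0] * u1 + ab[1] * u2 + sign * np.sqrt(rem / np.dot(w, w)) * w
    return center + bond * d / np.linalg.norm(d)


def chirality(cc, center, r1, r2, probe):
    u1, u2 = cc[r1] - cc[center], cc[r2] - cc[center]
    return np.sign(np.dot(np.cross(u1, u2), cc[probe] - cc[center]))


def build_unit():
    ring, cc = solve_ring()
    cc["N"] = cc["N9"]
    unit = dict(ring)
    unit["N"] = substituent(ring["C1'"], ring["O4'"], ring["C2'"], 108.2, 113.7, 1.470,
                            chirality(cc, "C1'", "O4'", "C2'", "N9"))
    unit["C5'"] = substituent(ring["C4'"], ring["C3'"], ring["O4'"], 115.2, 109.2, 1.510,
                              chirality(cc, "C4'", "C3'", "O4'", "C5'"))
    unit["O3'"] = substituent(ring["C3'"], ring["C4'"], ring["C2'"], 110.3, 109.5, 1.423,
                              chirality(cc, "C3'", "C4'", "C2'", "O3'"))
    return unit


UNIT = build_unit()


def nerf(p1, p2, p3, bond, theta, phi):
    theta, phi = np.radians(theta), np.radians(phi)
    bc = p3 - p2
    bc /= np.linalg.norm(bc)
    n = np.cross(p2 - p1, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = bond * np.array([-np.cos(theta), np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi)])
    return p3 + d[0] * bc + d[1] * m + d[2] * n


def place(chi, gamma, beta):
    R0, t0, _ = superpose(np.array([UNIT["C1'"], UNIT["N"]]), np.array([C1P, NG]))
    a = {n: R0 @ v + t0 for n, v in UNIT.items()}
    cur = dihedral(a["O4'"], a["C1'"], NG, CREF)
    Rc = rotation_about_axis(a["C1'"] - NG, wrap_angle(chi - cur))
    for n in a:
        a[n] = NG + Rc @ (a[n] - NG)
    a["C1'"], a["N"] = C1P, NG
    a["O5'"] = nerf(a["C3'"], a["C4'"], a["C5'"], 1.427, 110.2, gamma)
    a["P"] = nerf(a["C4'"], a["C5'"], a["O5'"], 1.592, 120.9, beta)
    return a


def image(v, k, cx):
    c = np.array([cx, 0.0, 0.0])
    g = np.linalg.matrix_power(RZ, k) if k >= 0 else np.linalg.matrix_power(RZ.T, -k)
    return g @ (v - c) + c + np.array([0.0, 0.0, RISE * k])


def residuals(theta):
    chi, gamma, beta, cx = theta
    a = place(chi, gamma, beta)
    Pn, O5n = image(a["P"], 1, cx), image(a["O5'"], 1, cx)
    rr = [30.0 * (np.linalg.norm(Pn - a["O3'"]) - 1.607)]

    def ang(p, q, s):
        u, v = p - q, s - q
        return np.degrees(np.arccos(np.clip(
            np.dot(u, v) / np.linalg.norm(u) / np.linalg.norm(v), -1, 1)))

    rr.append(10.0 * np.radians(ang(a["C3'"], a["O3'"], Pn) - 119.7))
    rr.append(10.0 * np.radians(ang(a["O3'"], Pn, O5n) - 104.0))
    eps = dihedral(a["C4'"], a["C3'"], a["O3'"], Pn)
    zet = dihedral(a["C3'"], a["O3'"], Pn, O5n)
    rr.append(8.0 * np.radians(wrap_angle(eps - zet + 90.0)))
    rr.append(2.0 * np.radians(wrap_angle(eps + 171.0)))
    rr.append(2.0 * np.radians(wrap_angle(zet + 103.0)))
    alp = dihedral(image(a["O3'"], -1, cx), a["P"], a["O5'"], a["C5'"])
    rr.append(2.0 * np.radians(wrap_angle(alp + 63.0)))
    P = a["P"]
    rr.append(4.0 * (np.linalg.norm(image(FLIP @ P, -3, cx) - P) - 11.75))
    rr.append(4.0 * (np.linalg.norm(image(FLIP @ P, -4, cx) - P) - 11.75))
    for k in range(-8, 9):
        rr.append(10.0 * max(0.0, 11.0 - np.linalg.norm(image(FLIP @ P, k, cx) - P)))
    rr.append(2.0 * (np.linalg.norm(image(P, 1, cx) - P) - 6.8))
    return np.array(rr)


def main():
    best = None
    for chi0 in (-90.0, -105.0, -120.0, -140.0):
        for g0 in (30.0, 54.0, 80.0):
            for b0 in (150.0, 171.0, -170.0):
                for cx0 in (-1.0, 0.0, 1.0):
                    sol = least_squares(residuals, [chi0, g0, b0, cx0],
                                        xtol=1e-13, ftol=1e-13, max_nfev=5000)
                    if best is None or sol.cost < best.cost:
                        best = sol
    chi, gamma, beta, cx = best.x
    a = place(chi, gamma, beta)
    # phosphate oxygens: symmetric about the O5'-P-O3'(prev) bisector plane
    P, O5 = a["P"], a["O5'"]
    O3prev = image(a["O3'"], -1, cx)
    u1 = (O5 - P) / np.linalg.norm(O5 - P)
    u2 = (O3prev - P) / np.linalg.norm(O3prev - P)
    b = -(u1 + u2)
    b /= np.linalg.norm(b)
    w = np.cross(u1, u2)
    w /= np.linalg.norm(w)
    half = np.radians(119.6 / 2)
    a["OP1"] = P + 1.485 * (b * np.cos(half) + w * np.sin(half))
    a["OP2"] = P + 1.485 * (b * np.cos(half) - w * np.sin(half))

    print(f"# solved: chi={chi:.2f} gamma={gamma:.2f} beta={beta:.2f} cx={cx:.4f} "
          f"cost={best.cost:.3f}")
    slide = rotation_about_axis([0, 0, 1], -TWIST / 2) @ ((np.eye(3) - RZ) @ np.array([cx, 0, 0]))
    print(f"# implied FIBER_SLIDE = {slide[1]:.4f}")
    print("BACKBONE_TEMPLATE = {")
    for n in ["P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'"]:
        x, y, z = a[n]
        print(f'    "{n}": ({x:.6f}, {y:.6f}, {z:.6f}),')
    print("}")


if __name__ == "__main__":
    main()
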
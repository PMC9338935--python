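"""Synthetic B-DNA duplexes and toy protein probes for pipeline testing.

``build_fiber_bdna`` constructs an all-heavy-atom duplex of arbitrary
sequence from a single helically symmetric nucleotide repeating unit.
The backbone unit was derived once by constrained least squares: standard
deoxyribose/phosphate bond lengths and angles (C2'-endo sugar) closed
under the helical symmetry of 36 deg twist / 3.38 Å rise, with the
cross-strand phosphate geometry calibrated so the regular-B-DNA
minor-groove P-to-P reference of 11.7 Å emerges from the default build
(see docs/methods.md; scripts/derive_fiber_template.py regenerates it).
The unit is expressed in the base-pair reference frame; the complementary
strand is its image under the pair dyad (180 deg rotation about x).

Base pairs are placed along the helix by composing per-step rigid-body
parameters, so per-step roll/twist overrides feed straight into the same
mid-frame algebra the analysis module inverts.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .bases import (BASE_ATOMS, COMPLEMENT, PAIR_FLIP, STANDARD_BASES,
                    complement_sequence, residue_name)
from .frames import StepParameters, compose_step, frames_about_mid
from .geom import rotation_about_axis, superpose, wrap_angle, dihedral
from .model import Atom, Chain, Residue, StructureModel

__all__ = ["FiberParams", "build_fiber_bdna", "apply_step_perturbations",
           "make_probe_complex", "BACKBONE_TEMPLATE"]

# Sugar-phosphate repeating unit in the base-pair frame (strand c), Å.
# Frozen output of the one-time fiber calibration (see module docstring).
BACKBONE_TEMPLATE: Dict[str, np.ndarray] = {
    "P": (0.193074, 9.468251, -1.143687),
    "OP1": (1.349169, 9.130958, -0.274837),
    "OP2": (-0.527872, 10.750474, -0.940298),
    "O5'": (-0.873442, 8.296831, -0.986260),
    "C5'": (-2.117578, 8.339874, -1.683828),
    "C4'": (-3.087509, 7.351665, -1.081517),
    "O4'": (-2.571347, 6.011671, -1.256194),
    "C3'": (-3.345000, 7.522317, 0.416548),
    "O3'": (-4.708231, 7.246910, 0.717681),
    "C2'": (-2.463829, 6.459235, 1.042151),
    "C1'": (-2.479000, 5.350000, 0.000000),
}
BACKBONE_TEMPLATE = {k: np.asarray(v, float) for k, v in BACKBONE_TEMPLATE.items()}

#: Constant slide implied by the calibrated axis offset of the fiber unit;
#: with it, the default step keeps the duplex straight around a fixed axis.
FIBER_SLIDE = -0.8642
BACKBONE_ORDER = ["P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'"]
_TERMINAL_5P = {"P", "OP1", "OP2"}


@dataclass
class FiberParams:
    """Helical parameters of the fiber generator.

    Defaults produce a straight, regular B-DNA duplex: 36.0 deg twist and
    3.38 Å rise per step with zero roll and tilt.  ``slide`` carries the
    calibration constant that keeps the repeating unit on a fixed helix
    axis; ``propeller`` rotates the two bases of each pair about their
    long axis in opposite senses (bases only; the backbone stays on the
    fiber path).  ``seed`` feeds the optional coordinate ``jitter`` (Å,
    Gaussian), the only randomised feature.
    """

    twist: float = 36.0
    rise: float = 3.38
    roll: float = 0.0
    tilt: float = 0.0
    shift: float = 0.0
    slide: float = FIBER_SLIDE
    propeller: float = 0.0
    sugar_pucker: str = "C2'-endo"
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sugar_pucker != "C2'-endo":
            raise ValueError("only the C2'-endo sugar preset is available")


def _validate_sequence(sequence: str) -> str:
    seq = sequence.upper()
    if len(seq) < 4:
        raise ValueError("sequence must be at least 4 bases long")
    for i, ch in enumerate(seq):
        if ch not in COMPLEMENT:
            raise ValueError(f"invalid base {sequence[i]!r} at position {i}")
    return seq


def _pair_frames(n_steps: int, params: FiberParams,
                 step_overrides: Optional[Dict[int, Dict[str, float]]] = None):
    """Chain of base-pair frames produced by composing per-step parameters."""
    frames = [(np.eye(3), np.zeros(3))]
    for k in range(n_steps):
        over = (step_overrides or {}).get(k, {})
        sp = StepParameters(
            shift=over.get("shift", params.shift),
            slide=over.get("slide", params.slide),
            rise=over.get("rise", params.rise),
            tilt=over.get("tilt", params.tilt),
            roll=over.get("roll", params.roll),
            twist=over.get("twist", params.twist),
        )
        R, o = frames[-1]
        R2, o2, _, _ = compose_step(R, o, sp)
        frames.append((R2, o2))
    return frames


def _nucleotide_atoms(base: str, R: np.ndarray, o: np.ndarray, flip: bool,
                      propeller: float) -> Dict[str, np.ndarray]:
    """All heavy atoms of one nucleotide placed in the global frame."""
    Rb = R @ (PAIR_FLIP if flip else np.eye(3))
    if propeller:
        # each base rotates about the pair long axis by half the propeller
        half = propeller / 2.0
        Rprop = rotation_about_axis(R[:, 1], half if not flip else -half)
    else:
        Rprop = np.eye(3)
    out = {}
    for name in BACKBONE_ORDER:
        out[name] = Rb @ BACKBONE_TEMPLATE[name] + o
    for name in BASE_ATOMS[base]:
        out[name] = Rprop @ (Rb @ STANDARD_BASES[base][name]) + o
    return out


def build_fiber_bdna(sequence: str, params: Optional[FiberParams] = None,
                     step_overrides: Optional[Dict[int, Dict[str, float]]] = None,
                     backbone_overrides: Optional[Dict[Tuple[str, int], Dict[str, float]]] = None,
                     ) -> StructureModel:
    """Build an ideal double-stranded B-DNA fragment from a sequence.

    Parameters
    ----------
    sequence : strand c sequence 5'->3' over the ACGT alphabet (>= 4 nt).
    params : helical parameters; defaults give straight regular B-DNA.
    step_overrides : optional per-step parameter overrides keyed by step
        index (0 = step between pairs 0 and 1); values like
        ``{"roll": 5.0, "twist": 34.0}``.
    backbone_overrides : optional per-nucleotide torsion overrides keyed
        by (chain id, residue number) with target ``epsilon`` and/or
        ``zeta`` values in degrees (local phosphate repositioning).

    Returns a two-chain model: chain C = the given strand, chain D = the
    reverse complement, both listed 5'->3', with 5'-hydroxyl termini (no
    terminal phosphate).  Deterministic for fixed inputs.
    """
    params = params or FiberParams()
    seq = _validate_sequence(sequence)
    n = len(seq)
    if step_overrides:
        bad = [k for k in step_overrides if not (0 <= k < n - 1)]
        if bad:
            raise IndexError(f"step overrides reference absent steps {bad}")
    frames = _pair_frames(n - 1, params, step_overrides)

    c_res: List[Residue] = []
    d_res: List[Residue] = []
    for k, (R, o) in enumerate(frames):
        bc = seq[k]
        bd = COMPLEMENT[bc]
        atoms_c = _nucleotide_atoms(bc, R, o, flip=False, propeller=params.propeller)
        atoms_d = _nucleotide_atoms(bd, R, o, flip=True, propeller=params.propeller)
        if k == 0:
            atoms_c = {nm: v for nm, v in atoms_c.items() if nm not in _TERMINAL_5P}
        if k == n - 1:
            atoms_d = {nm: v for nm, v in atoms_d.items() if nm not in _TERMINAL_5P}
        c_res.append(Residue(residue_name(bc), k + 1, "", [
            Atom(nm, _element_of(nm), v) for nm, v in atoms_c.items()]))
        d_res.append(Residue(residue_name(bd), n - k, "", [
            Atom(nm, _element_of(nm), v) for nm, v in atoms_d.items()]))

    model = StructureModel(
        chains=[Chain("C", c_res), Chain("D", list(reversed(d_res)))],
        source="fiber-bdna", title=f"fiber B-DNA duplex {seq}")
    if backbone_overrides:
        _apply_backbone_overrides(model, backbone_overrides)
    if params.jitter > 0:
        rng = np.random.default_rng(params.seed)
        for _, _, a in model.iter_atoms():
            a.position = a.position + rng.normal(scale=params.jitter, size=3)
    model._fiber_spec = {  # enables apply_step_perturbations round-trips
        "sequence": seq, "params": params,
        "step_overrides": copy.deepcopy(step_overrides) or {},
        "backbone_overrides": copy.deepcopy(backbone_overrides) or {},
    }
    return model


def _element_of(atom_name: str) -> str:
    return atom_name.strip("0123456789'")[0]


def _apply_backbone_overrides(model: StructureModel,
                              overrides: Dict[Tuple[str, int], Dict[str, float]]) -> None:
    """Retarget epsilon/zeta of named nucleotides by rotating the 3'-phosphate.

    epsilon(i) is adjusted by rotating the whole 5'-phosphate group of the
    following nucleotide (P, OP1, OP2, O5') about the C3'(i)-O3'(i) bond;
    zeta(i) by rotating that O5' about the O3'(i)-P bond.  The sugar and
    pairing geometry are untouched; the O5'-C5' bond of the neighbour
    absorbs the strain (documented limitation of the perturbation model).
    """
    for (cid, num), target in overrides.items():
        chain = model.chain(cid)
        idx = next((i for i, r in enumerate(chain.residues) if r.number == num), None)
        if idx is None:
            raise IndexError(f"no residue {num} in chain {cid}")
        if idx + 1 >= len(chain.residues):
            raise IndexError(f"residue {cid}:{num} has no 3'-neighbour; epsilon/zeta undefined")
        res, nxt = chain.residues[idx], chain.residues[idx + 1]
        c3, o3 = res.atom("C3'"), res.atom("O3'")
        c4 = res.atom("C4'")
        p, o5 = nxt.atom("P"), nxt.atom("O5'")
        if any(a is None for a in (c3, o3, c4, p, o5)):
            raise ValueError(f"residue {cid}:{num}: missing backbone atoms for override")
        if "epsilon" in target:
            cur = dihedral(c4.position, c3.position, o3.position, p.position)
            rot = rotation_about_axis(o3.position - c3.position,
                                      wrap_angle(target["epsilon"] - cur))
            for nm in ("P", "OP1", "OP2", "O5'"):
                a = nxt.atom(nm)
                if a is not None:
                    a.position = o3.position + rot @ (a.position - o3.position)
        if "zeta" in target:
            cur = dihedral(c3.position, o3.position, p.position, o5.position)
            rot = rotation_about_axis(p.position - o3.position,
                                      wrap_angle(target["zeta"] - cur))
            o5.position = p.position + rot @ (o5.position - p.position)


def apply_step_perturbations(model: StructureModel,
                             step_overrides: Optional[Dict[int, Dict[str, float]]] = None,
                             backbone_overrides: Optional[Dict[Tuple[str, int], Dict[str, float]]] = None,
                             ) -> StructureModel:
    """Rebuild a fiber duplex with additional per-step / per-nucleotide overrides.

    Only models produced by :func:`build_fiber_bdna` carry the generation
    record needed for an exact rebuild.  With no overrides the result is
    coordinate-identical to the input.
    """
    spec = getattr(model, "_fiber_spec", None)
    if spec is None:
        raise ValueError("model was not built by build_fiber_bdna; cannot perturb")
    merged_steps = dict(spec["step_overrides"])
    for k, v in (step_overrides or {}).items():
        merged_steps[k] = {**merged_steps.get(k, {}), **v}
    merged_bb = dict(spec["backbone_overrides"])
    for k, v in (backbone_overrides or {}).items():
        merged_bb[k] = {**merged_bb.get(k, {}), **v}
    return build_fiber_bdna(spec["sequence"], spec["params"],
                            step_overrides=merged_steps or None,
                            backbone_overrides=merged_bb or None)


# ---------------------------------------------------------------- probes

_PROBE_TEMPLATES: Dict[str, Tuple[str, str, Dict[str, np.ndarray]]] = {
    # residue name, head atom (placed on the approach ray), local atoms
    "point-atom": ("GLY", "N", {"N": np.array([0.0, 0.0, 0.0])}),
    "LYS-like": ("LYS", "NZ", {
        "CD": np.array([0.0, 0.0, -2.95]),
        "CE": np.array([0.0, 0.7, -1.6]),
        "NZ": np.array([0.0, 0.0, 0.0]),
    }),
    "ARG-like": ("ARG", "NH1", {
        "CD": np.array([0.0, 0.4, -2.75]),
        "NE": np.array([0.0, -0.25, -1.55]),
        "CZ": np.array([0.0, 0.45, -0.45]),
        "NH1": np.array([0.0, 1.78, -0.40]),
        "NH2": np.array([0.0, -0.25, 0.65]),
    }),
    "HIS-like": ("HIS", "NE2", {
        "CG": np.array([0.0, 0.55, -2.15]),
        "ND1": np.array([0.0, -0.50, -1.27]),
        "CD2": np.array([0.0, 1.72, -1.40]),
        "CE1": np.array([0.0, 0.05, -0.11]),
        "NE2": np.array([0.0, 1.39, 0.05]),
    }),
}


def make_probe_complex(duplex: StructureModel,
                       probes: Sequence[Tuple[str, int, str, float]],
                       ) -> StructureModel:
    """Place toy amino-acid-like probe groups near duplex grooves.

    Each probe is ``(kind, operator_index, groove, distance)`` with kind
    in ``point-atom | LYS-like | ARG-like | HIS-like``, groove ``minor`` /
    ``major`` / ``phosphate``, and the requested closest heavy-atom
    distance (Å, achieved within 0.05 Å).  For groove targets the
    distance is measured to the groove floor (base atoms) — the sugar
    O4' rim may then sit slightly closer, as it does for real edge-on
    minor-groove binders; for ``phosphate`` targets it is measured to
    all DNA atoms.  Probes are appended as protein residues on a new
    chain so component selection by polymer type behaves as for a real
    complex.

    Raises ``ValueError`` when the requested distance cannot be reached
    along the outward groove direction (probe would overlap the DNA).
    """
    out = duplex.copy()
    # keep the generation record so downstream perturbation still works
    if hasattr(duplex, "_fiber_spec"):
        out._fiber_spec = copy.deepcopy(duplex._fiber_spec)
    chain_c = out.chains[0]
    n = len(chain_c.residues)
    center = (n + 1) // 2  # residue number of operator index 0 on chain C
    dna_xyz = duplex.coords()
    _bb = set(BACKBONE_ORDER)
    dna_base_xyz = np.array([a.position for _, r, a in duplex.iter_atoms()
                             if a.name not in _bb])
    probe_chain = Chain("Z", [])
    for pnum, (kind, op_index, groove, dist) in enumerate(probes, start=1):
        if kind not in _PROBE_TEMPLATES:
            raise ValueError(f"unknown probe kind {kind!r}")
        if dist <= 0:
            raise ValueError("probe distance must be positive")
        resname, head, raw_tmpl = _PROBE_TEMPLATES[kind]
        tmpl = {nm: v - raw_tmpl[head] for nm, v in raw_tmpl.items()}
        resnum = op_index + center
        res = chain_c.residue(resnum)
        if res is None:
            raise IndexError(f"operator index {op_index} outside the duplex")
        anchor, axis_point = _groove_anchor(out, resnum, groove)
        if groove == "phosphate":
            u = anchor - axis_point
        else:
            # approach the groove floor: ray from the rim midpoint down to the
            # nearest base atom, so the controlling contact is a base atom
            floor = dna_base_xyz[np.argmin(((dna_base_xyz - anchor) ** 2).sum(1))]
            u = anchor - floor
            anchor = floor
        u = u / np.linalg.norm(u)
        Ralign = _rotation_z_to(-u)

        measure_xyz = dna_xyz if groove == "phosphate" else dna_base_xyz

        def min_dist(t: float) -> float:
            pts = np.array([anchor + t * u + Ralign @ v for v in tmpl.values()])
            d = np.sqrt(((pts[:, None, :] - measure_xyz[None, :, :]) ** 2).sum(-1))
            return float(d.min())

        # walk the probe along the outward ray; pick the crossing on the
        # outward-facing branch (distance increasing away from the duplex)
        ts = np.arange(-6.0, 40.0, 0.2)
        fs = np.array([min_dist(t) for t in ts])
        k0 = int(np.argmin(fs))
        if dist < fs[k0]:
            raise ValueError(
                f"probe {kind} at index {op_index}: requested distance {dist} Å "
                f"is closer than the groove allows ({fs[k0]:.2f} Å at contact)")
        k1 = next(k for k in range(k0, len(ts)) if fs[k] >= dist)
        lo = ts[max(k1 - 1, 0)]
        hi = ts[k1] if fs[k1] > dist else ts[min(k1 + 1, len(ts) - 1)]
        t = brentq(lambda t: min_dist(t) - dist, lo, hi, xtol=1e-4) \
            if fs[k1] != dist else ts[k1]
        placed = np.array([anchor + t * u + Ralign @ v for v in tmpl.values()])
        hard = np.sqrt(((placed[:, None, :] - dna_xyz[None, :, :]) ** 2).sum(-1)).min()
        if hard < 0.8:
            raise ValueError(
                f"probe {kind} at index {op_index}: placement at {dist} Å "
                f"overlaps the DNA (closest atom {hard:.2f} Å)")
        atoms = [Atom(nm, _element_of(nm), anchor + t * u + Ralign @ v)
                 for nm, v in tmpl.items()]
        probe_chain.residues.append(Residue(resname, pnum, "", atoms))
    out.chains.append(probe_chain)
    return out


def _groove_anchor(model: StructureModel, resnum: int, groove: str):
    """Anchor point on the groove rim near chain-C residue ``resnum`` and a
    local helix-axis point, for outward probe placement."""
    chain_c, chain_d = model.chains[0], model.chains[1]
    n = len(chain_c.residues)
    def P_of(chain, num):
        r = chain.residue(num)
        a = r.atom("P") if r else None
        return a.position if a is not None else None
    pc = P_of(chain_c, resnum)
    if groove == "phosphate":
        if pc is None:
            raise ValueError(f"residue C:{resnum} has no phosphate")
        anchor = pc
    else:
        # cross-strand partner offsets; chain D residue j pairs chain C residue n+1-j
        offs = range(2, 6) if groove == "minor" else range(-7, -1)
        cands = []
        for off in offs:
            pd = P_of(chain_d, (n + 1 - resnum) + off)
            if pd is not None and pc is not None:
                cands.append((float(np.linalg.norm(pc - pd)), pd))
        if not cands:
            raise ValueError(f"no cross-strand phosphate partner for C:{resnum}")
        _, pd = min(cands)
        anchor = (pc + pd) / 2.0
    # local axis estimate: centroid of nearby C1' atoms on both strands
    pts = []
    for dlt in range(-3, 4):
        for chain, num in ((chain_c, resnum + dlt), (chain_d, (n + 1 - resnum) + dlt)):
            r = chain.residue(num)
            if r is not None and r.atom("C1'") is not None:
                pts.append(r.atom("C1'").position)
    axis_point = np.mean(pts, axis=0)
    return anchor, axis_point


def _rotation_z_to(u: np.ndarray) -> np.ndarray:
    """Rotation taking +z onto unit vector u."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, u)
    s = np.linalg.norm(v)
    c = float(np.dot(z, u))
    if s < 1e-12:
        return np.eye(3) if c > 0 else rotation_about_axis([1, 0, 0], 180.0)
    return rotation_about_axis(v, float(np.degrees(np.arctan2(s, c))))
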
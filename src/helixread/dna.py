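"""Nucleic-acid geometry: torsions, backbone states, pairing, bp/step parameters.

Backbone dihedrals follow the IUPAC definitions (alpha = O3'(i-1)-P-O5'-C5'
through zeta = C3'-O3'-P(i+1)-O5'(i+1); chi over the glycosidic bond).
The B_I/B_II substates of the phosphodiester backbone are classified from
epsilon - zeta: canonical B_I sits near -90 deg (epsilon trans, zeta
gauche-), B_II near +90 deg; a configurable symmetric dead zone around
zero is reported as ``intermediate``.

Base reference frames are obtained by least-squares superposition of the
embedded standard base geometry onto the observed ring atoms; base-pair
and step parameters then come from the mid-frame algebra in
:mod:`helixread.frames`, with the complementary-strand frame flipped
about its x-axis so that (buckle, propeller, opening) read from the
(tilt, roll, twist) slots.  With that convention the usual B-DNA
propeller is negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .bases import BASE_ATOMS, COMPLEMENT, PAIR_FLIP, RING_ATOMS, STANDARD_BASES, base_letter
from .frames import StepParameters, decompose_step
from .geom import angle_between, dihedral, superpose, wrap_angle
from .model import Chain, Residue, StructureModel

__all__ = [
    "Nucleotide", "BackboneTorsions", "BackboneState", "BasePair",
    "nucleotides_of", "backbone_torsions", "classify_backbone_state",
    "base_frame", "detect_base_pairs", "bp_and_step_parameters",
    "region_average_roll", "BI_BII_BAND",
]

#: Half-width (deg) of the intermediate dead zone between B_I and B_II.
BI_BII_BAND = 45.0

_MAX_O3P_BOND = 2.5  # Å; covalent connectivity check between residues


@dataclass
class Nucleotide:
    """One nucleotide with its chain context (prev/next are chain neighbours
    only when covalently connected through the phosphodiester bridge)."""
    chain_id: str
    residue: Residue
    letter: str
    prev: Optional["Nucleotide"] = None
    next: Optional["Nucleotide"] = None

    @property
    def key(self) -> Tuple[str, int]:
        return (self.chain_id, self.residue.number)

    def atom_pos(self, name: str) -> Optional[np.ndarray]:
        a = self.residue.atom(name)
        return None if a is None else a.position

    def __repr__(self):
        return f"<Nucleotide {self.letter} {self.chain_id}:{self.residue.number}>"


@dataclass
class BackboneTorsions:
    """IUPAC backbone/glycosidic torsions in degrees; ``None`` = undefined."""
    alpha: Optional[float] = None
    beta: Optional[float] = None
    gamma: Optional[float] = None
    delta: Optional[float] = None
    epsilon: Optional[float] = None
    zeta: Optional[float] = None
    chi: Optional[float] = None


@dataclass
class BackboneState:
    state: str                      # BI | BII | intermediate | undefined
    eps_minus_zeta: Optional[float]


@dataclass
class BasePair:
    c: Nucleotide
    d: Nucleotide
    pair_type: str                  # watson-crick | other
    origin: Optional[np.ndarray] = None
    frame: Optional[np.ndarray] = None
    buckle: Optional[float] = None
    propeller: Optional[float] = None
    opening: Optional[float] = None
    shear: Optional[float] = None
    stretch: Optional[float] = None
    stagger: Optional[float] = None


def nucleotides_of(model: StructureModel) -> List[Nucleotide]:
    """Extract DNA nucleotides in chain order and link covalent neighbours."""
    out: List[Nucleotide] = []
    for chain in model.chains:
        prev: Optional[Nucleotide] = None
        for res in chain.residues:
            if res.kind != "dna":
                prev = None
                continue
            nuc = Nucleotide(chain.cid, res, base_letter(res.name))
            if prev is not None:
                o3 = prev.atom_pos("O3'")
                p = nuc.atom_pos("P")
                if o3 is not None and p is not None and np.linalg.norm(o3 - p) <= _MAX_O3P_BOND:
                    prev.next = nuc
                    nuc.prev = prev
            out.append(nuc)
            prev = nuc
    return out


def _dihedral_of(*pts) -> Optional[float]:
    if any(p is None for p in pts):
        return None
    return dihedral(*pts)


def backbone_torsions(nuc: Nucleotide) -> BackboneTorsions:
    """All seven torsions of one nucleotide; missing atoms or chain termini
    leave the affected torsion ``None`` while the others are still computed."""
    p = nuc.atom_pos
    prev_o3 = nuc.prev.atom_pos("O3'") if nuc.prev else None
    next_p = nuc.next.atom_pos("P") if nuc.next else None
    next_o5 = nuc.next.atom_pos("O5'") if nuc.next else None
    if nuc.letter in ("A", "G"):
        chi = _dihedral_of(p("O4'"), p("C1'"), p("N9"), p("C4"))
    else:
        chi = _dihedral_of(p("O4'"), p("C1'"), p("N1"), p("C2"))
    return BackboneTorsions(
        alpha=_dihedral_of(prev_o3, p("P"), p("O5'"), p("C5'")),
        beta=_dihedral_of(p("P"), p("O5'"), p("C5'"), p("C4'")),
        gamma=_dihedral_of(p("O5'"), p("C5'"), p("C4'"), p("C3'")),
        delta=_dihedral_of(p("C5'"), p("C4'"), p("C3'"), p("O3'")),
        epsilon=_dihedral_of(p("C4'"), p("C3'"), p("O3'"), next_p),
        zeta=_dihedral_of(p("C3'"), p("O3'"), next_p, next_o5),
        chi=chi,
    )


def classify_backbone_state(t: BackboneTorsions, band: float = BI_BII_BAND) -> BackboneState:
    """B_I / B_II / intermediate from epsilon - zeta (wrapped to (-180, 180]).

    B_I iff eps - zeta <= -band, B_II iff >= +band, otherwise intermediate;
    undefined when either torsion is undefined (e.g. 3'-terminal)."""
    if t.epsilon is None or t.zeta is None:
        return BackboneState("undefined", None)
    d = wrap_angle(t.epsilon - t.zeta)
    if d <= -band:
        state = "BI"
    elif d >= band:
        state = "BII"
    else:
        state = "intermediate"
    return BackboneState(state, d)


def base_frame(nuc: Nucleotide):
    """Fitted standard reference frame of one base.

    Returns ``(origin, frame, rmsd)`` where ``frame`` columns are the
    frame axes in global coordinates; raises ``ValueError`` when fewer
    than six ring atoms are present.
    """
    ring = RING_ATOMS[nuc.letter]
    std, obs = [], []
    for name in ring:
        pos = nuc.atom_pos(name)
        if pos is not None:
            std.append(STANDARD_BASES[nuc.letter][name])
            obs.append(pos)
    if len(obs) < 6:
        raise ValueError(f"{nuc}: only {len(obs)} ring atoms; frame undefined")
    R, t, rmsd = superpose(np.array(std), np.array(obs))
    return t, R, rmsd


# ---------------------------------------------------------------- pairing

_C1C1_MEAN, _C1C1_TOL = 10.4, 1.6
_HBOND_MAX = 3.5
_PLANE_MAX = 65.0
_WC_PARTNERS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def _pair_score(a: Nucleotide, b: Nucleotide) -> Optional[Tuple[int, float]]:
    """(number of inter-base N/O contacts, C1'-C1' distance) or None."""
    c1a, c1b = a.atom_pos("C1'"), b.atom_pos("C1'")
    if c1a is None or c1b is None:
        return None
    d_c1 = float(np.linalg.norm(c1a - c1b))
    if abs(d_c1 - _C1C1_MEAN) > _C1C1_TOL:
        return None
    try:
        _, Ra, _ = base_frame(a)
        _, Rb, _ = base_frame(b)
    except ValueError:
        return None
    if min(angle_between(Ra[:, 2], Rb[:, 2]), 180 - angle_between(Ra[:, 2], Rb[:, 2])) > _PLANE_MAX:
        return None
    n_hb = 0
    for na in BASE_ATOMS[a.letter]:
        pa = a.atom_pos(na)
        if pa is None or na[0] not in "NO":
            continue
        for nb in BASE_ATOMS[b.letter]:
            pb = b.atom_pos(nb)
            if pb is None or nb[0] not in "NO":
                continue
            if np.linalg.norm(pa - pb) <= _HBOND_MAX:
                n_hb += 1
    if n_hb < 2:
        return None
    return n_hb, d_c1


def detect_base_pairs(model: StructureModel) -> List[BasePair]:
    """Find base pairs by geometric criteria (C1'-C1' distance, >= 2
    inter-base N/O contacts <= 3.5 Å, near-parallel base planes).

    Greedy matching keeps at most one partner per nucleotide, preferring
    more hydrogen-bond-like contacts.  Pairs are ordered 5'->3' along the
    strand designated ``c`` (the chain of the first paired nucleotide).
    Returns an empty list (after emitting a diagnostic on the model) when
    nothing pairs.
    """
    nucs = nucleotides_of(model)
    cand = []
    for i, a in enumerate(nucs):
        for b in nucs[i + 1:]:
            if a.chain_id == b.chain_id and abs(a.residue.number - b.residue.number) < 2:
                continue
            sc = _pair_score(a, b)
            if sc is not None:
                n_hb, d_c1 = sc
                cand.append((-n_hb, abs(d_c1 - _C1C1_MEAN), a, b))
    cand.sort(key=lambda t: (t[0], t[1]))
    used = set()
    raw: List[Tuple[Nucleotide, Nucleotide]] = []
    for _, _, a, b in cand:
        if a.key in used or b.key in used:
            continue
        used.add(a.key)
        used.add(b.key)
        raw.append((a, b))
    if not raw:
        return []
    # orient: strand c = chain of the lowest-numbered paired nucleotide
    c_chain = min((a for a, _ in raw), key=lambda n: (n.chain_id, n.residue.number)).chain_id
    pairs = []
    for a, b in raw:
        if b.chain_id == c_chain and a.chain_id != c_chain:
            a, b = b, a
        ptype = "watson-crick" if (a.letter, b.letter) in _WC_PARTNERS else "other"
        pairs.append(BasePair(a, b, ptype))
    pairs.sort(key=lambda p: (p.c.chain_id != c_chain, p.c.chain_id, p.c.residue.number))
    return pairs


def bp_and_step_parameters(pairs: Sequence[BasePair]):
    """Intra-pair and inter-pair parameters for an ordered list of pairs.

    Fills origin/frame and (buckle, propeller, opening, shear, stretch,
    stagger) on each pair in place, and returns ``(pairs, steps)`` where
    ``steps[k]`` are the :class:`StepParameters` between pairs k and k+1.
    """
    if not pairs:
        raise ValueError("no base pairs supplied")
    for bp in pairs:
        oc, Rc, _ = base_frame(bp.c)
        od, Rd, _ = base_frame(bp.d)
        Rdf = Rd @ PAIR_FLIP
        params, Rm, om = decompose_step(Rdf, od, Rc, oc)
        bp.origin, bp.frame = om, Rm
        bp.shear, bp.stretch, bp.stagger = params.shift, params.slide, params.rise
        bp.buckle, bp.propeller, bp.opening = params.tilt, params.roll, params.twist
    steps: List[StepParameters] = []
    for p1, p2 in zip(pairs, pairs[1:]):
        sp, _, _ = decompose_step(p1.frame, p1.origin, p2.frame, p2.origin)
        steps.append(sp)
    return list(pairs), steps


def region_average_roll(steps: Sequence[StepParameters],
                        pair_indices: Sequence[int],
                        lo: int, hi: int) -> float:
    """Arithmetic mean roll over steps lying fully inside [lo, hi].

    ``pair_indices[k]`` is the operator index of pair k; step k joins
    pairs k and k+1 and counts when both indices are inside the region.
    """
    if len(pair_indices) != len(steps) + 1:
        raise ValueError("pair_indices must have one more entry than steps")
    rolls = [s.roll for s, i, j in zip(steps, pair_indices, pair_indices[1:])
             if lo <= i <= hi and lo <= j <= hi]
    if len(rolls) < 2:
        raise ValueError(f"region [{lo}, {hi}] covers {len(rolls)} steps; need >= 2")
    return float(np.mean(rolls))
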
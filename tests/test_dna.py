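"""Torsions, backbone-state classification, base frames, pair/step parameters."""

import numpy as np
import pytest

import helixread as hx
from helixread.bases import PAIR_FLIP, RING_ATOMS, STANDARD_BASES
from helixread.dna import (BackboneTorsions, backbone_torsions, base_frame,
                           bp_and_step_parameters, classify_backbone_state,
                           detect_base_pairs, nucleotides_of, region_average_roll)
from helixread.geom import rotation_about_axis, wrap_angle


def test_terminal_torsions_undefined(hmpa1_duplex):
    nucs = [n for n in nucleotides_of(hmpa1_duplex) if n.chain_id == "C"]
    first, last = nucs[0], nucs[-1]
    t_first = backbone_torsions(first)
    assert t_first.alpha is None and t_first.beta is None  # no 5'-phosphate
    t_last = backbone_torsions(last)
    assert t_last.epsilon is None and t_last.zeta is None  # no 3'-neighbour
    mid = backbone_torsions(nucs[10])
    assert all(v is not None for v in vars(mid).values())


@pytest.mark.parametrize("eps,zeta,want", [
    (-170.0, -90.0, "BI"),       # canonical B_I: eps trans, zeta gauche-
    (-100.0, 170.0, "BII"),      # canonical B_II (wrap across +/-180)
    (-150.0, -130.0, "intermediate"),
    (170.0, -101.0, "BI"),
])
def test_backbone_state_classification(eps, zeta, want):
    t = BackboneTorsions(epsilon=eps, zeta=zeta)
    s = classify_backbone_state(t)
    assert s.state == want
    assert s.eps_minus_zeta == pytest.approx(wrap_angle(eps - zeta))


def test_backbone_state_undefined_when_missing():
    assert classify_backbone_state(BackboneTorsions(epsilon=None, zeta=-90)).state == "undefined"


def test_backbone_state_monotone_in_eps_minus_zeta():
    order = {"BI": 0, "intermediate": 1, "BII": 2}
    last = -1
    for d in np.linspace(-179, 179, 181):
        s = classify_backbone_state(BackboneTorsions(epsilon=d, zeta=0.0))
        assert order[s.state] >= last
        last = order[s.state]


def test_band_is_configurable():
    t = BackboneTorsions(epsilon=-30.0, zeta=0.0)
    assert classify_backbone_state(t, band=45.0).state == "intermediate"
    assert classify_backbone_state(t, band=20.0).state == "BI"


def test_base_frame_fixed_point():
    from helixread.model import Atom, Residue
    from helixread.dna import Nucleotide
    res = Residue("DA", 1, "", [Atom(n, n[0], STANDARD_BASES["A"][n])
                                for n in RING_ATOMS["A"]])
    nuc = Nucleotide("C", res, "A")
    origin, frame, rmsd = base_frame(nuc)
    assert rmsd < 1e-10
    assert np.allclose(frame, np.eye(3), atol=1e-10)
    assert np.allclose(origin, 0.0, atol=1e-10)


def test_base_frame_rotation_equivariance():
    from helixread.model import Atom, Residue
    from helixread.dna import Nucleotide
    R = rotation_about_axis([0.3, 1.0, 0.2], 41.0)
    t = np.array([4.0, -2.0, 7.0])
    res = Residue("DG", 1, "", [Atom(n, n[0], R @ STANDARD_BASES["G"][n] + t)
                                for n in RING_ATOMS["G"]])
    origin, frame, rmsd = base_frame(Nucleotide("C", res, "G"))
    assert rmsd < 1e-10
    assert np.allclose(frame, R, atol=1e-6)
    assert np.allclose(origin, t, atol=1e-6)


def test_base_frame_needs_six_ring_atoms():
    from helixread.model import Atom, Residue
    from helixread.dna import Nucleotide
    res = Residue("DA", 1, "", [Atom(n, n[0], STANDARD_BASES["A"][n])
                                for n in RING_ATOMS["A"][:5]])
    with pytest.raises(ValueError):
        base_frame(Nucleotide("C", res, "A"))


def test_parameters_invariant_under_rigid_motion(hmpa1_duplex, hmpa1_pairs):
    pairs, steps = hmpa1_pairs
    R = rotation_about_axis([1.0, -0.4, 0.7], 113.0)
    moved = hmpa1_duplex.transformed(R, np.array([-20.0, 5.0, 9.0]))
    pairs2, steps2 = bp_and_step_parameters(detect_base_pairs(moved))
    for s1, s2 in zip(steps, steps2):
        assert np.allclose(s1.as_tuple(), s2.as_tuple(), atol=1e-6)
    for p1, p2 in zip(pairs, pairs2):
        assert p1.propeller == pytest.approx(p2.propeller, abs=1e-6)
        assert p1.opening == pytest.approx(p2.opening, abs=1e-6)


def test_propeller_sign_convention():
    """Generator propeller of -15 deg is recovered as -15 (negative =
    the usual B-DNA propeller sense)."""
    m = hx.build_fiber_bdna("ACGTACGTAC", hx.FiberParams(propeller=-15.0))
    pairs, _ = bp_and_step_parameters(detect_base_pairs(m))
    assert np.mean([p.propeller for p in pairs]) == pytest.approx(-15.0, abs=0.1)


def test_region_average_roll_zero_on_straight_fiber(hmpa1_pairs, hmpa1_numbering):
    pairs, steps = hmpa1_pairs
    idx = [hmpa1_numbering.index_of(p.c.chain_id, p.c.residue.number)[0] for p in pairs]
    assert region_average_roll(steps, idx, -5, 5) == pytest.approx(0.0, abs=0.1)


def test_region_average_roll_recovers_override(hmpa1_duplex, hmpa1_numbering):
    m = hx.apply_step_perturbations(
        hmpa1_duplex, step_overrides={k: {"roll": 5.0} for k in range(6, 16)})
    pairs, steps = bp_and_step_parameters(detect_base_pairs(m))
    idx = [hmpa1_numbering.index_of(p.c.chain_id, p.c.residue.number)[0] for p in pairs]
    assert region_average_roll(steps, idx, -5, 5) == pytest.approx(5.0, abs=0.2)


def test_region_average_roll_requires_two_steps(hmpa1_pairs):
    pairs, steps = hmpa1_pairs
    idx = list(range(-11, 12))
    with pytest.raises(ValueError):
        region_average_roll(steps, idx, 20, 30)
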
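"""Fiber generator: determinism, complementarity, closure and perturbations."""

import numpy as np
import pytest

import helixread as hx
from helixread.bases import complement_sequence
from helixread.dna import (backbone_torsions, bp_and_step_parameters,
                           classify_backbone_state, detect_base_pairs,
                           nucleotides_of)

HMPA1 = "AACACGAATATCATCTACCAATT"


def test_operator_sequence_gives_23_wc_pairs(hmpa1_duplex, hmpa1_pairs):
    pairs, _ = hmpa1_pairs
    assert len(pairs) == 23
    assert all(p.pair_type == "watson-crick" for p in pairs)
    seq_d = "".join(n.letter for n in nucleotides_of(hmpa1_duplex) if n.chain_id == "D")
    assert seq_d == complement_sequence(HMPA1)


def test_build_is_deterministic():
    a = hx.build_fiber_bdna("ACGTACGTAC").coords()
    b = hx.build_fiber_bdna("ACGTACGTAC").coords()
    assert np.array_equal(a, b)


def test_invalid_sequence_reports_position():
    with pytest.raises(ValueError, match="position 3"):
        hx.build_fiber_bdna("ACGXACGT")
    with pytest.raises(ValueError):
        hx.build_fiber_bdna("ACG")


def test_default_fiber_is_all_BI(hmpa1_duplex):
    states = [classify_backbone_state(backbone_torsions(n)).state
              for n in nucleotides_of(hmpa1_duplex)]
    defined = [s for s in states if s != "undefined"]
    assert len(defined) == 44  # 46 nucleotides minus the two 3' termini
    assert set(defined) == {"BI"}


def test_pairing_partner_is_reverse_position():
    seq = "GATTACAGGT"
    m = hx.build_fiber_bdna(seq)
    pairs = detect_base_pairs(m)
    n = len(seq)
    assert len(pairs) == n
    for p in pairs:
        assert p.d.residue.number == n + 1 - p.c.residue.number


def test_separated_strands_do_not_pair(hmpa1_duplex):
    moved = hmpa1_duplex.copy()
    for r in moved.chain("D").residues:
        for a in r.atoms:
            a.position = a.position + np.array([50.0, 0.0, 0.0])
    assert detect_base_pairs(moved) == []


def test_step_override_roundtrip(hmpa1_duplex):
    m = hx.apply_step_perturbations(hmpa1_duplex,
                                    step_overrides={k: {"roll": 5.0} for k in range(8, 14)})
    _, steps = bp_and_step_parameters(detect_base_pairs(m))
    for k, s in enumerate(steps):
        expect = 5.0 if 8 <= k < 14 else 0.0
        assert s.roll == pytest.approx(expect, abs=0.2)


def test_backbone_override_creates_four_BII(hmpa1_duplex):
    targets = {("C", 10): {"epsilon": -100.0, "zeta": 170.0},
               ("C", 12): {"epsilon": -100.0, "zeta": 170.0},
               ("D", 10): {"epsilon": -100.0, "zeta": 170.0},
               ("D", 12): {"epsilon": -100.0, "zeta": 170.0}}
    m = hx.apply_step_perturbations(hmpa1_duplex, backbone_overrides=targets)
    nucs = {(n.chain_id, n.residue.number): n for n in nucleotides_of(m)}
    n_bii = 0
    for key, want in targets.items():
        t = backbone_torsions(nucs[key])
        assert t.epsilon == pytest.approx(want["epsilon"], abs=0.2)
        assert t.zeta == pytest.approx(want["zeta"], abs=0.2)
        if classify_backbone_state(t).state == "BII":
            n_bii += 1
    assert n_bii == 4
    all_states = [classify_backbone_state(backbone_torsions(n)).state
                  for n in nucleotides_of(m)]
    assert all_states.count("BII") == 4


def test_zero_overrides_identity(hmpa1_duplex):
    same = hx.apply_step_perturbations(hmpa1_duplex)
    assert np.array_equal(same.coords(), hmpa1_duplex.coords())


def test_perturbing_foreign_model_rejected(hmpa1_duplex, tmp_path):
    path = str(tmp_path / "x.pdb")
    hx.write_structure(hmpa1_duplex, path)
    parsed = hx.parse_structure(path)  # generation record lost on disk
    with pytest.raises(ValueError):
        hx.apply_step_perturbations(parsed, step_overrides={0: {"roll": 1.0}})


def test_reverse_complement_symmetry():
    seq = "AACGGTTCAGT"
    s1 = bp_and_step_parameters(detect_base_pairs(hx.build_fiber_bdna(seq)))[1]
    s2 = bp_and_step_parameters(detect_base_pairs(
        hx.build_fiber_bdna(complement_sequence(seq))))[1]
    r1 = [s.roll for s in s1]
    r2 = [s.roll for s in s2]
    assert np.allclose(r1, r2[::-1], atol=0.2)
    assert np.allclose([s.twist for s in s1], [s.twist for s in s2][::-1], atol=0.2)


def test_jitter_controlled_by_seed():
    p1 = hx.FiberParams(jitter=0.1, seed=5)
    p2 = hx.FiberParams(jitter=0.1, seed=5)
    p3 = hx.FiberParams(jitter=0.1, seed=6)
    a = hx.build_fiber_bdna("ACGTACGT", p1).coords()
    b = hx.build_fiber_bdna("ACGTACGT", p2).coords()
    c = hx.build_fiber_bdna("ACGTACGT", p3).coords()
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


# ---------------------------------------------------------------- probes

def test_point_probe_distance_exact(probe_complex):
    prot = probe_complex.select(kind="protein")
    dna = probe_complex.select(kind="dna")
    gly = [r for c in prot.chains for r in c.residues if r.name == "GLY"][0]
    dmin = min(np.linalg.norm(a.position - b.position)
               for a in gly.atoms for _, _, b in dna.iter_atoms())
    assert dmin == pytest.approx(3.2, abs=0.05)


def test_infeasible_probe_distance_raises(hmpa1_duplex):
    with pytest.raises(ValueError):
        hx.make_probe_complex(hmpa1_duplex, [("ARG-like", 0, "minor", 0.05)])
    with pytest.raises(ValueError):
        hx.make_probe_complex(hmpa1_duplex, [("point-atom", 0, "minor", -1.0)])
    with pytest.raises(IndexError):
        hx.make_probe_complex(hmpa1_duplex, [("point-atom", 40, "minor", 3.0)])
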
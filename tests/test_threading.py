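"""Base threading on a fixed backbone and steric clash scanning."""

import numpy as np
import pytest

import helixread as hx
from helixread.bases import ideal_base_geometry
from helixread.dna import nucleotides_of
from helixread.synthetic import BACKBONE_ORDER
from helixread.threading import clash_scan, summarize_clashes, thread_operator_sequence


def backbone_coords(model):
    keep = set(BACKBONE_ORDER)
    return {(c.cid, r.number, a.name): a.position.copy()
            for c, r, a in model.iter_atoms() if a.name in keep}


def test_ideal_geometry_atom_sets():
    t = ideal_base_geometry("T")
    assert "C7" in t                       # thymine methyl carbon
    a = ideal_base_geometry("A")
    assert len(a) == 10                    # purine ring + N6
    with pytest.raises(ValueError):
        ideal_base_geometry("U")


def test_ideal_geometry_ring_bonds_standard():
    ring_bonds = {"A": [("N9", "C8"), ("C8", "N7"), ("N1", "C2")],
                  "T": [("N1", "C2"), ("C2", "N3"), ("C5", "C7")]}
    for base, bonds in ring_bonds.items():
        g = ideal_base_geometry(base)
        for p, q in bonds:
            d = np.linalg.norm(g[p] - g[q])
            assert 1.28 < d < 1.52


def test_identity_threading_keeps_bases_and_contacts(probe_complex, hmpa1_numbering):
    prot = probe_complex.select(kind="protein")
    seq = "AACACGAATATCATCTACCAATT"
    subs = {i - 11: b for i, b in enumerate(seq)}   # thread the native sequence
    thr = thread_operator_sequence(probe_complex, hmpa1_numbering, subs)
    assert thr.replaced == []                        # nothing actually changes
    assert np.array_equal(thr.model.coords(), probe_complex.coords())
    before = hx.classify_and_summarize(hx.enumerate_contacts(
        prot, probe_complex.select(kind="dna")))
    after = hx.classify_and_summarize(hx.enumerate_contacts(
        prot, thr.model.select(kind="dna")))
    key = lambda s: sorted((c.protein_atom, c.dna_atom, c.contact_class)
                           for c in s.contacts)
    assert key(before) == key(after)


def test_substitution_gains_thymine_methyl(hmpa1_duplex, hmpa1_numbering):
    # operator index +6 on strand c is a C in the native sequence
    thr = thread_operator_sequence(hmpa1_duplex, hmpa1_numbering, {6: "T"})
    assert (6, "c", "C", "T") in thr.replaced
    assert (6, "d", "G", "A") in thr.replaced
    nucs = {(n.chain_id, n.residue.number): n for n in nucleotides_of(thr.model)}
    cid, num = hmpa1_numbering.residue_of(6, "c")
    new_t = nucs[(cid, num)]
    assert new_t.letter == "T" and new_t.residue.atom("C7") is not None
    assert new_t.residue.name == "DT"


def test_backbone_bitwise_identical_after_threading(hmpa1_duplex, hmpa1_numbering):
    thr = thread_operator_sequence(hmpa1_duplex, hmpa1_numbering,
                                   {0: "G", 4: "C", -8: "T"})
    before = backbone_coords(hmpa1_duplex)
    after = backbone_coords(thr.model)
    assert before.keys() == after.keys()
    assert all(np.array_equal(before[k], after[k]) for k in before)


def test_double_strand_complementarity_enforced(hmpa1_duplex, hmpa1_numbering):
    thr = thread_operator_sequence(hmpa1_duplex, hmpa1_numbering, {2: "G"})
    nucs = {(n.chain_id, n.residue.number): n for n in nucleotides_of(thr.model)}
    c = nucs[hmpa1_numbering.residue_of(2, "c")]
    d = nucs[hmpa1_numbering.residue_of(-2, "d")]
    assert (c.letter, d.letter) == ("G", "C")


def test_threaded_base_pairs_still_detected(hmpa1_duplex, hmpa1_numbering):
    thr = thread_operator_sequence(hmpa1_duplex, hmpa1_numbering,
                                   {i: "G" for i in (-4, 0, 5)})
    pairs = hx.detect_base_pairs(thr.model)
    assert len(pairs) == 23
    assert all(p.pair_type == "watson-crick" for p in pairs)


def test_invalid_inputs_rejected(hmpa1_duplex, hmpa1_numbering):
    with pytest.raises(ValueError):
        thread_operator_sequence(hmpa1_duplex, hmpa1_numbering, {0: "X"})
    with pytest.raises(KeyError):
        thread_operator_sequence(hmpa1_duplex, hmpa1_numbering, {40: "A"})


def test_probe_clash_detected_and_monotone(probe_complex, hmpa1_numbering):
    prot = probe_complex.select(kind="protein")
    thr = thread_operator_sequence(probe_complex, hmpa1_numbering, {})
    recs = clash_scan(thr, prot)
    rep = [r for r in recs if r.verdict == "repulsive"]
    assert len(rep) >= 1                       # the 2.5 Å minor-groove probe
    assert min(r.distance for r in rep) == pytest.approx(2.5, abs=0.05)
    # raising the cutoff never removes a repulsive record
    prev: set = set()
    for cutoff in (2.0, 2.5, 2.85, 3.2, 3.6):
        cur = {(r.dna_atom, r.protein_atom, r.operator_index)
               for r in clash_scan(thr, prot, repulsive_cutoff=cutoff)
               if r.verdict == "repulsive"}
        assert prev <= cur
        prev = cur


def test_native_fiber_complex_has_no_repulsive_contacts(hmpa1_duplex, hmpa1_numbering):
    gentle = hx.make_probe_complex(hmpa1_duplex, [("HIS-like", 2, "phosphate", 3.1)])
    prot = gentle.select(kind="protein")
    thr = thread_operator_sequence(gentle, hmpa1_numbering, {})
    recs = clash_scan(thr, prot)
    assert all(r.verdict == "attractive" for r in recs)


def test_summary_counts(probe_complex, hmpa1_numbering):
    prot = probe_complex.select(kind="protein")
    thr = thread_operator_sequence(probe_complex, hmpa1_numbering, {})
    summary = summarize_clashes(clash_scan(thr, prot), residue_of_interest="ARG")
    assert summary["n_repulsive"] >= 1
    assert summary["n_repulsive_ARG"] == summary["n_repulsive"]
    assert sum(summary["repulsive_by_residue"].values()) == summary["n_repulsive"]
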
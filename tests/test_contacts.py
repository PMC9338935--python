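"""Contact enumeration vs brute force, and distance-rule classification."""

import numpy as np
import pytest

import helixread as hx
from helixread.contacts import (Contact, classify_contact, enumerate_contacts,
                                moiety_of)
from helixread.model import Atom, Chain, Residue, StructureModel


def brute_force_pairs(protein, dna, cutoff):
    out = []
    for pc, pr, pa in protein.iter_atoms():
        for dc, dr, da in dna.iter_atoms():
            d = float(np.linalg.norm(pa.position - da.position))
            if d <= cutoff:
                out.append((pc.cid, pr.number, pa.name, dc.cid, dr.number, da.name, round(d, 9)))
    return sorted(out)


def _single_atom_model(name, element, pos, resname="ALA", cid="A"):
    return StructureModel([Chain(cid, [Residue(resname, 1, "", [Atom(name, element, pos)])])])


def test_two_atoms_at_three_angstroms():
    a = _single_atom_model("N", "N", [0, 0, 0])
    b = _single_atom_model("OP1", "O", [3.0, 0, 0], resname="DA", cid="B")
    contacts = enumerate_contacts(a, b)
    assert len(contacts) == 1
    assert contacts[0].distance == pytest.approx(3.0)


def test_enumeration_matches_bruteforce(probe_complex):
    prot = probe_complex.select(kind="protein")
    dna = probe_complex.select(kind="dna")
    got = sorted((c.protein_chain, c.protein_resnum, c.protein_atom,
                  c.dna_chain, c.dna_resnum, c.dna_atom, round(c.distance, 9))
                 for c in enumerate_contacts(prot, dna, cutoff=3.8))
    assert got == brute_force_pairs(prot, dna, 3.8)


def test_contact_counts_symmetric_under_argument_swap(probe_complex):
    prot = probe_complex.select(kind="protein")
    dna = probe_complex.select(kind="dna")
    assert len(enumerate_contacts(prot, dna)) == len(enumerate_contacts(dna, prot))


def test_empty_component_raises(probe_complex):
    prot = probe_complex.select(kind="protein")
    empty = StructureModel([Chain("Q", [])])
    with pytest.raises(ValueError):
        enumerate_contacts(prot, empty)


def _contact(presname, patom, datom, d):
    return Contact(protein_chain="A", protein_resname=presname, protein_resnum=1,
                   protein_atom=patom, main_chain=patom in {"N", "CA", "C", "O"},
                   dna_chain="C", dna_resname="DA", dna_resnum=5, dna_atom=datom,
                   moiety=moiety_of(datom), distance=d)


@pytest.mark.parametrize("presname,patom,datom,d,want,possible", [
    ("LYS", "N", "OP1", 2.9, "hbond", False),          # main-chain N H-bond
    ("HIS", "NE2", "OP2", 3.1, "salt_bridge", True),   # possible salt bridge
    ("ARG", "NH1", "OP1", 3.2, "salt_bridge", False),
    ("LYS", "NZ", "O3'", 3.0, "salt_bridge", False),
    ("ALA", "CB", "C1'", 3.5, "vdw", False),           # C...C vdW
    ("ALA", "CB", "C1'", 3.9, "none", False),          # beyond outer cutoff
    ("SER", "OG", "N3", 3.2, "hbond", False),          # base H-bond
    ("SER", "OG", "N3", 3.5, "vdw", False),            # N/O pair beyond 3.3
])
def test_classification_rules(presname, patom, datom, d, want, possible):
    c = classify_contact(_contact(presname, patom, datom, d))
    assert c.contact_class == want
    assert c.possible is possible


def test_class_hierarchy_nested_by_distance(probe_complex):
    prot = probe_complex.select(kind="protein")
    dna = probe_complex.select(kind="dna")
    summary = hx.classify_and_summarize(enumerate_contacts(prot, dna), protein=prot)
    for c in summary.contacts:
        if c.contact_class in ("hbond", "salt_bridge"):
            assert c.distance <= 3.3 < 3.8
        assert c.distance < 3.8


def test_main_chain_flag():
    c = classify_contact(_contact("LYS", "N", "OP1", 2.9))
    assert c.main_chain
    c2 = classify_contact(_contact("LYS", "NZ", "OP1", 2.9))
    assert not c2.main_chain


def test_moiety_partition():
    assert moiety_of("OP1") == "phosphate" and moiety_of("O5'") == "phosphate"
    assert moiety_of("C1'") == "sugar" and moiety_of("O4'") == "sugar"
    assert moiety_of("N3") == "base" and moiety_of("C7") == "base"


def test_summary_flags_missing_side_chain(probe_complex):
    prot = probe_complex.select(kind="protein")
    dna = probe_complex.select(kind="dna")
    summary = hx.classify_and_summarize(enumerate_contacts(prot, dna), protein=prot)
    # probe residues carry partial side chains by construction
    assert any(resname == "ARG" for _, resname, _ in summary.missing_side_chains)


def test_boundary_inclusive_exclusive():
    a = _single_atom_model("OG", "O", [0, 0, 0], resname="SER")
    b = _single_atom_model("N3", "N", [3.3, 0, 0], resname="DA", cid="B")
    c = enumerate_contacts(a, b, cutoff=3.8)[0]
    classify_contact(c)
    assert c.contact_class == "hbond"     # 3.3 inclusive
    b2 = _single_atom_model("N3", "N", [3.8, 0, 0], resname="DA", cid="B")
    c2 = enumerate_contacts(a, b2, cutoff=3.8)[0]
    classify_contact(c2)
    assert c2.contact_class == "none"     # 3.8 exclusive
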
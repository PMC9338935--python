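"""Protein-DNA atomic contact enumeration and classification.

Heavy-atom contacts are classified purely by distance and atom identity
(the crystallographic models carry no hydrogens, so no angular hydrogen-
bond criteria are applied):

* ``hbond`` — both atoms N or O at d <= 3.3 Å;
* ``salt_bridge`` — titratable side-chain nitrogen (Arg NH1/NH2/NE,
  Lys NZ, His ND1/NE2) against a phosphate oxygen (or the P atom as
  proxy) at d <= 3.3 Å; histidine pairs are "possible" salt bridges
  since the protonation state is unknown;
* ``vdw`` — any remaining heavy-atom pair below the outer cutoff
  (default d < 3.8 Å).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model import OperatorNumbering, StructureModel

__all__ = ["Contact", "ContactSummary", "enumerate_contacts", "classify_and_summarize",
           "HBOND_CUTOFF", "VDW_CUTOFF"]

HBOND_CUTOFF = 3.3   # Å, inclusive
VDW_CUTOFF = 3.8     # Å, exclusive

PHOSPHATE_ATOMS = {"P", "OP1", "OP2", "OP3", "O5'", "O3'"}
SUGAR_ATOMS = {"C1'", "C2'", "C3'", "C4'", "C5'", "O4'"}
MAIN_CHAIN = {"N", "CA", "C", "O", "OXT"}
TITRATABLE_N = {("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"),
                ("LYS", "NZ"), ("HIS", "ND1"), ("HIS", "NE2")}
PHOSPHATE_O = {"OP1", "OP2", "OP3", "O5'", "O3'", "P"}

# expected side-chain heavy atoms, for flagging disordered interface residues
SIDE_CHAIN_ATOMS: Dict[str, set] = {
    "ALA": {"CB"},
    "ARG": {"CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"},
    "ASN": {"CB", "CG", "OD1", "ND2"},
    "ASP": {"CB", "CG", "OD1", "OD2"},
    "CYS": {"CB", "SG"},
    "GLN": {"CB", "CG", "CD", "OE1", "NE2"},
    "GLU": {"CB", "CG", "CD", "OE1", "OE2"},
    "GLY": set(),
    "HIS": {"CB", "CG", "ND1", "CD2", "CE1", "NE2"},
    "ILE": {"CB", "CG1", "CG2", "CD1"},
    "LEU": {"CB", "CG", "CD1", "CD2"},
    "LYS": {"CB", "CG", "CD", "CE", "NZ"},
    "MET": {"CB", "CG", "SD", "CE"},
    "PHE": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "PRO": {"CB", "CG", "CD"},
    "SER": {"CB", "OG"},
    "THR": {"CB", "OG1", "CG2"},
    "TRP": {"CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "TYR": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"},
    "VAL": {"CB", "CG1", "CG2"},
}


def moiety_of(atom_name: str) -> str:
    if atom_name in PHOSPHATE_ATOMS:
        return "phosphate"
    if atom_name in SUGAR_ATOMS:
        return "sugar"
    return "base"


@dataclass
class Contact:
    protein_chain: str
    protein_resname: str
    protein_resnum: int
    protein_atom: str
    main_chain: bool
    dna_chain: str
    dna_resname: str
    dna_resnum: int
    dna_atom: str
    moiety: str
    distance: float
    contact_class: str = "none"
    possible: bool = False            # "possible salt bridge" qualifier (His)
    operator_index: Optional[int] = None
    strand: Optional[str] = None


@dataclass
class ContactSummary:
    contacts: List[Contact]
    per_residue: pd.DataFrame
    per_nucleotide: pd.DataFrame
    missing_side_chains: List[Tuple[str, str, int]]


def enumerate_contacts(protein: StructureModel, dna: StructureModel,
                       cutoff: float = VDW_CUTOFF,
                       numbering: Optional[OperatorNumbering] = None,
                       inclusive: bool = True) -> List[Contact]:
    """All inter-component heavy-atom pairs within ``cutoff`` Å.

    Hydrogens (if any survived parsing) are excluded.  Contacts are
    annotated with the DNA moiety and, when an operator numbering is
    supplied, the operator index and strand of the nucleotide.  The
    boundary is inclusive by default (``d <= cutoff``).
    """
    prot_atoms = [(c, r, a) for c, r, a in protein.iter_atoms() if a.element != "H"]
    dna_atoms = [(c, r, a) for c, r, a in dna.iter_atoms() if a.element != "H"]
    if not prot_atoms or not dna_atoms:
        raise ValueError("both components must contain heavy atoms")
    tree = cKDTree(np.array([a.position for _, _, a in dna_atoms]))
    out: List[Contact] = []
    for pc, pr, pa in prot_atoms:
        for j in tree.query_ball_point(pa.position, cutoff):
            dc, dr, da = dna_atoms[j]
            d = float(np.linalg.norm(pa.position - da.position))
            if d > cutoff or (not inclusive and d == cutoff):
                continue
            op_idx = strand = None
            if numbering is not None:
                try:
                    op_idx, strand = numbering.index_of(dc.cid, dr.number)
                except KeyError:
                    pass
            out.append(Contact(
                protein_chain=pc.cid, protein_resname=pr.name, protein_resnum=pr.number,
                protein_atom=pa.name, main_chain=pa.name in MAIN_CHAIN,
                dna_chain=dc.cid, dna_resname=dr.name, dna_resnum=dr.number,
                dna_atom=da.name, moiety=moiety_of(da.name), distance=d,
                operator_index=op_idx, strand=strand))
    out.sort(key=lambda c: (c.protein_chain, c.protein_resnum, c.dna_chain,
                            c.dna_resnum, c.distance))
    return out


def classify_contact(c: Contact, hbond_cutoff: float = HBOND_CUTOFF,
                     vdw_cutoff: float = VDW_CUTOFF) -> Contact:
    pe, de = c.protein_atom[0], c.dna_atom[0]
    c.contact_class = "none"
    c.possible = False
    if c.distance < vdw_cutoff:
        c.contact_class = "vdw"
    if c.distance <= hbond_cutoff:
        if (c.protein_resname, c.protein_atom) in TITRATABLE_N and c.dna_atom in PHOSPHATE_O:
            c.contact_class = "salt_bridge"
            c.possible = c.protein_resname == "HIS"
        elif pe in "NO" and de in "NO":
            c.contact_class = "hbond"
    return c


def classify_and_summarize(contacts: List[Contact],
                           hbond_cutoff: float = HBOND_CUTOFF,
                           vdw_cutoff: float = VDW_CUTOFF,
                           protein: Optional[StructureModel] = None) -> ContactSummary:
    """Classify contacts in place and aggregate per residue / nucleotide.

    When the protein model is supplied, interface residues with missing
    side-chain atoms (disordered in the crystal) are listed rather than
    silently treated as absent.
    """
    for c in contacts:
        classify_contact(c, hbond_cutoff, vdw_cutoff)
    kept = [c for c in contacts if c.contact_class != "none"]
    df = pd.DataFrame([vars(c) for c in kept]) if kept else pd.DataFrame(
        columns=[f.name for f in Contact.__dataclass_fields__.values()])

    def agg(group_cols, moiety_cols):
        if df.empty:
            return pd.DataFrame()
        g = df.groupby(group_cols)
        tab = g.agg(n_contacts=("distance", "size"), min_distance=("distance", "min"))
        cls = df.pivot_table(index=group_cols, columns="contact_class",
                             values="distance", aggfunc="size", fill_value=0)
        moi = df.pivot_table(index=group_cols, columns="moiety",
                             values="distance", aggfunc="size", fill_value=0)
        return tab.join(cls, how="left").join(moi, how="left", rsuffix="_moiety").reset_index()

    per_res = agg(["protein_chain", "protein_resname", "protein_resnum"], True)
    per_nuc = agg(["dna_chain", "dna_resname", "dna_resnum"], True)

    missing: List[Tuple[str, str, int]] = []
    if protein is not None and kept:
        iface = {(c.protein_chain, c.protein_resname, c.protein_resnum) for c in kept}
        for cid, resname, num in sorted(iface):
            res = protein.chain(cid).residue(num)
            expected = SIDE_CHAIN_ATOMS.get(resname)
            if res is not None and expected:
                present = {a.name for a in res.atoms}
                if expected - present:
                    missing.append((cid, resname, num))
    return ContactSummary(contacts=kept, per_residue=per_res,
                          per_nucleotide=per_nuc, missing_side_chains=missing)
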
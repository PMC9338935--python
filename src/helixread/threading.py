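"""Operator threading: model a new base sequence on a fixed DNA backbone.

The procedure mirrors rigid in-silico mutagenesis: at each substituted
position the standard geometry of the new base is placed in the fitted
reference frame of the original base, leaving every backbone and sugar
atom (through C1') untouched.  Because standard reference frames of
ideally paired bases coincide (up to the pair dyad), this rule gives
the correct glycosidic geometry for purine<->pyrimidine swaps as well —
the new base is positioned as if forming an ideal Watson-Crick pair
with the partner strand.  No refinement or repacking follows: steric
verdicts are read straight off the modelled coordinates, with heavy-atom
pairs below 2.85 Å called repulsive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .bases import (BASE_ATOMS, COMPLEMENT, ideal_base_geometry, residue_name)
from .dna import Nucleotide, base_frame, detect_base_pairs, nucleotides_of
from .model import Atom, OperatorNumbering, StructureModel

__all__ = ["ThreadedModel", "ClashRecord", "thread_operator_sequence", "clash_scan",
           "REPULSIVE_CUTOFF", "ATTRACTIVE_WINDOW"]

REPULSIVE_CUTOFF = 2.85   # Å; heavy-atom pairs closer than this are repulsive
ATTRACTIVE_WINDOW = 4.0   # Å; contacts reported out to this distance


@dataclass
class ThreadedModel:
    model: StructureModel
    numbering: OperatorNumbering
    replaced: List[Tuple[int, str, str, str]]  # (operator index, strand, old, new)

    def replaced_positions(self) -> List[Tuple[int, str]]:
        return [(i, s) for i, s, _, _ in self.replaced]


@dataclass
class ClashRecord:
    operator_index: int
    strand: str
    dna_resname: str
    dna_atom: str
    protein_chain: str
    protein_resname: str
    protein_resnum: int
    protein_atom: str
    distance: float
    verdict: str               # attractive | repulsive
    modeled: bool              # atom belongs to a substituted base
    possible_hbond: bool = False   # N/O pair in the 2.6-2.85 Å range


def _rebuild_base(nuc: Nucleotide, new_letter: str) -> None:
    """Replace the base atoms of one nucleotide in place (backbone kept)."""
    origin, R, _ = base_frame(nuc)
    res = nuc.residue
    res.atoms = [a for a in res.atoms if a.name not in BASE_ATOMS[nuc.letter]
                 and a.name not in BASE_ATOMS[new_letter]]
    b_mean = float(np.mean([a.b_factor for a in res.atoms])) if res.atoms else 0.0
    for name, local in ideal_base_geometry(new_letter).items():
        res.atoms.append(Atom(name, name.strip("0123456789'")[0],
                              R @ local + origin, b_factor=b_mean))
    res.name = residue_name(new_letter)
    nuc.letter = new_letter


def thread_operator_sequence(template: StructureModel,
                             numbering: OperatorNumbering,
                             substitutions: Dict[int, str],
                             ) -> ThreadedModel:
    """Thread a new operator sequence onto the template backbone.

    ``substitutions`` maps operator indices to the new strand-c base;
    the complementary base is threaded at the paired strand-d position
    automatically, so double-strand consistency holds by construction.
    Entries equal to the current base are no-ops (recorded as kept).
    Raises on positions absent from the numbering or without a fittable
    base frame.
    """
    out = template.copy()
    nucs = {(n.chain_id, n.residue.number): n for n in nucleotides_of(out)}
    replaced: List[Tuple[int, str, str, str]] = []
    for op_idx, new_c in sorted(substitutions.items()):
        new_c = new_c.upper()
        if new_c not in COMPLEMENT:
            raise ValueError(f"invalid base {new_c!r} at operator index {op_idx}")
        for strand, letter in (("c", new_c), ("d", COMPLEMENT[new_c])):
            try:
                cid, num = numbering.residue_of(op_idx if strand == "c" else -op_idx, strand)
            except KeyError as exc:
                raise KeyError(f"operator index {op_idx}{strand} not in template") from exc
            nuc = nucs[(cid, num)]
            old = nuc.letter
            if old != letter:
                _rebuild_base(nuc, letter)
                replaced.append((op_idx, strand, old, letter))
    return ThreadedModel(out, numbering, replaced)


def clash_scan(threaded: ThreadedModel, protein: StructureModel,
               attractive_window: float = ATTRACTIVE_WINDOW,
               repulsive_cutoff: float = REPULSIVE_CUTOFF,
               modeled_only: bool = False) -> List[ClashRecord]:
    """Scan base atoms against protein heavy atoms.

    For every base atom of the threaded duplex (optionally restricted to
    substituted positions), protein heavy atoms within the attractive
    window are reported; a record is ``repulsive`` iff its distance is
    below the repulsive cutoff.  N/O pairs between 2.6 Å and the cutoff
    are additionally flagged as possible hydrogen bonds rather than
    certain clashes.
    """
    prot_atoms = [(c, r, a) for c, r, a in protein.iter_atoms() if a.element != "H"]
    if not prot_atoms:
        raise ValueError("protein component is empty")
    tree = cKDTree(np.array([a.position for _, _, a in prot_atoms]))
    modeled = set(threaded.replaced_positions())
    records: List[ClashRecord] = []
    for nuc in nucleotides_of(threaded.model):
        try:
            op_idx, strand = threaded.numbering.index_of(nuc.chain_id, nuc.residue.number)
        except KeyError:
            continue
        is_modeled = (op_idx, strand) in modeled
        if modeled_only and not is_modeled:
            continue
        for a in nuc.residue.atoms:
            if a.name not in BASE_ATOMS[nuc.letter]:
                continue
            for j in tree.query_ball_point(a.position, attractive_window):
                pc, pr, pa = prot_atoms[j]
                d = float(np.linalg.norm(a.position - pa.position))
                if d > attractive_window:
                    continue
                rep = d < repulsive_cutoff
                records.append(ClashRecord(
                    operator_index=op_idx, strand=strand, dna_resname=nuc.residue.name,
                    dna_atom=a.name, protein_chain=pc.cid, protein_resname=pr.name,
                    protein_resnum=pr.number, protein_atom=pa.name, distance=d,
                    verdict="repulsive" if rep else "attractive", modeled=is_modeled,
                    possible_hbond=(rep and d >= 2.6 and a.name[0] in "NO"
                                    and pa.name[0] in "NO")))
    records.sort(key=lambda r: (r.operator_index, r.strand, r.distance))
    return records


def summarize_clashes(records: Sequence[ClashRecord],
                      residue_of_interest: Optional[str] = None) -> dict:
    """Per-candidate summary: repulsive counts, optionally restricted to a
    named protein residue (e.g. the minor-groove arginine)."""
    rep = [r for r in records if r.verdict == "repulsive"]
    out = {
        "n_records": len(records),
        "n_repulsive": len(rep),
        "repulsive": [vars(r) for r in rep],
    }
    if residue_of_interest:
        out[f"n_repulsive_{residue_of_interest}"] = sum(
            1 for r in rep if r.protein_resname == residue_of_interest)
    per_res: Dict[str, int] = {}
    for r in rep:
        key = f"{r.protein_resname}{r.protein_resnum}{r.protein_chain}"
        per_res[key] = per_res.get(key, 0) + 1
    out["repulsive_by_residue"] = per_res
    return out


def clash_table(records: Sequence[ClashRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])
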
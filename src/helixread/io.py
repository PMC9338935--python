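"""Reading and writing macromolecular structures (PDB / mmCIF via gemmi).

Parsing policy, chosen for deterministic single-conformer geometry:

* hydrogens are dropped (all downstream analysis is heavy-atom only);
* for alternate conformations the highest-occupancy altloc is kept,
  ties broken by altloc letter ascending; dropped conformers are
  counted on the returned model (``model.dropped_altlocs``);
* elements missing from the file are inferred from the atom name.
"""

from __future__ import annotations

import os
import urllib.request
from typing import Dict, Optional, Tuple

import gemmi

from .dna import detect_base_pairs, nucleotides_of
from .model import Atom, Chain, OperatorNumbering, Residue, StructureModel

__all__ = ["parse_structure", "write_structure", "fetch_structure",
           "assign_operator_numbering", "ParseError"]


class ParseError(ValueError):
    pass


def _infer_element(name: str, resname: str) -> str:
    stripped = name.strip("0123456789'*")
    if not stripped:
        raise ParseError(f"cannot infer element for atom {name!r} in {resname}")
    if len(stripped) >= 2 and stripped[:2].upper() in ("FE", "MG", "ZN", "CL", "BR", "NA"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


def parse_structure(path: str, fmt: str = "auto") -> StructureModel:
    """Parse a PDB or mmCIF file into a :class:`StructureModel`.

    ``fmt`` is one of ``pdb``, ``mmcif`` or ``auto`` (by extension /
    content sniffing).  Only the first model of multi-model files is
    read.  Unreadable input raises :class:`ParseError` naming the file
    and underlying record error.
    """
    if fmt not in ("pdb", "mmcif", "auto"):
        raise ValueError(f"unknown format {fmt!r}; expected pdb, mmcif or auto")
    if not os.path.exists(path):
        raise ParseError(f"no such file: {path}")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(path)
        elif fmt == "mmcif":
            st = gemmi.read_structure(path, format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(path)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"failed to parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: no models found")
    st.setup_entities()
    model = st[0]
    out = StructureModel([], source=st.name or os.path.basename(path), title=st.name)
    dropped = 0
    for ch in model:
        chain = Chain(ch.name, [])
        for res in ch:
            picked: Dict[str, gemmi.Atom] = {}
            for at in res:
                if at.is_hydrogen():
                    continue
                prev = picked.get(at.name)
                if prev is None:
                    picked[at.name] = at
                else:
                    dropped += 1
                    if (at.occ, -ord(at.altloc or "~")) > (prev.occ, -ord(prev.altloc or "~")):
                        picked[at.name] = at
            atoms = []
            for at in picked.values():
                el = at.element.name if at.element and at.element.name != "X" else ""
                if not el or el == "D":
                    el = _infer_element(at.name, res.name)
                atoms.append(Atom(at.name, el, [at.pos.x, at.pos.y, at.pos.z],
                                  b_factor=at.b_iso, occupancy=min(at.occ, 1.0),
                                  alt_loc=(at.altloc or "")))
            if atoms:
                chain.residues.append(Residue(res.name, res.seqid.num,
                                              res.seqid.icode.strip(), atoms))
        if chain.residues:
            out.chains.append(chain)
    out.validate()
    out.dropped_altlocs = dropped
    return out


def write_structure(model: StructureModel, path: str) -> None:
    """Write a model as PDB (coordinates at the format's 1e-3 Å precision)."""
    st = gemmi.Structure()
    st.name = model.source or "helixread"
    gm = gemmi.Model("1")
    for chain in model.chains:
        gc = gemmi.Chain(chain.cid)
        for res in chain.residues:
            gr = gemmi.Residue()
            gr.name = res.name
            gr.seqid = gemmi.SeqId(res.number, res.icode or " ")
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.position)
                ga.b_iso = a.b_factor
                ga.occ = a.occupancy
                if a.alt_loc:
                    ga.altloc = a.alt_loc
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    doc = st.make_pdb_string()
    with open(path, "w") as fh:
        fh.write(doc)


def fetch_structure(accession: str, directory: str = ".",
                    fmt: str = "mmcif", timeout: float = 30.0) -> str:
    """Download a deposited entry from the PDB archive (optional helper).

    Returns the local file path.  Requires network access; everything
    else in the package runs without it.
    """
    acc = accession.upper()
    ext = "cif" if fmt == "mmcif" else "pdb"
    url = f"https://files.rcsb.org/download/{acc}.{ext}"
    os.makedirs(directory, exist_ok=True)
    dest = os.path.join(directory, f"{acc}.{ext}")
    if not os.path.exists(dest):
        with urllib.request.urlopen(url, timeout=timeout) as resp, open(dest, "wb") as fh:
            fh.write(resp.read())
    return dest


def assign_operator_numbering(model: StructureModel,
                              center: Tuple[str, int],
                              strand_labels: Optional[Dict[str, str]] = None,
                              ) -> OperatorNumbering:
    """Signed operator indices centred on a chosen nucleotide.

    ``center`` names the (chain, author residue number) of the
    nucleotide given index 0; its chain becomes strand ``c`` with
    indices increasing 5'->3' in chain order.  Strand-d nucleotides take
    the negated index of their Watson-Crick partner (detected
    geometrically); unpaired strand-d overhangs continue by backbone
    adjacency.  ``strand_labels`` may override the chain -> c/d naming.
    """
    cid, num = center
    chain = model.chain(cid)
    positions = [r.number for r in chain.residues if r.kind == "dna"]
    if num not in positions:
        raise TypeError(f"center residue {cid}:{num} is not a nucleotide")
    center_pos = positions.index(num)
    mapping: Dict[Tuple[str, int], Tuple[int, str]] = {}
    for k, resnum in enumerate(positions):
        mapping[(cid, resnum)] = (k - center_pos, "c")

    pairs = detect_base_pairs(model)
    d_assigned: Dict[str, Dict[int, int]] = {}
    for bp in pairs:
        a, b = bp.c, bp.d
        if b.chain_id == cid and a.chain_id != cid:
            a, b = b, a
        if a.chain_id != cid or b.chain_id == cid:
            continue
        idx = mapping.get((cid, a.residue.number))
        if idx is None:
            continue
        mapping[(b.chain_id, b.residue.number)] = (-idx[0], "d")
        d_assigned.setdefault(b.chain_id, {})[b.residue.number] = -idx[0]

    # backbone continuation for unpaired strand-d overhangs
    for dcid, assigned in d_assigned.items():
        dchain = model.chain(dcid)
        dpos = [r.number for r in dchain.residues if r.kind == "dna"]
        known = sorted((dpos.index(n), i) for n, i in assigned.items())
        if not known:
            continue
        first_k, first_i = known[0]
        last_k, last_i = known[-1]
        for k, resnum in enumerate(dpos):
            if (dcid, resnum) in mapping:
                continue
            if k < first_k:
                mapping[(dcid, resnum)] = (first_i - (first_k - k), "d")
            elif k > last_k:
                mapping[(dcid, resnum)] = (last_i + (k - last_k), "d")
    if strand_labels:
        mapping = {key: (idx, strand_labels.get(key[0], s)) for key, (idx, s) in mapping.items()}
    return OperatorNumbering(mapping)
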
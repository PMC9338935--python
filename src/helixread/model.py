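"""Hierarchical structure container and component selection.

The container is deliberately plain: chains -> residues -> atoms, with
numpy views for geometry work.  It is populated from PDB/mmCIF files by
:mod:`helixread.io` or built directly by the synthetic generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "OperatorNumbering",
    "EmptySelectionError",
    "AMINO_ACIDS",
    "DNA_RESIDUES",
    "WATER_RESIDUES",
]

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}
DNA_RESIDUES = {"DA", "DC", "DG", "DT", "DI", "DU"}
WATER_RESIDUES = {"HOH", "WAT", "DOD"}

# Bondi-type van der Waals radii (Å) used for SASA and steric work.
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "S": 1.80,
    "H": 1.20, "FE": 1.40, "MG": 1.73, "ZN": 1.39, "CA": 2.31,
    "NA": 2.27, "K": 2.75, "CL": 1.75, "F": 1.47, "BR": 1.85, "I": 1.98,
}


class EmptySelectionError(ValueError):
    """Raised when a selection matches no atoms (never silently empty)."""


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray  # (3,) Å
    b_factor: float = 0.0
    occupancy: float = 1.0
    alt_loc: str = ""

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")
        if not self.element:
            raise ValueError(f"atom {self.name}: element must be non-empty")

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.position.copy(),
                    self.b_factor, self.occupancy, self.alt_loc)


@dataclass
class Residue:
    name: str
    number: int              # author residue number
    icode: str = ""
    atoms: List[Atom] = field(default_factory=list)

    @property
    def kind(self) -> str:
        """Polymer classification: protein | dna | water | hetero."""
        if self.name in AMINO_ACIDS:
            return "protein"
        if self.name in DNA_RESIDUES:
            return "dna"
        if self.name in WATER_RESIDUES:
            return "water"
        return "hetero"

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def copy(self) -> "Residue":
        return Residue(self.name, self.number, self.icode,
                       [a.copy() for a in self.atoms])


@dataclass
class Chain:
    cid: str
    residues: List[Residue] = field(default_factory=list)

    def residue(self, number: int, icode: str = "") -> Optional[Residue]:
        for r in self.residues:
            if r.number == number and r.icode == icode:
                return r
        return None

    def copy(self) -> "Chain":
        return Chain(self.cid, [r.copy() for r in self.residues])


@dataclass
class StructureModel:
    chains: List[Chain] = field(default_factory=list)
    source: str = ""
    title: str = ""

    # ------------------------------------------------------------------ basic
    def chain(self, cid: str) -> Chain:
        for c in self.chains:
            if c.cid == cid:
                return c
        raise KeyError(f"no chain {cid!r} in model {self.source!r}")

    def iter_residues(self) -> Iterator[Tuple[Chain, Residue]]:
        for c in self.chains:
            for r in c.residues:
                yield c, r

    def iter_atoms(self) -> Iterator[Tuple[Chain, Residue, Atom]]:
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    yield c, r, a

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    def coords(self) -> np.ndarray:
        return np.array([a.position for _, _, a in self.iter_atoms()])

    def copy(self) -> "StructureModel":
        return StructureModel([c.copy() for c in self.chains], self.source, self.title)

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "StructureModel":
        """Rigid-body copy: positions -> R @ x + t."""
        out = self.copy()
        R = np.asarray(R, float)
        t = np.asarray(t, float)
        for _, _, a in out.iter_atoms():
            a.position = R @ a.position + t
        return out

    def validate(self) -> None:
        seen_chain = set()
        for c in self.chains:
            if c.cid in seen_chain:
                raise ValueError(f"duplicate chain id {c.cid!r}")
            seen_chain.add(c.cid)
            seen_key = set()
            for r in c.residues:
                for a in r.atoms:
                    key = (c.cid, r.number, r.icode, a.name, a.alt_loc)
                    if key in seen_key:
                        raise ValueError(f"duplicate atom key {key}")
                    seen_key.add(key)

    # -------------------------------------------------------------- selection
    def select(
        self,
        kind: Optional[str] = None,
        chains: Optional[Sequence[str]] = None,
        residue_range: Optional[Tuple[int, int]] = None,
        include_waters: bool = False,
        allow_empty: bool = False,
    ) -> "StructureModel":
        """Sub-model by polymer kind, chain ids and/or residue number range.

        ``kind`` is one of ``protein``, ``dna``, ``hetero``, ``water`` or
        ``None`` (all kinds).  Hetero groups (e.g. iron-sulfur clusters)
        are retained under ``hetero``; waters are excluded unless asked
        for.  Ordering and metadata are preserved.
        """
        if kind is not None and kind not in {"protein", "dna", "hetero", "water", "all"}:
            raise ValueError(f"unknown selector kind {kind!r}")
        if chains is not None:
            known = {c.cid for c in self.chains}
            missing = [cid for cid in chains if cid not in known]
            if missing:
                raise KeyError(f"selector references absent chains {missing}")
        out = StructureModel([], self.source, self.title)
        for c in self.chains:
            if chains is not None and c.cid not in chains:
                continue
            newc = Chain(c.cid, [])
            for r in c.residues:
                if kind not in (None, "all") and r.kind != kind:
                    continue
                if r.kind == "water" and not include_waters and kind != "water":
                    continue
                if residue_range is not None and not (residue_range[0] <= r.number <= residue_range[1]):
                    continue
                newc.residues.append(r.copy())
            if newc.residues:
                out.chains.append(newc)
        if not out.chains and not allow_empty:
            raise EmptySelectionError(
                f"selection (kind={kind!r}, chains={chains!r}, range={residue_range!r}) "
                f"matched nothing in {self.source!r}"
            )
        return out


@dataclass
class OperatorNumbering:
    """Map (chain id, author residue number) -> (operator index, strand label).

    Operator indices are signed integers centred on the middle base pair
    (index 0); the reference strand is labelled ``c`` and its complement
    ``d``.  On strand d each nucleotide carries the negated index of its
    Watson-Crick partner, which reduces to index negation only for a
    perfect palindrome.
    """

    mapping: Dict[Tuple[str, int], Tuple[int, str]] = field(default_factory=dict)

    def index_of(self, cid: str, number: int) -> Tuple[int, str]:
        return self.mapping[(cid, number)]

    def residue_of(self, index: int, strand: str) -> Tuple[str, int]:
        for (cid, num), (idx, s) in self.mapping.items():
            if idx == index and s == strand:
                return cid, num
        raise KeyError(f"no nucleotide at operator index {index}{strand}")

    def shifted(self, k: int) -> "OperatorNumbering":
        """Re-centre: moving the centre by +k shifts strand-c indices by -k
        (and strand-d indices by +k, since they are negated)."""
        out = {}
        for key, (idx, s) in self.mapping.items():
            out[key] = (idx - k if s == "c" else idx + k, s)
        return OperatorNumbering(out)
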
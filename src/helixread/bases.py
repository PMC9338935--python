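"""Idealized nucleobase geometry in the standard reference frame.

Heavy-atom coordinates of the four DNA bases expressed in the standard
(Tsukuba-convention) base reference frame: the x-axis points from the
minor- to the major-groove edge along the pseudo-dyad, the y-axis runs
along the C1'...C1' direction toward strand I, and z completes a
right-handed set, so that an ideal Watson-Crick partner is obtained by a
180 deg rotation about x (``PAIR_FLIP``).  All analysis that needs a base
frame (frame fitting, pair/step parameters, threading) is anchored to
this one embedded geometry.
"""

from __future__ import annotations

from typing import Dict

import numpy as np

__all__ = [
    "STANDARD_BASES",
    "RING_ATOMS",
    "BASE_ATOMS",
    "C1P_POSITION",
    "PAIR_FLIP",
    "COMPLEMENT",
    "PURINES",
    "PYRIMIDINES",
    "ideal_base_geometry",
    "complement_sequence",
    "base_letter",
    "residue_name",
]

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

# 180 deg rotation about the standard x-axis: maps a base frame onto the
# frame of its ideal Watson-Crick partner.
PAIR_FLIP = np.diag([1.0, -1.0, -1.0])

# Standard-frame heavy-atom coordinates (Å).  C1' is included to anchor
# the glycosidic bond; it belongs to the sugar, not the base proper.
STANDARD_BASES: Dict[str, Dict[str, np.ndarray]] = {
    "A": {
        "C1'": (-2.479, 5.346, 0.000),
        "N9": (-1.291, 4.498, 0.000),
        "C8": (0.024, 4.897, 0.000),
        "N7": (0.877, 3.902, 0.000),
        "C5": (0.071, 2.771, 0.000),
        "C6": (0.369, 1.398, 0.000),
        "N6": (1.611, 0.909, 0.000),
        "N1": (-0.668, 0.532, 0.000),
        "C2": (-1.912, 1.023, 0.000),
        "N3": (-2.320, 2.290, 0.000),
        "C4": (-1.267, 3.124, 0.000),
    },
    "G": {
        "C1'": (-2.477, 5.399, 0.000),
        "N9": (-1.289, 4.551, 0.000),
        "C8": (0.023, 4.962, 0.000),
        "N7": (0.870, 3.969, 0.000),
        "C5": (0.071, 2.833, 0.000),
        "C6": (0.424, 1.460, 0.000),
        "O6": (1.554, 0.955, 0.000),
        "N1": (-0.700, 0.641, 0.000),
        "C2": (-1.999, 1.087, 0.000),
        "N2": (-2.949, 0.139, -0.001),
        "N3": (-2.342, 2.364, 0.001),
        "C4": (-1.265, 3.177, 0.000),
    },
    "C": {
        "C1'": (-2.477, 5.402, 0.000),
        "N1": (-1.285, 4.542, 0.000),
        "C2": (-1.472, 3.158, 0.000),
        "O2": (-2.628, 2.709, 0.001),
        "N3": (-0.391, 2.344, 0.000),
        "C4": (0.837, 2.868, 0.000),
        "N4": (1.875, 2.027, 0.001),
        "C5": (1.056, 4.275, 0.000),
        "C6": (-0.023, 5.068, 0.000),
    },
    "T": {
        "C1'": (-2.481, 5.354, 0.000),
        "N1": (-1.284, 4.500, 0.000),
        "C2": (-1.462, 3.135, 0.000),
        "O2": (-2.562, 2.608, 0.000),
        "N3": (-0.298, 2.407, 0.000),
        "C4": (0.994, 2.897, 0.000),
        "O4": (1.944, 2.119, 0.000),
        "C5": (1.106, 4.338, 0.000),
        "C7": (2.466, 4.961, 0.001),
        "C6": (-0.024, 5.057, 0.000),
    },
}
STANDARD_BASES = {
    b: {name: np.asarray(xyz, dtype=float) for name, xyz in atoms.items()}
    for b, atoms in STANDARD_BASES.items()
}

# Ring atoms used for frame fitting (planar, well-ordered).
RING_ATOMS = {
    "A": ["N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"],
    "G": ["N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"],
    "C": ["N1", "C2", "N3", "C4", "C5", "C6"],
    "T": ["N1", "C2", "N3", "C4", "C5", "C6"],
}

# All heavy atoms belonging to the base moiety (excludes C1').
BASE_ATOMS = {b: [n for n in atoms if n != "C1'"] for b, atoms in STANDARD_BASES.items()}

C1P_POSITION = {b: STANDARD_BASES[b]["C1'"] for b in STANDARD_BASES}

_RESNAME = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}
_LETTER = {v: k for k, v in _RESNAME.items()}


def residue_name(letter: str) -> str:
    """One-letter base -> PDB residue name (A -> DA)."""
    try:
        return _RESNAME[letter.upper()]
    except KeyError:
        raise ValueError(f"unknown base {letter!r}") from None


def base_letter(resname: str) -> str:
    """PDB residue name -> one-letter base (DA -> A)."""
    try:
        return _LETTER[resname.upper()]
    except KeyError:
        raise ValueError(f"not a standard DNA residue: {resname!r}") from None


def ideal_base_geometry(base: str) -> Dict[str, np.ndarray]:
    """Standard heavy-atom coordinates of one base in its reference frame.

    Includes the glycosidic nitrogen (N9 for purines, N1 for
    pyrimidines) and, for thymine, the C7 methyl carbon.  Raises
    ``ValueError`` for anything outside the ACGT alphabet.
    """
    b = base.upper()
    if b not in STANDARD_BASES:
        raise ValueError(f"unknown base {base!r}; expected one of A, C, G, T")
    return {name: xyz.copy() for name, xyz in STANDARD_BASES[b].items() if name != "C1'"}


def complement_sequence(seq: str) -> str:
    """Reverse complement of a sequence over ACGT (5'->3' in, 5'->3' out)."""
    try:
        return "".join(COMPLEMENT[c] for c in reversed(seq.upper()))
    except KeyError:
        bad = next(i for i, c in enumerate(seq.upper()) if c not in COMPLEMENT)
        raise ValueError(f"invalid base {seq[bad]!r} at position {bad}") from None
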
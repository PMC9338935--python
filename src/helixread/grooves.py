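"""Minor/major-groove width profiles from cross-strand phosphate distances.

Groove widths are measured as raw phosphorus-to-phosphorus distances
(no phosphate-radius subtraction): for each phosphate the minimum
distance to opposite-strand phosphates within a window of base-pair
offsets along the duplex alignment.  The window brackets the canonical
cross-groove register (about 3 bp for the minor groove); on the
complementary strand the window sign mirrors under the duplex dyad.
The deviation from the 11.7 Å regular-B-DNA minor-groove average is
reported as a delta profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dna import BasePair, detect_base_pairs
from .model import StructureModel, OperatorNumbering

__all__ = ["GrooveEntry", "GrooveProfile", "groove_profile", "delta_pp_profile",
           "BDNA_MINOR_REFERENCE"]

#: Average minimal minor-groove P-P distance in regular B-DNA (Å).
BDNA_MINOR_REFERENCE = 11.7

MINOR_WINDOW = (-5, -2)
MAJOR_WINDOW = (2, 7)


@dataclass
class GrooveEntry:
    chain: str
    number: int
    aligned: int                 # operator index (or pair rank) of this nucleotide
    strand: str                  # "c" | "d"
    d_minor: Optional[float] = None
    partner_minor: Optional[Tuple[str, int]] = None
    minor_edge: bool = False
    d_major: Optional[float] = None
    partner_major: Optional[Tuple[str, int]] = None
    major_edge: bool = False
    delta_minor: Optional[float] = None


@dataclass
class GrooveProfile:
    entries: List[GrooveEntry]
    reference: float = BDNA_MINOR_REFERENCE
    skipped: List[Tuple[str, int, str]] = field(default_factory=list)

    def mean_minor(self, interior_only: bool = True) -> float:
        vals = [e.d_minor for e in self.entries
                if e.d_minor is not None and not (interior_only and e.minor_edge)]
        if not vals:
            raise ValueError("no minor-groove distances available")
        return float(np.mean(vals))

    def min_minor(self):
        """Smallest minor-groove distance and its entry."""
        best = min((e for e in self.entries if e.d_minor is not None),
                   key=lambda e: e.d_minor)
        return best.d_minor, best

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.entries])


def groove_profile(model: StructureModel,
                   pairs: Optional[Sequence[BasePair]] = None,
                   numbering: Optional[OperatorNumbering] = None,
                   minor_window: Tuple[int, int] = MINOR_WINDOW,
                   major_window: Tuple[int, int] = MAJOR_WINDOW,
                   reference: float = BDNA_MINOR_REFERENCE) -> GrooveProfile:
    """Per-phosphate minimal cross-strand P-to-P distances.

    The duplex alignment comes from detected base pairs (supplied or
    detected here); each paired nucleotide gets an aligned coordinate —
    the operator index of its strand-c partner when ``numbering`` is
    given, its pair rank otherwise.  For a strand-c phosphate at aligned
    position i the minor-groove distance is the minimum |P_i - P_j| over
    strand-d phosphates with aligned offset j - i inside
    ``minor_window``; strand-d phosphates use the mirrored window.
    Positions whose window extends beyond the duplex are flagged as edge
    values; nucleotides without a phosphate (5' termini) are recorded in
    ``skipped``.
    """
    if pairs is None:
        pairs = detect_base_pairs(model)
    if len(pairs) < 6:
        raise ValueError(f"need a duplex of >= 6 bp; got {len(pairs)} pairs")

    def aligned_index(k: int) -> int:
        if numbering is None:
            return k
        nuc = pairs[k].c
        return numbering.index_of(nuc.chain_id, nuc.residue.number)[0]

    # collect phosphates: strand -> list of (aligned, chain, number, coords)
    phos: Dict[str, List[Tuple[int, str, int, np.ndarray]]] = {"c": [], "d": []}
    skipped = []
    for k, bp in enumerate(pairs):
        ai = aligned_index(k)
        for strand, nuc in (("c", bp.c), ("d", bp.d)):
            p = nuc.atom_pos("P")
            if p is None:
                skipped.append((nuc.chain_id, nuc.residue.number, "no phosphate"))
            else:
                phos[strand].append((ai, nuc.chain_id, nuc.residue.number, p))

    lo_c, hi_c = min(a for a, *_ in phos["c"] + phos["d"]), max(a for a, *_ in phos["c"] + phos["d"])
    entries: List[GrooveEntry] = []
    for strand, other in (("c", "d"), ("d", "c")):
        for ai, cid, num, p in phos[strand]:
            e = GrooveEntry(cid, num, ai, strand)
            for attr, window in (("minor", minor_window), ("major", major_window)):
                w0, w1 = window
                if strand == "d":
                    w0, w1 = -w1, -w0
                cands = [(float(np.linalg.norm(p - q)), (cid2, num2))
                         for aj, cid2, num2, q in phos[other] if w0 <= aj - ai <= w1]
                full = (lo_c <= ai + w0) and (ai + w1 <= hi_c)
                if cands:
                    d, partner = min(cands)
                    setattr(e, f"d_{attr}", d)
                    setattr(e, f"partner_{attr}", partner)
                setattr(e, f"{attr}_edge", not full or not cands)
            if e.d_minor is not None and e.d_minor <= 0:
                raise ValueError(f"non-positive P-P distance at {cid}:{num}")
            entries.append(e)
    entries.sort(key=lambda e: (e.strand, e.aligned))
    prof = GrooveProfile(entries, reference=reference, skipped=skipped)
    return delta_pp_profile(prof, reference)


def delta_pp_profile(profile: GrooveProfile, reference: float = BDNA_MINOR_REFERENCE) -> GrooveProfile:
    """Profile with minor-groove deltas relative to ``reference`` (Å)."""
    entries = [replace(e, delta_minor=(None if e.d_minor is None else e.d_minor - reference))
               for e in profile.entries]
    return GrooveProfile(entries, reference=reference, skipped=list(profile.skipped))
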
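"""End-to-end analysis of a protein-DNA complex and cross-complex comparison.

``analyze_complex`` runs the full stack on one structure — component
selection, operator numbering, backbone torsions and states, base-pair
and step parameters, groove profiles, contact classification and buried
surface areas — and returns a serialisable report.  Stages degrade to
annotated gaps instead of aborting when optional inputs are missing
(e.g. no protein component, or unfittable terminal bases).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as structio
from .contacts import (HBOND_CUTOFF, VDW_CUTOFF, classify_and_summarize,
                       enumerate_contacts)
from .dna import (BI_BII_BAND, backbone_torsions, bp_and_step_parameters,
                  classify_backbone_state, detect_base_pairs, nucleotides_of,
                  region_average_roll)
from .grooves import BDNA_MINOR_REFERENCE, groove_profile
from .model import EmptySelectionError, OperatorNumbering, StructureModel
from .sasa import buried_surface_area
from .threading import REPULSIVE_CUTOFF

__all__ = ["AnalysisConfig", "AnalysisReport", "analyze_complex", "compare_complexes"]


@dataclass
class AnalysisConfig:
    """Chain roles, operator centring and every distance/angle threshold.

    All thresholds default to the values used throughout the package:
    hydrogen bonds at 3.3 Å, van der Waals contacts below 3.8 Å,
    repulsive clashes below 2.85 Å, the 11.7 Å regular-B-DNA
    minor-groove reference and a +/-45 deg B_I/B_II dead zone.
    """
    protein_chains: Optional[List[str]] = None
    dna_chains: Optional[List[str]] = None
    center: Optional[Tuple[str, int]] = None      # nucleotide of operator index 0
    strand_labels: Optional[Dict[str, str]] = None
    hbond_cutoff: float = HBOND_CUTOFF
    vdw_cutoff: float = VDW_CUTOFF
    repulsive_cutoff: float = REPULSIVE_CUTOFF
    groove_reference: float = BDNA_MINOR_REFERENCE
    bi_bii_band: float = BI_BII_BAND
    include_waters: bool = False
    stages: Tuple[str, ...] = ("dna", "grooves", "contacts", "sasa")


@dataclass
class AnalysisReport:
    structure_id: str
    config: AnalysisConfig
    nucleotide_table: Optional[pd.DataFrame] = None
    pair_table: Optional[pd.DataFrame] = None
    step_table: Optional[pd.DataFrame] = None
    groove_table: Optional[pd.DataFrame] = None
    contact_table: Optional[pd.DataFrame] = None
    residue_summary: Optional[pd.DataFrame] = None
    bsa: Optional[Dict[str, float]] = None
    state_counts: Optional[Dict[str, int]] = None
    gaps: List[str] = field(default_factory=list)

    def to_json(self, path: Optional[str] = None) -> str:
        payload = {"structure_id": self.structure_id,
                   "config": asdict(self.config),
                   "state_counts": self.state_counts,
                   "bsa": self.bsa,
                   "gaps": self.gaps}
        for name in ("nucleotide_table", "pair_table", "step_table",
                     "groove_table", "contact_table", "residue_summary"):
            df = getattr(self, name)
            payload[name] = None if df is None else df.to_dict(orient="records")
        text = json.dumps(payload, indent=1, sort_keys=True, default=_jsonable)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not serialisable: {type(obj)}")


def analyze_complex(structure, config: Optional[AnalysisConfig] = None) -> AnalysisReport:
    """Full analysis of one complex (path or :class:`StructureModel`)."""
    config = config or AnalysisConfig()
    if isinstance(structure, StructureModel):
        model = structure
    else:
        model = structio.parse_structure(str(structure))
    report = AnalysisReport(structure_id=model.source, config=config)

    try:
        dna = (model.select(chains=config.dna_chains) if config.dna_chains
               else model.select(kind="dna"))
    except (EmptySelectionError, KeyError) as exc:
        raise ValueError(f"cannot isolate DNA component: {exc}") from exc
    protein = None
    try:
        protein = (model.select(chains=config.protein_chains) if config.protein_chains
                   else model.select(kind="protein"))
    except (EmptySelectionError, KeyError):
        report.gaps.append("no protein component; contact and BSA stages skipped")

    numbering = None
    if config.center is not None:
        numbering = structio.assign_operator_numbering(model, config.center,
                                                       config.strand_labels)

    pairs = detect_base_pairs(dna)
    nucs = nucleotides_of(dna)

    if "dna" in config.stages:
        rows = []
        counts: Dict[str, int] = {}
        for n in nucs:
            t = backbone_torsions(n)
            s = classify_backbone_state(t, band=config.bi_bii_band)
            counts[s.state] = counts.get(s.state, 0) + 1
            row = {"chain": n.chain_id, "number": n.residue.number, "base": n.letter,
                   **{k: (None if v is None else round(v, 2)) for k, v in vars(t).items()},
                   "eps_minus_zeta": None if s.eps_minus_zeta is None else round(s.eps_minus_zeta, 2),
                   "state": s.state}
            if numbering is not None:
                try:
                    row["operator_index"], row["strand"] = numbering.index_of(
                        n.chain_id, n.residue.number)
                except KeyError:
                    pass
            rows.append(row)
        report.nucleotide_table = pd.DataFrame(rows)
        report.state_counts = counts
        if pairs:
            pairs, steps = bp_and_step_parameters(pairs)
            prow = []
            for bp in pairs:
                prow.append({"c": f"{bp.c.chain_id}:{bp.c.residue.number}",
                             "d": f"{bp.d.chain_id}:{bp.d.residue.number}",
                             "bases": f"{bp.c.letter}/{bp.d.letter}",
                             "type": bp.pair_type,
                             "propeller": round(bp.propeller, 2),
                             "buckle": round(bp.buckle, 2),
                             "opening": round(bp.opening, 2),
                             "origin": [round(x, 3) for x in bp.origin]})
            report.pair_table = pd.DataFrame(prow)
            report.step_table = pd.DataFrame(
                [{k: round(v, 3) for k, v in vars(s).items()} for s in steps])
        else:
            report.gaps.append("no base pairs detected; pair/step stage skipped")

    if "grooves" in config.stages:
        try:
            prof = groove_profile(dna, pairs=pairs or None, numbering=numbering,
                                  reference=config.groove_reference)
            report.groove_table = prof.to_frame()
        except ValueError as exc:
            report.gaps.append(f"groove stage skipped: {exc}")

    if "contacts" in config.stages and protein is not None:
        contacts = enumerate_contacts(protein, dna, cutoff=config.vdw_cutoff,
                                      numbering=numbering)
        summary = classify_and_summarize(contacts, hbond_cutoff=config.hbond_cutoff,
                                         vdw_cutoff=config.vdw_cutoff, protein=protein)
        report.contact_table = pd.DataFrame([vars(c) for c in summary.contacts])
        report.residue_summary = summary.per_residue
        for cid, resname, num in summary.missing_side_chains:
            report.gaps.append(f"interface residue {resname}{num}{cid} has missing "
                               f"side-chain atoms (disordered)")

    if "sasa" in config.stages and protein is not None:
        prot_sel = ({"chains": config.protein_chains} if config.protein_chains
                    else {"kind": "protein"})
        dna_sel = ({"chains": config.dna_chains} if config.dna_chains
                   else {"kind": "dna"})
        report.bsa = {"protein_dna": round(
            buried_surface_area(model, prot_sel, dna_sel), 1)}
        dna_cids = [c.cid for c in dna.chains]
        if len(dna_cids) == 2:
            report.bsa["dna_strands"] = round(buried_surface_area(
                model, {"chains": [dna_cids[0]]}, {"chains": [dna_cids[1]]}), 1)
    return report


def compare_complexes(reports: Sequence[AnalysisReport],
                      alignment: Optional[Dict[str, int]] = None) -> Dict[str, pd.DataFrame]:
    """Side-by-side groove and step tables over aligned operator indices.

    ``alignment`` maps structure id -> offset added to that complex's
    operator indices to bring them onto a common coordinate (identity
    when omitted).  Raises when a report lacks the tables to align.
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    alignment = alignment or {}
    groove_cols = {}
    roll_cols = {}
    for rep in reports:
        off = alignment.get(rep.structure_id, 0)
        if rep.groove_table is None or "aligned" not in rep.groove_table:
            raise ValueError(f"report {rep.structure_id} has no groove table")
        g = rep.groove_table
        gc = g[g.strand == "c"].set_index(g[g.strand == "c"].aligned + off)["d_minor"]
        groove_cols[rep.structure_id] = gc
        if rep.step_table is not None and rep.nucleotide_table is not None:
            roll = rep.step_table["roll"]
            idx = sorted(g[g.strand == "c"].aligned + off)
            roll.index = idx[:len(roll)]
            roll_cols[rep.structure_id] = roll
    out = {"groove_minor": pd.DataFrame(groove_cols).sort_index()}
    if roll_cols:
        out["step_roll"] = pd.DataFrame(roll_cols).sort_index()
    diffs = out["groove_minor"]
    summary = pd.DataFrame({
        "mean_minor": diffs.mean(),
        "min_minor": diffs.min(),
        "mean_roll": out.get("step_roll", pd.DataFrame()).mean()
        if roll_cols else np.nan,
    })
    out["summary"] = summary
    return out
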
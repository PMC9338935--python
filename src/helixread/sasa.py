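"""Solvent-accessible and buried surface areas (Shrake-Rupley).

Per-atom SASA is computed by sampling each solvent-expanded sphere with
a deterministic Fibonacci lattice (no random number generator, so
results are bit-reproducible) and counting points not occluded by any
neighbouring expanded sphere.  Buried surface area between two groups is
SASA(A) + SASA(B) - SASA(A u B), with all third-party atoms excluded
from every term so the value reflects only the A/B interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geom import fibonacci_sphere
from .model import VDW_RADII, StructureModel

__all__ = ["SasaResult", "shrake_rupley_sasa", "buried_surface_area",
           "DEFAULT_PROBE", "DEFAULT_POINTS"]

DEFAULT_PROBE = 1.4    # Å water probe
DEFAULT_POINTS = 960   # sphere sample points per atom


@dataclass
class SasaResult:
    atom_keys: List[Tuple[str, int, str]]   # (chain, residue number, atom name)
    areas: np.ndarray                       # per-atom accessible area, Å^2
    probe: float
    n_points: int
    radii: Dict[str, float]

    @property
    def total(self) -> float:
        return float(self.areas.sum())

    def per_chain(self) -> Dict[str, float]:
        out: Dict[str, float] = {}
        for (cid, _, _), a in zip(self.atom_keys, self.areas):
            out[cid] = out.get(cid, 0.0) + float(a)
        return out

    def per_residue(self) -> pd.DataFrame:
        df = pd.DataFrame(self.atom_keys, columns=["chain", "resnum", "atom"])
        df["area"] = self.areas
        return df.groupby(["chain", "resnum"], as_index=False)["area"].sum()


def _radii_for(model: StructureModel, radii: Dict[str, float], probe: float):
    keys, coords, rr = [], [], []
    for c, r, a in model.iter_atoms():
        if a.element == "H":
            continue
        el = a.element.upper()
        if el not in radii:
            raise KeyError(
                f"no van der Waals radius for element {a.element!r} "
                f"(atom {a.name} in {c.cid}:{r.number} {r.name})")
        keys.append((c.cid, r.number, a.name))
        coords.append(a.position)
        rr.append(radii[el] + probe)
    if not keys:
        raise ValueError("model contains no heavy atoms")
    return keys, np.array(coords), np.array(rr)


def shrake_rupley_sasa(model: StructureModel, probe: float = DEFAULT_PROBE,
                       n_points: int = DEFAULT_POINTS,
                       radii: Optional[Dict[str, float]] = None) -> SasaResult:
    """Per-atom solvent-accessible surface area of a model.

    Unknown elements raise ``KeyError`` naming the atom — there is no
    silent default radius.  Waters should be excluded by selection
    before calling when a solvent-free surface is wanted.
    """
    radii = dict(VDW_RADII if radii is None else radii)
    keys, coords, expanded = _radii_for(model, radii, probe)
    sphere = fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    rmax = expanded.max()
    areas = np.empty(len(keys))
    for i in range(len(keys)):
        pts = coords[i] + expanded[i] * sphere
        nb = [j for j in tree.query_ball_point(coords[i], expanded[i] + rmax) if j != i]
        if nb:
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(-1)
            buried = (d2 < (expanded[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * expanded[i] ** 2
    return SasaResult(keys, areas, probe, n_points, radii)


def buried_surface_area(model: StructureModel, group_a: dict, group_b: dict,
                        probe: float = DEFAULT_PROBE, n_points: int = DEFAULT_POINTS,
                        radii: Optional[Dict[str, float]] = None) -> float:
    """Interface area buried between two atom groups of one model (Å^2).

    ``group_a`` / ``group_b`` are keyword dictionaries for
    :meth:`StructureModel.select` (e.g. ``{"kind": "protein"}`` or
    ``{"chains": ["C", "D"]}``).  The groups must be disjoint; atoms in
    neither group take no part in any of the three SASA evaluations.
    """
    A = model.select(**group_a)
    B = model.select(**group_b)
    keys_a = {(c.cid, r.number, r.icode, a.name) for c, r, a in A.iter_atoms()}
    keys_b = {(c.cid, r.number, r.icode, a.name) for c, r, a in B.iter_atoms()}
    overlap = keys_a & keys_b
    if overlap:
        raise ValueError(f"groups overlap on {len(overlap)} atoms, e.g. {sorted(overlap)[:3]}")
    AB = _merge(A, B)
    sa = shrake_rupley_sasa(A, probe, n_points, radii).total
    sb = shrake_rupley_sasa(B, probe, n_points, radii).total
    sab = shrake_rupley_sasa(AB, probe, n_points, radii).total
    return sa + sb - sab


def _merge(a: StructureModel, b: StructureModel) -> StructureModel:
    out = a.copy()
    for chain in b.chains:
        try:
            dest = out.chain(chain.cid)
        except KeyError:
            out.chains.append(chain.copy())
            continue
        for res in chain.residues:
            dest.residues.append(res.copy())
    out.validate()
    return out
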
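"""Binding-interface detection and comparison.

A residue of chain A belongs to the A:B interface iff any of its heavy atoms
lies within a distance cutoff of any heavy atom of chain B. The default
cutoff of 5.0 A is a standard atom-contact criterion; it replaces the
server-based interface predictor used historically for this kind of screen
with a deterministic, reproducible definition.

Interfaces of two instances of the same protein are compared through an
alignment map, never through raw author numbering: two structures of one
protein routinely disagree on residue numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Set, Tuple

from scipy.spatial import cKDTree
import numpy as np

from clashscan.seqmap import AlignmentMap
from clashscan.structio import ResidueKey, StructureModel

logger = logging.getLogger(__name__)

DEFAULT_CONTACT_CUTOFF = 5.0  # Angstrom, heavy-atom to heavy-atom


@dataclass(frozen=True)
class InterfaceRecord:
    structure_id: str
    chain_id: str
    partner_chain_id: str
    residue_keys: frozenset  # of ResidueKey
    size: int

    def __post_init__(self):
        if self.size != len(self.residue_keys):
            raise ValueError("size must equal |residue_keys|")


@dataclass(frozen=True)
class InterfaceComparison:
    shared_positions: frozenset  # alignment column indices
    shared_fraction: float  # % of the smaller interface shared
    distinct: bool


def _heavy_atoms(model: StructureModel, chain_id: str):
    chain = model.get_chain(chain_id)
    keys, coords = [], []
    for res in chain.residues:
        for atom in res.atoms:
            if atom.element.upper() == "H":
                continue
            keys.append(res.key)
            coords.append(atom.position)
    return keys, np.asarray(coords, dtype=float)


def detect_interface(model: StructureModel, chain_a: str, chain_b: str,
                     contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
                     ) -> Tuple[InterfaceRecord, InterfaceRecord]:
    """Return the interface records of chain_a and chain_b against each other."""
    if chain_a == chain_b:
        raise ValueError("chains must be distinct")
    keys_a, xyz_a = _heavy_atoms(model, chain_a)
    keys_b, xyz_b = _heavy_atoms(model, chain_b)
    res_a: Set[ResidueKey] = set()
    res_b: Set[ResidueKey] = set()
    if len(xyz_a) and len(xyz_b):
        tree_b = cKDTree(xyz_b)
        hits = cKDTree(xyz_a).query_ball_tree(tree_b, r=contact_cutoff)
        for i, neighbours in enumerate(hits):
            if neighbours:
                res_a.add(keys_a[i])
                for j in neighbours:
                    res_b.add(keys_b[j])
    rec_a = InterfaceRecord(model.entry_id, chain_a, chain_b, frozenset(res_a), len(res_a))
    rec_b = InterfaceRecord(model.entry_id, chain_b, chain_a, frozenset(res_b), len(res_b))
    return rec_a, rec_b


def meets_min_size(iface: InterfaceRecord, min_residues: int = 5) -> bool:
    """True iff the interface has at least ``min_residues`` residues."""
    return iface.size >= min_residues


def compare_interfaces(iface_pr: InterfaceRecord, iface_ps: InterfaceRecord,
                       amap: AlignmentMap) -> InterfaceComparison:
    """Compare two interfaces of the same protein via aligned positions.

    ``amap`` must align the instance carrying ``iface_pr`` (side 1) with the
    instance carrying ``iface_ps`` (side 2). Interface residues falling
    outside the aligned region count as unshared.
    """
    pos1 = {key: i for i, (key, _) in enumerate(amap.pairs)}
    pos2 = {key: i for i, (_, key) in enumerate(amap.pairs)}
    cols1 = {pos1[k] for k in iface_pr.residue_keys if k in pos1}
    cols2 = {pos2[k] for k in iface_ps.residue_keys if k in pos2}
    out1 = len(iface_pr.residue_keys) - len(cols1)
    out2 = len(iface_ps.residue_keys) - len(cols2)
    if out1 or out2:
        logger.warning("%d interface residue(s) outside the aligned region; counted as unshared",
                       out1 + out2)
    shared = cols1 & cols2
    smaller = min(iface_pr.size, iface_ps.size)
    fraction = 100.0 * len(shared) / smaller if smaller else 0.0
    return InterfaceComparison(frozenset(shared), fraction, distinct=not shared)


def write_interfaces(records, path) -> None:
    """Serialize interface records to TSV (residues as chain:number:icode)."""
    from pathlib import Path
    lines = ["entry\tchain\tpartner\tresidues"]
    for rec in records:
        keys = sorted(rec.residue_keys, key=lambda k: (k[0], k[1], k[2]))
        res = ",".join(f"{c}:{n}:{i or '-'}" for c, n, i in keys)
        lines.append(f"{rec.structure_id}\t{rec.chain_id}\t{rec.partner_chain_id}\t{res}")
    Path(path).write_text("\n".join(lines) + "\n")
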
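"""Grouping chain instances by protein accession and aligning instance pairs.

Two structure instances of the same protein rarely resolve exactly the same
residues, so residue correspondence is established by optimal global pairwise
alignment (Needleman-Wunsch, BLOSUM62, affine gaps: open 10, extend 0.5,
the customary protein defaults). For the intended use case the two sequences are
near-identical and the exact parameter choice is immaterial.

Matched pairs are restricted to residues that have a C-alpha atom in both
instances, because superposition and interface bookkeeping operate on those.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from Bio import Align
from Bio.Align import substitution_matrices

from clashscan.structio import Chain, ResidueKey, StructureCollection

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChainInstance:
    entry_id: str
    chain_id: str
    accession: str
    sequence: str

    def __post_init__(self):
        if not self.accession:
            raise ValueError("accession must be nonempty")

    @property
    def label(self) -> str:
        return f"{self.entry_id}:{self.chain_id}"


@dataclass
class AlignmentMap:
    """Residue correspondence between two instances of one protein."""
    pairs: List[Tuple[ResidueKey, ResidueKey]]
    identity: float  # % identical residues over aligned columns
    len1: int
    len2: int

    @property
    def aligned_length(self) -> int:
        return len(self.pairs)


def _make_aligner(scoring: Optional[dict] = None) -> Align.PairwiseAligner:
    scoring = scoring or {}
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(
        scoring.get("matrix", "BLOSUM62"))
    aligner.open_gap_score = -abs(scoring.get("gap_open", 10.0))
    aligner.extend_gap_score = -abs(scoring.get("gap_extend", 0.5))
    return aligner


def global_align_indices(seq1: str, seq2: str, scoring: Optional[dict] = None,
                         ) -> Tuple[List[Tuple[int, int]], float]:
    """Optimal global alignment; returns matched index pairs and % identity."""
    if not seq1 or not seq2:
        raise ValueError("sequences must be nonempty")
    aligner = _make_aligner(scoring)
    aln = aligner.align(seq1, seq2)[0]
    pairs: List[Tuple[int, int]] = []
    ident = 0
    for (s1, e1), (s2, e2) in zip(*aln.aligned):
        for i, j in zip(range(s1, e1), range(s2, e2)):
            pairs.append((i, j))
            if seq1[i] == seq2[j]:
                ident += 1
    identity = 100.0 * ident / len(pairs) if pairs else 0.0
    return pairs, identity


def global_align(chain1: Chain, chain2: Chain, scoring: Optional[dict] = None) -> AlignmentMap:
    """Align two chain instances; keep columns where both residues have a CA."""
    idx_pairs, identity = global_align_indices(chain1.sequence, chain2.sequence, scoring)
    pairs: List[Tuple[ResidueKey, ResidueKey]] = []
    for i, j in idx_pairs:
        r1, r2 = chain1.residues[i], chain2.residues[j]
        if r1.ca is not None and r2.ca is not None:
            pairs.append((r1.key, r2.key))
    return AlignmentMap(pairs, identity, len(chain1.residues), len(chain2.residues))


# kept as an alias: the chain-level entry point is the common one
align_chains = global_align


def write_fasta(instances: List[ChainInstance], path) -> None:
    """Export chain sequences as FASTA (header: entry:chain accession)."""
    from pathlib import Path
    lines = []
    for inst in instances:
        lines.append(f">{inst.label} {inst.accession}")
        lines.extend(inst.sequence[i:i + 60] for i in range(0, len(inst.sequence), 60))
    Path(path).write_text("\n".join(lines) + "\n")


def alignment_to_tsv(amap: AlignmentMap, path) -> None:
    """Serialize matched residue pairs (chain:number:icode per side)."""
    from pathlib import Path
    lines = ["residue_1\tresidue_2"]
    for (c1, n1, i1), (c2, n2, i2) in amap.pairs:
        lines.append(f"{c1}:{n1}:{i1 or '-'}\t{c2}:{n2}:{i2 or '-'}")
    Path(path).write_text("\n".join(lines) + "\n")


def passes_length_filters(amap: AlignmentMap, max_len_diff: int = 15,
                          min_aligned: int = 30) -> bool:
    """Sequence-length difference <= max_len_diff and alignment covers >= min_aligned."""
    return abs(amap.len1 - amap.len2) <= max_len_diff and amap.aligned_length >= min_aligned


def group_by_accession(collection: StructureCollection,
                       infer_missing: bool = False,
                       min_identity: float = 98.0,
                       max_len_diff: int = 15) -> Dict[str, List[ChainInstance]]:
    """Group protein chains by accession; groups of size >= 2 are candidate primaries.

    Chains absent from the accession map are excluded (logged), unless
    ``infer_missing`` is set, in which case unmapped chains are auto-grouped by
    near-identity (>= ``min_identity`` % over the alignment and length
    difference <= ``max_len_diff``) under synthetic accessions ``AUTO<n>``.
    """
    groups: Dict[str, List[ChainInstance]] = {}
    unmapped = []
    for model in collection.models:
        for chain in model.chains:
            acc = collection.accession_map.get((model.entry_id, chain.id))
            if acc is None:
                unmapped.append((model.entry_id, chain.id, chain.sequence))
                continue
            groups.setdefault(acc, []).append(
                ChainInstance(model.entry_id, chain.id, acc, chain.sequence))
    if unmapped and not infer_missing:
        logger.warning("%d chain(s) without accession mapping excluded", len(unmapped))
    elif unmapped:
        for acc, members in _infer_groups(unmapped, min_identity, max_len_diff).items():
            groups[acc] = members
    return groups


def _infer_groups(unmapped: List[Tuple[str, str, str]], min_identity: float,
                  max_len_diff: int) -> Dict[str, List[ChainInstance]]:
    # single-linkage grouping by near-identity
    parent = list(range(len(unmapped)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(unmapped)), 2):
        s1, s2 = unmapped[i][2], unmapped[j][2]
        if abs(len(s1) - len(s2)) > max_len_diff or not s1 or not s2:
            continue
        _, identity = global_align_indices(s1, s2)
        if identity >= min_identity:
            parent[find(i)] = find(j)
    groups: Dict[str, List[ChainInstance]] = {}
    roots: Dict[int, str] = {}
    for idx, (entry, chain, seq) in enumerate(unmapped):
        root = find(idx)
        acc = roots.setdefault(root, f"AUTO{len(roots) + 1}")
        groups.setdefault(acc, []).append(ChainInstance(entry, chain, acc, seq))
    return groups
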
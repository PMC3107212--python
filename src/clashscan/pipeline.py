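"""Screen orchestration: pair enumeration, the filter cascade, and reports.

An interaction pair couples two interactions P-R and P-S found in different
structure instances, where the two P chains are the same protein (same
accession) and R and S are different proteins. Each pair passes through a
cascade of gates before being called a collision:

  1. both interfaces have at least 5 residues,
  2. the P instances align and the two interfaces share no aligned position,
  3. sequence lengths differ by at most 15 residues and the alignment covers
     at least 30 amino acids,
  4. the C-alpha superposition of the P instances achieves RMSD below 7 A,
  5. both volume methods report an overlap of the secondary proteins of at
     least 2000 A^3.

Threshold senses follow the screen's definitions exactly: "less than 7 A"
is strict, "at least five residues" / "at least 2000 A^3" / "at least
thirty amino acids" are non-strict, and "differ by more than 15 residues"
excludes strictly above 15.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from clashscan import interface as iface_mod
from clashscan import seqmap, superpose, volume
from clashscan.seqmap import AlignmentMap, ChainInstance
from clashscan.structio import StructureCollection, StructureModel, assign_radii
from clashscan.superpose import DegenerateGeometryError

logger = logging.getLogger(__name__)

GATES = ("min_interface_size", "interfaces_distinct", "len_diff_ok",
         "aligned_len_ok", "rmsd_ok", "overlap_ok_ses", "overlap_ok_sas")


@dataclass(frozen=True)
class FilterConfig:
    contact_cutoff: float = 5.0  # A, heavy-atom contact criterion
    min_interface_residues: int = 5
    overlap_threshold: float = 2000.0  # A^3, required of both methods
    max_rmsd: float = 7.0  # A, strict upper bound
    max_len_diff: int = 15
    min_aligned: int = 30
    ses_probe: float = 1.5
    ses_spacing: float = 0.5
    sas_probe: float = 1.4
    sas_samples: int = 2_000_000
    sas_seed: int = 1337
    radius_table: Optional[Mapping[str, float]] = None

    def __post_init__(self):
        for name in ("contact_cutoff", "min_interface_residues", "overlap_threshold",
                     "max_rmsd", "max_len_diff", "min_aligned", "ses_probe",
                     "ses_spacing", "sas_probe", "sas_samples"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def ses_method(self) -> volume.VolumeMethod:
        return volume.ses_method(self.ses_probe, self.ses_spacing)

    def sas_method(self) -> volume.VolumeMethod:
        return volume.sas_method(self.sas_probe, self.sas_samples, self.sas_seed)


@dataclass(frozen=True)
class InteractionPair:
    primary_1: ChainInstance  # P in the structure containing R
    secondary_r: ChainInstance
    primary_2: ChainInstance  # P in the structure containing S
    secondary_s: ChainInstance

    def __post_init__(self):
        if self.primary_1.accession != self.primary_2.accession:
            raise ValueError("primary instances must share an accession")
        if self.secondary_r.accession == self.secondary_s.accession:
            raise ValueError("secondary proteins must have different accessions")

    def __str__(self) -> str:
        return (f"P={self.primary_1.accession} [{self.primary_1.label}+{self.secondary_r.label}"
                f" vs {self.primary_2.label}+{self.secondary_s.label}]")


@dataclass
class CollisionVerdict:
    pair: InteractionPair
    flags: Dict[str, Optional[bool]] = field(default_factory=lambda: dict.fromkeys(GATES))
    rmsd: Optional[float] = None
    overlap_ses: Optional[float] = None
    overlap_sas: Optional[float] = None
    unevaluable: bool = False

    @property
    def is_collision(self) -> bool:
        return not self.unevaluable and all(self.flags[g] is True for g in GATES)


def _interactions_by_accession(collection: StructureCollection, config: FilterConfig,
                               ) -> Dict[str, List[Tuple[ChainInstance, ChainInstance]]]:
    """All chain-level interactions (P, partner) with a nonempty interface."""
    out: Dict[str, List[Tuple[ChainInstance, ChainInstance]]] = {}
    for model in collection.models:
        ids = [c.id for c in model.chains]
        contacts: Dict[Tuple[str, str], bool] = {}
        for a, b in itertools.combinations(ids, 2):
            rec_a, _ = iface_mod.detect_interface(model, a, b, config.contact_cutoff)
            contacts[(a, b)] = rec_a.size > 0
        for a, b in itertools.permutations(ids, 2):
            if not contacts.get((a, b) if a < b else (b, a)):
                continue
            acc_a = collection.accession_map.get((model.entry_id, a))
            acc_b = collection.accession_map.get((model.entry_id, b))
            if acc_a is None or acc_b is None:
                continue
            inst_p = ChainInstance(model.entry_id, a, acc_a, model.get_chain(a).sequence)
            inst_q = ChainInstance(model.entry_id, b, acc_b, model.get_chain(b).sequence)
            out.setdefault(acc_a, []).append((inst_p, inst_q))
    return out


def enumerate_interaction_pairs(collection: StructureCollection,
                                config: Optional[FilterConfig] = None,
                                ) -> List[InteractionPair]:
    """All-versus-all (P-R, P-S) combinations across structures.

    The two P instances must be distinct chain instances sharing an accession;
    R and S must have different accessions; pairs are deduplicated under
    swapping the two interactions.
    """
    config = config or FilterConfig()
    interactions = _interactions_by_accession(collection, config)
    pairs: List[InteractionPair] = []
    seen: Set[FrozenSet[Tuple[str, str, str, str]]] = set()
    for acc, inters in interactions.items():
        for (p1, r), (p2, s) in itertools.combinations(inters, 2):
            if (p1.entry_id, p1.chain_id) == (p2.entry_id, p2.chain_id):
                continue  # same P instance: both partners already co-resolved
            if r.accession == s.accession:
                continue
            key = frozenset([(p1.entry_id, p1.chain_id, r.entry_id, r.chain_id),
                             (p2.entry_id, p2.chain_id, s.entry_id, s.chain_id)])
            if key in seen:
                continue
            seen.add(key)
            pairs.append(InteractionPair(p1, r, p2, s))
    return pairs


def evaluate_pair(collection: StructureCollection, pair: InteractionPair,
                  config: Optional[FilterConfig] = None,
                  short_circuit: bool = True) -> CollisionVerdict:
    """Run the full filter cascade on one interaction pair.

    With ``short_circuit`` (default) later gates are skipped once one fails
    (their flags stay None); with ``short_circuit=False`` every gate that can
    be computed is, which is useful for diagnostics. The final classification
    is identical either way.
    """
    config = config or FilterConfig()
    verdict = CollisionVerdict(pair)
    flags = verdict.flags

    model_1 = collection.get_model(pair.primary_1.entry_id)
    model_2 = collection.get_model(pair.primary_2.entry_id)
    chain_p1 = model_1.get_chain(pair.primary_1.chain_id)
    chain_p2 = model_2.get_chain(pair.primary_2.chain_id)

    iface_pr, iface_r = iface_mod.detect_interface(
        model_1, pair.primary_1.chain_id, pair.secondary_r.chain_id, config.contact_cutoff)
    iface_ps, iface_s = iface_mod.detect_interface(
        model_2, pair.primary_2.chain_id, pair.secondary_s.chain_id, config.contact_cutoff)
    flags["min_interface_size"] = all(
        iface_mod.meets_min_size(i, config.min_interface_residues)
        for i in (iface_pr, iface_r, iface_ps, iface_s))
    if short_circuit and not flags["min_interface_size"]:
        return verdict

    amap = seqmap.global_align(chain_p1, chain_p2)

    comparison = iface_mod.compare_interfaces(iface_pr, iface_ps, amap)
    flags["interfaces_distinct"] = comparison.distinct
    if short_circuit and not flags["interfaces_distinct"]:
        return verdict

    flags["len_diff_ok"] = abs(amap.len1 - amap.len2) <= config.max_len_diff
    flags["aligned_len_ok"] = amap.aligned_length >= config.min_aligned
    if short_circuit and not (flags["len_diff_ok"] and flags["aligned_len_ok"]):
        return verdict

    ca1, ca2 = matched_ca_coords(chain_p1, chain_p2, amap)
    try:
        transform = superpose.kearsley_superpose(ca1, ca2)
    except DegenerateGeometryError as exc:
        logger.warning("pair %s unevaluable: %s", pair, exc)
        verdict.unevaluable = True
        return verdict
    verdict.rmsd = transform.rmsd
    flags["rmsd_ok"] = superpose.passes_rmsd_filter(transform, config.max_rmsd)
    if short_circuit and not flags["rmsd_ok"]:
        return verdict

    model_r = assign_radii(model_1.subset([pair.secondary_r.chain_id]).copy(),
                           config.radius_table)
    model_s = assign_radii(model_2.subset([pair.secondary_s.chain_id]).copy(),
                           config.radius_table)
    model_s = superpose.apply_transform(model_s, transform)

    m_ses = volume.overlap_volume(model_r, model_s, config.ses_method())
    m_sas = volume.overlap_volume(model_r, model_s, config.sas_method())
    verdict.overlap_ses = m_ses.overlap
    verdict.overlap_sas = m_sas.overlap
    flags["overlap_ok_ses"] = m_ses.overlap >= config.overlap_threshold
    flags["overlap_ok_sas"] = m_sas.overlap >= config.overlap_threshold
    return verdict


def matched_ca_coords(chain_1, chain_2, amap: AlignmentMap) -> Tuple[np.ndarray, np.ndarray]:
    """C-alpha coordinate arrays for the matched residue pairs of an alignment."""
    res1 = {r.key: r for r in chain_1.residues}
    res2 = {r.key: r for r in chain_2.residues}
    xyz1 = [res1[k1].ca.position for k1, _ in amap.pairs]
    xyz2 = [res2[k2].ca.position for _, k2 in amap.pairs]
    return np.asarray(xyz1), np.asarray(xyz2)


def method_correlation(verdicts: Sequence[CollisionVerdict]) -> float:
    """Pearson correlation of the SES and SAS overlaps across verdicts."""
    pts = [(v.overlap_ses, v.overlap_sas) for v in verdicts
           if v.overlap_ses is not None and v.overlap_sas is not None]
    if len(pts) < 2:
        raise ValueError("need at least 2 verdicts with both overlaps computed")
    x, y = np.asarray(pts).T
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("zero variance: correlation undefined")
        return float("nan")
    if len(pts) == 2:
        logger.warning("correlation over two points is degenerate (|r| = 1)")
    return float(np.corrcoef(x, y)[0, 1])


def whitelist_filter(verdicts: Iterable[CollisionVerdict],
                     whitelist: Set[FrozenSet[str]]) -> List[CollisionVerdict]:
    """Keep verdicts whose P-R and P-S interactions are both whitelisted.

    ``whitelist`` holds unordered accession pairs (frozensets of size 1-2).
    """
    if not whitelist:
        logger.warning("empty whitelist: all verdicts dropped")
        return []
    kept = []
    for v in verdicts:
        acc_p = v.pair.primary_1.accession
        pr = frozenset((acc_p, v.pair.secondary_r.accession))
        ps = frozenset((acc_p, v.pair.secondary_s.accession))
        if pr in whitelist and ps in whitelist:
            kept.append(v)
    return kept


REPORT_COLUMNS = [
    "primary_accession", "p1", "r", "p2", "s",
    *GATES, "rmsd", "overlap_ses", "overlap_sas", "unevaluable", "is_collision",
]


def verdicts_to_frame(verdicts: Sequence[CollisionVerdict]) -> pd.DataFrame:
    rows = []
    for v in verdicts:
        rows.append({
            "primary_accession": v.pair.primary_1.accession,
            "p1": v.pair.primary_1.label, "r": v.pair.secondary_r.label,
            "p2": v.pair.primary_2.label, "s": v.pair.secondary_s.label,
            **{g: v.flags[g] for g in GATES},
            "rmsd": v.rmsd, "overlap_ses": v.overlap_ses, "overlap_sas": v.overlap_sas,
            "unevaluable": v.unevaluable, "is_collision": v.is_collision,
        })
    frame = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if len(frame):
        frame = frame.sort_values(
            ["is_collision", "overlap_ses"], ascending=[False, False],
            na_position="last", kind="mergesort").reset_index(drop=True)
    return frame


def write_report(verdicts: Sequence[CollisionVerdict], path: str | Path) -> Path:
    """One TSV row per evaluated pair; collisions first, by SES overlap descending."""
    path = Path(path)
    verdicts_to_frame(verdicts).to_csv(path, sep="\t", index=False)
    return path


def run_screen(collection: StructureCollection, config: Optional[FilterConfig] = None,
               whitelist: Optional[Set[FrozenSet[str]]] = None,
               ) -> List[CollisionVerdict]:
    """Enumerate and evaluate all interaction pairs; log the filter funnel."""
    config = config or FilterConfig()
    pairs = enumerate_interaction_pairs(collection, config)
    logger.info("enumerated %d interaction pair(s)", len(pairs))
    verdicts = [evaluate_pair(collection, p, config) for p in pairs]
    for gate in GATES:
        n_pass = sum(1 for v in verdicts if v.flags[gate] is True)
        n_seen = sum(1 for v in verdicts if v.flags[gate] is not None)
        logger.info("gate %-20s passed %d / %d evaluated", gate, n_pass, n_seen)
    logger.info("collisions: %d / %d", sum(v.is_collision for v in verdicts), len(verdicts))
    if whitelist is not None:
        verdicts = whitelist_filter(verdicts, whitelist)
        logger.info("after whitelist filter: %d", len(verdicts))
    return verdicts
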
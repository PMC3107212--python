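"""Worked collision examples from the public PDB.

Three published collision cases serve as an end-to-end check of the screen;
each couples two crystal structures of the same primary protein bound to
different partners:

* Rac1 (primary; 1i4d chain D vs 2p2l chain C) with Arfaptin (1i4d chain A)
  against a Rac1 trimer chain (2p2l chain B),
* cyclophilin A (1mf8 chain C vs 1m9x chain A) with calcineurin B (1mf8
  chain B) against HIV-1 capsid protein (1m9x chain D),
* soluble growth hormone receptor (1hwg chain C vs 1a22 chain B) with the
  second receptor copy (1hwg chain B) against growth hormone (1a22 chain A).

The PDB entries are not distributed with the package; fetch them first with
``clashscan fetch`` (or :func:`fetch_entry`) into a directory, then call
:func:`evaluate_example` with that directory.
"""

from __future__ import annotations

import urllib.request
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple

from clashscan import seqmap, superpose, volume
from clashscan.pipeline import FilterConfig
from clashscan.structio import StructureModel, assign_radii, read_pdb

PDB_DOWNLOAD_URL = "https://files.rcsb.org/download/{code}.pdb"


@dataclass(frozen=True)
class WorkedExample:
    name: str
    primary_1: Tuple[str, str]  # (entry, chain) of P bound to R
    secondary_r: Tuple[str, str]
    primary_2: Tuple[str, str]  # (entry, chain) of P bound to S
    secondary_s: Tuple[str, str]


EXAMPLES: Dict[str, WorkedExample] = {
    "rac1": WorkedExample("rac1", ("1i4d", "D"), ("1i4d", "A"), ("2p2l", "C"), ("2p2l", "B")),
    "cypa": WorkedExample("cypa", ("1mf8", "C"), ("1mf8", "B"), ("1m9x", "A"), ("1m9x", "D")),
    "ghr": WorkedExample("ghr", ("1hwg", "C"), ("1hwg", "B"), ("1a22", "B"), ("1a22", "A")),
}


@dataclass
class ExampleResult:
    name: str
    aligned_residues: int
    identity: float
    rmsd: float
    overlap_ses: float
    overlap_sas: float
    exceeds_threshold: bool


def fetch_entry(code: str, out_dir: str | Path, timeout: float = 60.0) -> Path:
    """Download one PDB entry (requires network access)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dest = out_dir / f"{code.lower()}.pdb"
    if dest.exists():
        return dest
    url = PDB_DOWNLOAD_URL.format(code=code.upper())
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        dest.write_bytes(resp.read())
    return dest


def required_entries() -> set[str]:
    codes = set()
    for ex in EXAMPLES.values():
        for entry, _ in (ex.primary_1, ex.secondary_r, ex.primary_2, ex.secondary_s):
            codes.add(entry)
    return codes


def evaluate_example(example: WorkedExample, pdb_dir: str | Path,
                     config: Optional[FilterConfig] = None) -> ExampleResult:
    """Align, superpose and measure the secondary-protein overlap for one example."""
    config = config or FilterConfig()
    pdb_dir = Path(pdb_dir)

    def load(entry: str) -> StructureModel:
        return read_pdb(pdb_dir / f"{entry}.pdb", entry_id=entry)

    model_1 = load(example.primary_1[0])
    model_2 = load(example.primary_2[0])
    chain_p1 = model_1.get_chain(example.primary_1[1])
    chain_p2 = model_2.get_chain(example.primary_2[1])

    amap = seqmap.global_align(chain_p1, chain_p2)
    from clashscan.pipeline import matched_ca_coords
    ca1, ca2 = matched_ca_coords(chain_p1, chain_p2, amap)
    transform = superpose.kearsley_superpose(ca1, ca2)

    model_r = assign_radii(model_1.subset([example.secondary_r[1]]).copy(), config.radius_table)
    model_s = assign_radii(model_2.subset([example.secondary_s[1]]).copy(), config.radius_table)
    model_s = superpose.apply_transform(model_s, transform)

    m_ses = volume.overlap_volume(model_r, model_s, config.ses_method())
    m_sas = volume.overlap_volume(model_r, model_s, config.sas_method())
    return ExampleResult(
        name=example.name,
        aligned_residues=amap.aligned_length,
        identity=amap.identity,
        rmsd=transform.rmsd,
        overlap_ses=m_ses.overlap,
        overlap_sas=m_sas.overlap,
        exceeds_threshold=volume.passes_overlap_filter(m_ses, m_sas, config.overlap_threshold),
    )
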
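"""Reading and writing PDB structures into a uniform chain/residue/atom model.

Only protein content is retained: HETATM records, waters and non-amino-acid
residues are dropped, and for multi-model (NMR) entries only the first model
is kept, since it is the representative conformer by PDB convention.
Modified residues with a standard backbone (e.g. selenomethionine) are kept
and mapped to the parent one-letter code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Tuple

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

# Bondi-type van der Waals radii (Angstrom), keyed by upper-case element symbol.
BONDI_RADII: Dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "FE": 2.00, "ZN": 1.39, "MG": 1.73, "CA": 2.00, "MN": 2.00, "NA": 2.27, "K": 2.75,
}
FALLBACK_RADIUS = 1.70

THREE_TO_ONE: Dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common modified residues mapped to their parent
    "MSE": "M", "SEC": "U", "PYL": "O", "CSO": "C", "SEP": "S",
    "TPO": "T", "PTR": "Y", "MLY": "K", "HYP": "P",
}

ResidueKey = Tuple[str, int, str]  # (chain_id, author seq number, insertion code)


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be parsed."""


class EmptyStructureError(ValueError):
    """Raised when a parsed entry contains no protein chains."""


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    altloc: str = ""
    vdw_radius: Optional[float] = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")


@dataclass
class Residue:
    key: ResidueKey
    name3: str
    one_letter: str
    atoms: List[Atom] = field(default_factory=list)

    def get_atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Optional[Atom]:
        return self.get_atom("CA")


@dataclass
class Chain:
    id: str
    residues: List[Residue] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class StructureModel:
    entry_id: str
    model_number: int = 1
    chains: List[Chain] = field(default_factory=list)

    def get_chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"{self.entry_id}: no chain {chain_id!r}")

    def iter_atoms(self) -> Iterator[Tuple[Chain, Residue, Atom]]:
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    yield c, r, a

    def subset(self, chain_ids: Iterable[str]) -> "StructureModel":
        """New model restricted to the given chains (atoms are shared)."""
        wanted = list(chain_ids)
        return StructureModel(self.entry_id, self.model_number, [self.get_chain(c) for c in wanted])

    def copy(self) -> "StructureModel":
        chains = [
            Chain(c.id, [
                Residue(r.key, r.name3, r.one_letter,
                        [replace(a, position=a.position.copy()) for a in r.atoms])
                for r in c.residues
            ])
            for c in self.chains
        ]
        return StructureModel(self.entry_id, self.model_number, chains)


@dataclass
class StructureCollection:
    models: List[StructureModel] = field(default_factory=list)
    accession_map: Dict[Tuple[str, str], str] = field(default_factory=dict)

    def get_model(self, entry_id: str) -> StructureModel:
        for m in self.models:
            if m.entry_id == entry_id:
                return m
        raise KeyError(f"no entry {entry_id!r} in collection")


def _one_letter(name3: str) -> str:
    return THREE_TO_ONE.get(name3.upper(), "X")


def _is_amino(res: gemmi.Residue) -> bool:
    if res.het_flag == "W" or res.name in ("HOH", "DOD"):
        return False
    if res.name.upper() in THREE_TO_ONE:
        return True
    info = gemmi.find_tabulated_residue(res.name)
    return bool(info and info.is_amino_acid())


def _dedup_altlocs(atoms: List[Atom]) -> List[Atom]:
    # keep highest occupancy per atom name; ties broken by altloc letter order
    best: Dict[str, Atom] = {}
    for a in atoms:
        prev = best.get(a.name)
        if prev is None or (a.occupancy, _neg_ord(a.altloc)) > (prev.occupancy, _neg_ord(prev.altloc)):
            best[a.name] = a
    kept = [best[a.name] for a in atoms if best[a.name] is a]
    return kept


def _neg_ord(altloc: str) -> float:
    # earlier altloc letters win ties, blank first
    return -ord(altloc) if altloc else 0.0


def read_pdb(path: str | Path, entry_id: Optional[str] = None) -> StructureModel:
    """Parse a PDB file into a :class:`StructureModel`.

    Keeps only the first MODEL of multi-model entries, drops waters, hetero
    compounds and non-amino-acid residues, and keeps the highest-occupancy
    conformer of altloc duplicates.
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    gmodel = st[0]
    model_number = 1

    chains: List[Chain] = []
    for gchain in gmodel:
        residues: List[Residue] = []
        for gres in gchain:
            if not _is_amino(gres):
                continue
            atoms = [
                Atom(
                    name=ga.name,
                    element=ga.element.name.upper(),
                    position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=ga.occ,
                    altloc=(ga.altloc if ga.altloc != "\x00" else ""),
                )
                for ga in gres
            ]
            atoms = _dedup_altlocs(atoms)
            if not atoms:
                continue
            icode = gres.seqid.icode.strip()
            key: ResidueKey = (gchain.name, gres.seqid.num, icode)
            residues.append(Residue(key, gres.name, _one_letter(gres.name), atoms))
        if residues:
            chains.append(Chain(gchain.name, residues))
    if not chains:
        raise EmptyStructureError(f"{path}: no protein chains after filtering")
    return StructureModel(entry_id or (st.name.lower() if st.name else path.stem.lower()),
                          model_number, chains)


def assign_radii(model: StructureModel, radius_table: Optional[Mapping[str, float]] = None,
                 fallback: float = FALLBACK_RADIUS) -> StructureModel:
    """Assign van der Waals radii in place from an element table; idempotent.

    Unknown elements receive ``fallback`` and trigger a warning.
    """
    table = {k.upper(): v for k, v in (radius_table or BONDI_RADII).items()}
    unknown: set[str] = set()
    for _, _, atom in model.iter_atoms():
        r = table.get(atom.element.upper())
        if r is None:
            unknown.add(atom.element)
            r = fallback
        atom.vdw_radius = r
    if unknown:
        logger.warning("no vdW radius for element(s) %s; using fallback %.2f A",
                       sorted(unknown), fallback)
    return model


def write_pdb(model: StructureModel, path: str | Path) -> Path:
    """Serialize a model to fixed-column PDB format (coordinates to 3 decimals)."""
    if not model.chains:
        raise ValueError("cannot write a model with no chains")
    st = gemmi.Structure()
    st.name = model.entry_id.upper()
    gm = gemmi.Model(model.model_number)
    for chain in model.chains:
        if len(chain.id) != 1:
            raise ValueError(f"PDB format requires 1-character chain ids, got {chain.id!r}")
        gc = gemmi.Chain(chain.id)
        for res in chain.residues:
            gr = gemmi.Residue()
            gr.name = res.name3
            gr.seqid = gemmi.SeqId(res.key[1], res.key[2] or " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element.capitalize())
                ga.pos = gemmi.Position(*atom.position)
                ga.occ = atom.occupancy
                ga.altloc = atom.altloc or "\x00"
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    for gchain in st[0]:
        for gres in gchain:
            gres.het_flag = "A"  # always emit ATOM records: content is protein-only
    path = Path(path)
    st.write_pdb(str(path))
    return path


def read_accession_map(path: str | Path) -> Dict[Tuple[str, str], str]:
    """Read a TSV with columns entry_id, chain_id, accession (header optional)."""
    mapping: Dict[Tuple[str, str], str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if parts[0].lower() == "entry_id":
            continue
        if len(parts) < 3:
            raise ValueError(f"accession map line needs 3 columns: {line!r}")
        mapping[(parts[0].lower(), parts[1])] = parts[2]
    return mapping
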
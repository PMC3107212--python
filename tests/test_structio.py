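"""PDB round-trips, model selection, residue filtering and radius assignment."""

import numpy as np
import pytest

from clashscan import synth
from clashscan.structio import (
    BONDI_RADII, EmptyStructureError, StructureModel, assign_radii, read_pdb, write_pdb,
)


def models_equal(a: StructureModel, b: StructureModel, tol=1.5e-3) -> bool:
    if [c.id for c in a.chains] != [c.id for c in b.chains]:
        return False
    for ca, cb in zip(a.chains, b.chains):
        if [r.key for r in ca.residues] != [r.key for r in cb.residues]:
            return False
        if [r.name3 for r in ca.residues] != [r.name3 for r in cb.residues]:
            return False
        for ra, rb in zip(ca.residues, cb.residues):
            if [x.name for x in ra.atoms] != [x.name for x in rb.atoms]:
                return False
            for xa, xb in zip(ra.atoms, rb.atoms):
                if np.abs(xa.position - xb.position).max() > tol:
                    return False
    return True


class TestRoundTrip:
    def test_ideal_chain_roundtrip(self, toy_model, tmp_path):
        path = write_pdb(toy_model, tmp_path / "toy.pdb")
        back = read_pdb(path)
        assert models_equal(toy_model, back)

    def test_two_chain_roundtrip(self, two_chain_model, tmp_path):
        path = write_pdb(two_chain_model, tmp_path / "dimer.pdb")
        assert models_equal(two_chain_model, read_pdb(path))

    def test_coordinates_to_three_decimals(self, tmp_path):
        m = synth.make_sphere_model([[1.23456, 0.0, 0.0]], 1.7)
        text = write_pdb(m, tmp_path / "a.pdb").read_text()
        atom_line = next(l for l in text.splitlines() if l.startswith("ATOM"))
        assert atom_line[30:38].strip() in ("1.234", "1.235")

    def test_empty_model_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_pdb(StructureModel("x", 1, []), tmp_path / "x.pdb")

    def test_long_chain_id_rejected(self, toy_model, tmp_path):
        toy_model.chains[0].id = "AB"
        with pytest.raises(ValueError):
            write_pdb(toy_model, tmp_path / "x.pdb")


class TestParsing:
    def test_first_model_only(self, toy_model, tmp_path):
        """A multi-model file parses identically to a file holding model 1 alone."""
        single = write_pdb(toy_model, tmp_path / "single.pdb")
        body = [l for l in single.read_text().splitlines()
                if l.startswith(("ATOM", "TER"))]
        shifted = [l.replace("0.000", "9.000") for l in body]
        multi = tmp_path / "multi.pdb"
        lines = []
        for k, block in enumerate([body, shifted, shifted, shifted, shifted], start=1):
            lines.append(f"MODEL     {k:>4}")
            lines.extend(block)
            lines.append("ENDMDL")
        lines.append("END")
        multi.write_text("\n".join(lines) + "\n")
        parsed = read_pdb(multi)
        assert parsed.model_number == 1
        assert models_equal(parsed, read_pdb(single))

    def test_waters_and_hetero_excluded(self, toy_model, tmp_path):
        path = write_pdb(toy_model, tmp_path / "t.pdb")
        text = path.read_text().replace("END", "")
        extra = (
            "HETATM  901  O   HOH A 900      11.000  12.000  13.000  1.00  0.00           O\n"
            "HETATM  902  O   HOH A 901      14.000  12.000  13.000  1.00  0.00           O\n"
            "HETATM  903 ZN    ZN A 902      15.000  12.000  13.000  1.00  0.00          ZN\n"
            "END\n")
        mixed = tmp_path / "mixed.pdb"
        mixed.write_text(text + extra)
        parsed = read_pdb(mixed)
        assert len(parsed.chains) == 1
        assert len(parsed.chains[0].residues) == 3

    def test_altloc_highest_occupancy_kept(self, tmp_path):
        lines = [
            "ATOM      1  N  AALA A   1       0.000   0.000   0.000  0.30  0.00           N",
            "ATOM      2  N  BALA A   1       5.000   0.000   0.000  0.70  0.00           N",
            "ATOM      3  CA  ALA A   1       1.500   0.000   0.000  1.00  0.00           C",
            "END",
        ]
        path = tmp_path / "alt.pdb"
        path.write_text("\n".join(lines) + "\n")
        parsed = read_pdb(path)
        res = parsed.chains[0].residues[0]
        n_atoms = [a for a in res.atoms if a.name == "N"]
        assert len(n_atoms) == 1
        assert n_atoms[0].position[0] == pytest.approx(5.0)

    def test_no_protein_chains_is_error(self, tmp_path):
        path = tmp_path / "w.pdb"
        path.write_text(
            "HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\nEND\n")
        with pytest.raises(EmptyStructureError):
            read_pdb(path)

    def test_unparseable_file_is_error(self, tmp_path):
        path = tmp_path / "junk.pdb"
        path.write_text("ATOM this is not fixed column format at all\n")
        with pytest.raises(ValueError):
            read_pdb(path)

    def test_mse_kept_with_parent_code(self, tmp_path):
        lines = [
            "HETATM    1  CA  MSE A   1       0.000   0.000   0.000  1.00  0.00           C",
            "ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C",
            "END",
        ]
        path = tmp_path / "mse.pdb"
        path.write_text("\n".join(lines) + "\n")
        chain = read_pdb(path).chains[0]
        assert chain.sequence == "MG"


class TestRadii:
    def test_uniform_table(self, toy_model):
        assign_radii(toy_model, {"C": 1.7, "N": 1.7, "O": 1.7})
        radii = {a.vdw_radius for _, _, a in toy_model.iter_atoms()}
        assert radii == {1.7}

    def test_fallback_for_unknown_element(self, toy_model, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="clashscan.structio"):
            assign_radii(toy_model, {"C": 1.7})
        assert any(a.vdw_radius == 1.7 for _, _, a in toy_model.iter_atoms())
        assert caplog.records  # unknown N/O logged

    def test_idempotent(self, toy_model):
        assign_radii(toy_model)
        first = [a.vdw_radius for _, _, a in toy_model.iter_atoms()]
        assign_radii(toy_model)
        assert first == [a.vdw_radius for _, _, a in toy_model.iter_atoms()]

    def test_default_table_is_bondi_like(self, toy_model):
        assign_radii(toy_model)
        for _, _, a in toy_model.iter_atoms():
            assert a.vdw_radius == BONDI_RADII[a.element]
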
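import numpy as np
import pytest

from clashscan import synth
from clashscan.structio import Atom, Chain, Residue, StructureModel


@pytest.fixture
def toy_model() -> StructureModel:
    """Three-residue single-chain model with plain backbone atoms."""
    chain = synth.make_ideal_chain("ACD", "A")
    return StructureModel("toy1", 1, [chain])


@pytest.fixture
def two_chain_model() -> StructureModel:
    """Dimer with exactly 6 interface residues on chain A (by construction)."""
    spec = synth.ScenarioSpec(seed=7)
    model_pr, _, _ = synth.make_collision_scenario(spec)
    return model_pr


@pytest.fixture
def scenario():
    """Default collision scenario (P-R, P-S, ground truth)."""
    spec = synth.ScenarioSpec(displacement=(1.5, 0.5, 0.0), seed=11)
    return synth.make_collision_scenario(spec)


def single_atom_model(position, radius, entry_id="atom"):
    return synth.make_sphere_model([position], radius, entry_id=entry_id)
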
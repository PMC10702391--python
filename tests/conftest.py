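import numpy as np
import pytest

from eaatkit.structure import Atom, StructureModel
from eaatkit import synth


@pytest.fixture
def tiny_model() -> StructureModel:
    """Minimal fixture: three protein CA anchors, one ion, one ligand atom."""
    atoms = [
        Atom("A", 366, "SER", "CA", [0.0, 0.0, 0.0]),
        Atom("A", 442, "GLY", "CA", [6.0, 0.0, 0.0]),
        Atom("A", 487, "ASP", "CA", [0.0, 5.0, 0.0]),
        Atom("A", 601, "NA", "NA", [1.0, 5.0, 0.0], hetero=True),
        Atom("A", 500, "ASP", "C1", [3.0, 4.0, 0.0], hetero=True),
    ]
    return StructureModel.from_atoms(atoms, label="tiny fixture")


@pytest.fixture(scope="session")
def small_traj_set():
    """Three small replicates of the toy trimer (shared across tests)."""
    spec = synth.TrajectoryGenSpec(n_frames=60, n_replicates=3,
                                   gate_mean_A=6.0, gate_sd_A=0.2, seed=42)
    return synth.gen_trajectory(spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
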
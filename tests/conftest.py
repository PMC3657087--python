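import warnings

import pytest

from glycotraj.model_io import select
from glycotraj.synthetic import TwoPoseSpec, gen_two_pose_trajectory, \
    gen_ideal_backbones

warnings.filterwarnings("ignore", message="selection .* matched no atoms")


@pytest.fixture(scope="session")
def two_pose():
    """Shared 5000-frame two-pose system (seed 7) with analytic truth."""
    spec = TwoPoseSpec(n_frames=5000, seed=7)
    topology, stream, truth = gen_two_pose_trajectory(spec)
    return spec, topology, stream, truth


@pytest.fixture(scope="session")
def two_pose_selections(two_pose):
    _, topology, _, _ = two_pose
    return {
        "ligand": select("resname GLC", topology),
        "backbone": select("backbone", topology),
        "n5": select("resname FAD and name N5", topology),
    }


@pytest.fixture(scope="session")
def helix():
    return gen_ideal_backbones("helix", 20)


@pytest.fixture(scope="session")
def hairpin():
    return gen_ideal_backbones("hairpin", 16)


@pytest.fixture(scope="session")
def extended():
    return gen_ideal_backbones("extended", 12)


WATER_PDB = """\
ATOM      1  O   HOH A   1       0.000   0.000   0.000  1.00 10.00           O
ATOM      2  H1  HOH A   1       0.957   0.000   0.000  1.00 10.00           H
ATOM      3  H2  HOH A   1      -0.240   0.927   0.000  1.00 10.00           H
CONECT    1    2
CONECT    1    3
END
"""


@pytest.fixture
def water_pdb(tmp_path):
    path = tmp_path / "water.pdb"
    path.write_text(WATER_PDB)
    return path
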
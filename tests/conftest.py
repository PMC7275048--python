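import numpy as np
import pytest

from introntoggle import structio, synth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def helix_structure():
    """Synthetic triple-helix active-site fragment (pre-hydrolytic targets)."""
    return synth.active_site_structure(
        target_d=2.70, target_alpha=0.17, d_k1_n7=4.3, d_m1_m2=4.3, d_m2_o6=5.71
    )


@pytest.fixture
def helix_trajectory(helix_structure):
    return structio.Trajectory.from_structure(helix_structure)


@pytest.fixture
def minimal_pdb_text():
    return (
        "ATOM      1  N7    G A 288      11.104   6.134  -5.504  1.00  0.00           N\n"
        "ATOM      2  O2    C A 289       1.000   2.000   3.000  1.00  0.00           O\n"
        "HETATM    3  K     K A1001       0.500  -0.250   0.125  1.00  0.00           K\n"
        "END\n"
    )


def random_rigid_transform(rng):
    """A uniformly random proper rotation plus a random translation."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    return rot.as_matrix(), rng.normal(0, 5.0, 3)
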
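import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from pepion.synth import default_toy_params, generate_labeled_ensembles


@pytest.fixture(scope="session")
def toy_params():
    return default_toy_params()


@pytest.fixture(scope="session")
def suite_seed1():
    """The full labeled benchmark suite at seed 1, shared across tests."""
    return generate_labeled_ensembles(seed=1)


@pytest.fixture(scope="session")
def small_suite(tmp_path_factory):
    """A reduced on-disk suite (two ligands) for pipeline/CLI tests."""
    from pepion.synth import generate_benchmark_suite

    out = tmp_path_factory.mktemp("suite")
    generate_benchmark_suite(seed=3, out_dir=out, ligands=("Ala", "Ser"))
    return out


def random_rigid_motion(rng: np.random.Generator):
    """A uniformly random proper rotation matrix and a translation vector."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    return rot.as_matrix(), rng.uniform(-5, 5, size=3)
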
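import numpy as np
import pytest

from emsharp.fixtures import FragmentSpec, build_helix
from emsharp.models import Atom, AtomicModel
from emsharp.simulate import SimulationConfig, model_to_map


@pytest.fixture(scope="session")
def small_helix() -> AtomicModel:
    """A 12-residue poly-Ala helix at B = 30 Å²."""
    return build_helix(FragmentSpec("alpha", "A" * 12, b_iso=30.0))


@pytest.fixture(scope="session")
def small_helix_map(small_helix):
    """Map of the 12-residue helix on a 48 Å / 1 Å grid."""
    cfg = SimulationConfig(box_edge=48.0, voxel_size=1.0)
    return model_to_map(small_helix, cfg)


@pytest.fixture(scope="session")
def single_carbon() -> AtomicModel:
    return AtomicModel([Atom("C", np.zeros(3), 0.0)])


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
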
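import numpy as np
import pytest

import detrack
from detrack.phantom import AcquisitionSpec, Ellipsoid, PhantomSpec


@pytest.fixture(scope="session")
def default_phantom():
    return detrack.default_phantom()


@pytest.fixture(scope="session")
def small_acq():
    """Full-resolution detector but a short arc, to keep runtimes down."""
    return AcquisitionSpec(n_pairs=6)


@pytest.fixture(scope="session")
def tumor_only_phantom():
    """A bare spherical tumor in vacuum: projections depend only on the tumor."""
    return PhantomSpec(
        volume_extent=(100.0, 100.0, 100.0),
        primitives=[Ellipsoid((0.0, 0.0, 0.0), (10.0, 10.0, 10.0), "tumor")],
        mu={("tumor", "high"): 0.022, ("tumor", "low"): 0.030},
    )


@pytest.fixture(scope="session")
def noisefree_sequence(default_phantom, small_acq):
    motion = detrack.default_motion()
    pairs, gt = detrack.simulate_sequence(default_phantom, motion, small_acq, noise=False)
    return pairs, gt


@pytest.fixture(scope="session")
def template_bank(default_phantom, small_acq):
    return detrack.generate_templates(default_phantom, range(0, 181), small_acq)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
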
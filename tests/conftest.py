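import numpy as np
import pytest

from smdmap.confinement import REFERENCE_CELL, simulated_displacements


@pytest.fixture(scope="session")
def reference_displacements():
    """Lag-15 displacements of a D=5 um^2/s walk in the median cell.

    Shared by mapping/segmentation/statistics tests to avoid repeating
    the most expensive simulation.
    """
    return simulated_displacements(5.0, REFERENCE_CELL, n_particles=25, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
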
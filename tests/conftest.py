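"""Shared fixtures: all inputs are generated programmatically."""

import numpy as np
import pytest

from thermogate import synth
from thermogate.structures import RadiiSet


@pytest.fixture(scope="session")
def radii_set():
    return RadiiSet()


@pytest.fixture(scope="session")
def ring_stack():
    """Analytic cylinder: pore radius 3.3 Å at every ring plane."""
    return synth.make_ring_stack(ring_radius=5.0, atom_radius=1.7,
                                 n_rings=10, spacing=2.0, atoms_per_ring=12)


@pytest.fixture(scope="session")
def hourglass():
    """Analytic hourglass with a 0.7 Å neck at z = 0."""
    return synth.make_hourglass(neck_radius=0.7, mouth_radius=5.0,
                                half_length=10.0)


@pytest.fixture(scope="session")
def bundle():
    """C4 helix bundle with a perturbable loop; (structure, LoopSpec)."""
    return synth.make_c4_bundle()


@pytest.fixture
def random_cluster():
    """Factory for seeded 20-atom clusters used in SASA comparisons."""
    def make(seed, n=20, box=4.0, radius=1.7):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(-box, box, size=(n, 3))
        return synth._structure_from_coords(coords, radius,
                                            np.arange(1, n + 1))
    return make
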
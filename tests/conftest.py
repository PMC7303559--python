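import numpy as np
import pytest

from ntba.engine import ChemicalPotential
from ntba.motifs import MotifMatrix, to_energy

BOLTZMANN = ChemicalPotential("boltzmann")
FD0 = ChemicalPotential("fermi_dirac", 0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def simple_motif():
    """Width-4 count motif with consensus ACGT."""
    values = np.array([
        [9, 1, 1, 1],
        [1, 9, 1, 1],
        [1, 1, 9, 1],
        [1, 1, 1, 9],
    ], dtype=float)
    return MotifMatrix(id="simple", values=values)


@pytest.fixture
def simple_energy(simple_motif):
    return to_energy(simple_motif)


@pytest.fixture
def flat_energy():
    """All-equal columns: every site scores identically (energy 0)."""
    return to_energy(MotifMatrix(id="flat", values=np.full((4, 4), 0.25)))


def random_dna(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))
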
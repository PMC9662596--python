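import numpy as np
import pytest

from sml.chemdata import Dataset, Molecule
from sml.synthetic import GeneratorParams, make_benchmark


@pytest.fixture(scope="session")
def small_bench():
    """300-molecule synthetic benchmark shared by protocol-level tests."""
    return make_benchmark(GeneratorParams(n_per_class=(100, 100, 100), seed=11))


@pytest.fixture(scope="session")
def full_bench():
    """Full-size study conditions: 1500 molecules, default generator."""
    return make_benchmark(GeneratorParams(seed=1))


@pytest.fixture()
def methane():
    # tetrahedral CH4, C-H 1.09 Å
    a = 1.09 / np.sqrt(3.0)
    return Molecule(
        id="ch4",
        smiles="C",
        elements=["C", "H", "H", "H", "H"],
        coords=np.array(
            [[0, 0, 0], [a, a, a], [a, -a, -a], [-a, a, -a], [-a, -a, a]]
        ),
    )


@pytest.fixture()
def h2():
    return Molecule(
        id="h2", smiles="[H][H]", elements=["H", "H"],
        coords=np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.74]]),
    )


@pytest.fixture()
def tiny_dataset(methane, h2):
    return Dataset(molecules=[methane, h2])
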
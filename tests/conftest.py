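import pytest

import sharedrep as sr
from sharedrep.simulate import plant_patterns, simulate_subjects


@pytest.fixture(scope="session")
def small_grid():
    return sr.make_grid((6, 6, 6))


@pytest.fixture(scope="session")
def planted_truth(small_grid):
    return plant_patterns(small_grid, 30, 20, 20, 20, seed=1)


@pytest.fixture(scope="session")
def small_dataset(planted_truth):
    return simulate_subjects(planted_truth, 20, seed=2)


@pytest.fixture(scope="session")
def null_truth(small_grid):
    return plant_patterns(small_grid, 0, 0, 0, 0, seed=1)
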
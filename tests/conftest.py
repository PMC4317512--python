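import numpy as np
import pytest

import breedsim as bs


@pytest.fixture(scope="session")
def study_fixture():
    """The packaged 23-locus study fixture (map, parents, target, effects)."""
    return bs.load_study_fixture()


@pytest.fixture(scope="session")
def scenario_effects():
    return bs.load_scenario_effects()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def cross(study_fixture):
    """Factory: (parent1, parent2, target restricted to segregating loci)."""

    def _get(p1: str, p2: str):
        a, b = study_fixture.parents[p1], study_fixture.parents[p2]
        return a, b, study_fixture.target.restrict_to_segregating(a, b)

    return _get
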
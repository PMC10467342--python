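import numpy as np
import pytest

from natzone import SedimentNitrogenModel, scenario_from_dict


@pytest.fixture(scope="session")
def ref_model():
    """The packaged GS13-CC2-like reference scenario (400 cells, 4 m)."""
    return SedimentNitrogenModel.from_reference()


@pytest.fixture(scope="session")
def ref_results(ref_model):
    res = ref_model.solve()
    assert res.converged
    return res


@pytest.fixture(scope="session")
def coarse_model():
    """A 100-cell version of the reference scenario for cheap forward runs."""
    return SedimentNitrogenModel(scenario_from_dict({"grid": {"n_cells": 100}}))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
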
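import numpy as np
import pytest

from grainfill.design import DEFAULT_IONOME_DESIGN
from grainfill.kinetics import fit_logistic
from grainfill.simulate import ElementArchetype, simulate_grain_series


@pytest.fixture
def ionome_design():
    return DEFAULT_IONOME_DESIGN


@pytest.fixture
def mid_archetype():
    return ElementArchetype("X", "mid", a=25.0, k=0.25, x_c=13.0, unit="ug",
                            noise_cv=0.0)


@pytest.fixture
def noiseless_series(mid_archetype):
    return simulate_grain_series(mid_archetype, seed=0)


@pytest.fixture
def noiseless_fit(noiseless_series):
    res = fit_logistic(noiseless_series)
    assert res.converged
    return res
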
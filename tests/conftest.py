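import numpy as np
import pytest

from drsviab.colecole import ColeColeParams, evaluate_model
from drsviab.simulate import build_state_library
from drsviab.spectra import FrequencyGrid, PermittivitySpectrum, SpecimenMeta, default_grid


@pytest.fixture(scope="session")
def grid167():
    return default_grid()


@pytest.fixture(scope="session")
def library():
    return build_state_library()


@pytest.fixture(scope="session")
def control_params(library):
    return library["Control"]


def noiseless_spectrum(params: ColeColeParams, grid: FrequencyGrid, meta=None):
    eps = evaluate_model(params, grid)
    return PermittivitySpectrum(grid, eps.real, -eps.imag, meta)


@pytest.fixture(scope="session")
def control_spectrum(control_params, grid167):
    return noiseless_spectrum(control_params, grid167)


@pytest.fixture
def meta_control():
    return SpecimenMeta(subject_id="pig01", case_id=1, phase="control")
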
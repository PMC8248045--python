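import numpy as np
import pytest

from ecosunpass.registry import (
    canonical_dossiers,
    canonical_spectra,
    example_formulations,
)


@pytest.fixture(scope="session")
def dossiers():
    return canonical_dossiers(seed=12345)


@pytest.fixture(scope="session")
def spectra():
    return canonical_spectra()


@pytest.fixture(scope="session")
def formulations():
    return {f.name: f for f in example_formulations()}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
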
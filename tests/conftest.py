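import numpy as np
import pytest

from tetherloc import synthetic_data as sd


@pytest.fixture(scope="session")
def toy_complex():
    """Small tethered two-domain complex shared by read-only tests."""
    spec = sd.ToyComplexSpec(n_core_residues=60, n_mobile_residues=40, seed=7)
    return sd.make_toy_complex(spec)


@pytest.fixture(scope="session")
def assembled(toy_complex):
    core, mobile, truth = toy_complex
    return sd.assemble(core, mobile, truth)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
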
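import warnings

import numpy as np
import pytest

from telostress.synthetic_data import gen_expression, gen_network, gen_screen


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Generators and SAM emit advisory warnings (enumerated permutations,
    small samples) that are themselves under test elsewhere."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def planted_bundle():
    """One expression bundle with 5% planted DE at 3*sigma (single stress)."""
    bundle, truth = gen_expression(
        n_genes=1000, stresses=["ethanol"], de_fraction=0.05,
        effect=1.5, sigma=0.5, seed=11,
    )
    return bundle, truth


@pytest.fixture(scope="session")
def planted_network():
    return gen_network(planted=True, seed=11)


@pytest.fixture(scope="session")
def clean_screen():
    return gen_screen(n_mutants=100, outlier_fraction=0.0, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(11)
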
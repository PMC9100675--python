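import numpy as np
import pytest

from thoraseg.phantom import PhantomSpec, generate_case


@pytest.fixture(scope="session")
def coherent_case():
    """One coherent phantom with nodules, shared across tests (read-only)."""
    return generate_case(PhantomSpec(protocol="coherent", seed=11, n_nodules=3, peripheral_fraction=0.34))


@pytest.fixture(scope="session")
def defective_cases():
    """One phantom per defective annotation protocol, same geometry seed."""
    return {
        proto: generate_case(PhantomSpec(protocol=proto, seed=5, n_nodules=3, peripheral_fraction=0.34))
        for proto in ("nodules_excluded", "trachea_included", "auto_noisy")
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
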
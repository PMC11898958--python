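import numpy as np
import pytest
from hypothesis import settings

import bioqsrr as b

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    return b.organophosphate_table()


@pytest.fixture(scope="session")
def ref_models():
    return {m.endpoint_name: m for m in b.reference_models()}


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture()
def small_synth():
    """12 compounds, 8 descriptors, exact 2-descriptor signal."""
    X = b.generate_descriptors(12, 8, seed=7)
    ds = b.generate_response(X, support_size=2, effect_scale=1.0, noise_sd=0.0, seed=7)
    return ds
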
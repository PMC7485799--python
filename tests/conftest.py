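import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from protonseq.kinetics import SolutionConditions, default_pka_table

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def ph3():
    return SolutionConditions(ph=3.0)


@pytest.fixture(scope="session")
def pka_table():
    return default_pka_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
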
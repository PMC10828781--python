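import numpy as np
import pytest

from bloodpeach.sim import Edit, build_pav_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def pav_fixture():
    """Small planted-element fixture shared by LTR tests: 12 elements
    cycling keep / delete_element / delete_flank / degrade-to-85%."""
    actions = ["keep", "delete_element", "delete_flank",
               Edit("degrade_element", identity=0.85)]
    return build_pav_fixture(12, actions, seed=7, per_ltr_divergence=0.01)
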
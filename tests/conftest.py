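import numpy as np
import pytest

import ppa


@pytest.fixture(scope="session")
def clock():
    return ppa.build_clock_model()


@pytest.fixture(scope="session")
def clock_results():
    """The packaged headline clock analysis (delta=0.1, entrained cycle)."""
    return ppa.clock_reference_analysis()


@pytest.fixture(scope="session")
def toy_linear():
    return ppa.build_toy_linear()


@pytest.fixture(scope="session")
def toy_feedback():
    return ppa.build_toy_feedback()


@pytest.fixture(scope="session")
def toy_feedback_results():
    return ppa.PrincipalProcessAnalysis(ppa.build_toy_feedback(), delta=0.1,
                                        grid_step=0.01).fit(compute_errors=False)
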
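import numpy as np
import pytest
from hypothesis import settings

from noradscope import get_preset
from noradscope.pipeline import analyze_twop_cohort
from noradscope.synth import gen_twop_cohort

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def wt_cohort():
    """The control-like two-photon cohort preset with its ground truth."""
    return gen_twop_cohort(get_preset("wt_fig2"))


@pytest.fixture(scope="session")
def wt_analysis(wt_cohort):
    """Full default-parameter analysis of the control-like cohort."""
    recordings, _ = wt_cohort
    return analyze_twop_cohort(recordings)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
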
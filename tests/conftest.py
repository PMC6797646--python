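import numpy as np
import pytest
from hypothesis import settings

import eamsim as es

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

# 1% critical value of the equal-n two-sample KS statistic
KS_CRIT_1PCT = lambda n: 1.628 * np.sqrt(2.0 / n)


@pytest.fixture(scope="session")
def fine_lut():
    """Recommended-default table: granularity 1e-4, 9999 entries."""
    return es.build_lut(1e-4)
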
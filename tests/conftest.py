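import numpy as np
import pytest

import restensim as rs


@pytest.fixture
def default_config():
    return rs.VesselConfig(struts_per_stent=20)


@pytest.fixture
def kimura_state(default_config):
    """Freshly built post-intervention cross-section (2.9 mm scenario)."""
    return rs.build_initial_state(default_config, rng=np.random.default_rng(0))
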
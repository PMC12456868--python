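import numpy as np
import pytest

from plaquefp import synthgen, workbench


@pytest.fixture
def flat_protocol():
    return workbench.flat_protocol()


@pytest.fixture
def tf_protocol():
    # short scan interval keeps unit-test recordings small
    return workbench.tf_protocol(scan_interval_s=60.0)


@pytest.fixture
def geometry():
    return synthgen.TaperGeometry()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
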
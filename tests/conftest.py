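import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from xciskew.humara import PeakPair, SampleAssay

settings.register_profile(
    "ci",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_assay(replicate_values, sample_id="S1", sizes=(280.0, 289.0)):
    """Build a triplicate assay whose replicate XCI values equal the given list.

    Mock heights are balanced (1000, 1000) so Rm = 1 and the HpaII ratio
    alone sets the replicate XCI: h1/h2 = v / (100 - v).
    """
    mocks, hpaiis = [], []
    for v in replicate_values:
        mocks.append(PeakPair(sizes[0], sizes[1], 1000.0, 1000.0))
        h2 = 1000.0
        h1 = h2 * v / (100.0 - v) if v < 100 else 1e9
        hpaiis.append(PeakPair(sizes[0], sizes[1], h1, h2))
    return SampleAssay(sample_id=sample_id, mock_replicates=mocks,
                       hpaii_replicates=hpaiis,
                       mspi_peaks=PeakPair(sizes[0], sizes[1], 0.0, 0.0))
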
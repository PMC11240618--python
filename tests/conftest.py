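import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from caflux.traceio import CellTrace

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def make_trace():
    """Build a CellTrace from raw values on a 5-s grid."""

    def _make(values, cell_id="c0", channel="fura_ratio", interval=5.0):
        values = np.asarray(values, dtype=float)
        times = np.arange(values.size, dtype=float) * interval
        return CellTrace(cell_id=cell_id, times=times, values=values, channel=channel)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
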
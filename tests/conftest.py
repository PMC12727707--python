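import numpy as np
import pytest

from circaclust.types import EpochSeries


@pytest.fixture
def make_series():
    """Factory for small epoch series with constant defaults."""

    def _make(enmo, epoch_len_s=60, start="2022-06-01T12:00:00", wear=None,
              pid="P0"):
        enmo = np.asarray(enmo, dtype=float)
        if wear is None:
            wear = np.ones(enmo.size, dtype=bool)
        return EpochSeries(pid, np.datetime64(start, "s"), epoch_len_s, enmo, wear)

    return _make


@pytest.fixture
def day_night_series(make_series):
    """One noon-to-noon day: 40 mg waking, zero sleep 22:00-06:00."""
    enmo = np.full(1440, 40.0)
    # series starts at noon; 22:00 is epoch 600, 06:00 is epoch 1080
    enmo[600:1080] = 0.0
    return make_series(enmo), 600, 1080
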
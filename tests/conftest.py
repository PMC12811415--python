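import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from smlmclust.io import Channel, LocalizationTable


def make_table(x, y, channel=Channel.A_AF647, uncertainty=None, frame=None, field_extent=None):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    return LocalizationTable(
        x=x,
        y=y,
        frame=np.ones(n, dtype=np.int64) if frame is None else np.asarray(frame),
        uncertainty=np.full(n, 15.0) if uncertainty is None else np.asarray(uncertainty, dtype=float),
        channel=channel,
        field_extent=field_extent,
    )


def random_table(rng, n, extent=(10000.0, 10000.0), channel=Channel.A_AF647):
    return make_table(
        rng.uniform(0, extent[0], n),
        rng.uniform(0, extent[1], n),
        channel=channel,
        uncertainty=rng.uniform(5, 40, n),
        frame=rng.integers(1, 15000, n),
        field_extent=extent,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
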
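import numpy as np
import pytest

from gammaplane.accel_io import MagnitudeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_series(values, participant="p1", day=1, session=1):
    """MagnitudeSeries with uniform provenance tags."""
    values = np.asarray(values, dtype=float)
    return MagnitudeSeries(
        participant_id=participant,
        values=values,
        provenance=[(day, session)] * len(values),
    )


@pytest.fixture
def series_factory():
    return make_series
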
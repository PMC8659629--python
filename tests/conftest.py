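import numpy as np
import pytest

from filmrelease.kinetics import ReleaseCurve

#: Canonical seed used across the suite for every stochastic check.
SEED = 0


def fraction_curve(times, fractions, sample_id="test"):
    return ReleaseCurve(
        sample_id=sample_id,
        times=np.asarray(times, float),
        values=np.asarray(fractions, float),
        value_kind="fraction",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)
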
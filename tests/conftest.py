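import numpy as np
import pytest

from ontopace import CurveParams, DisplacementSeries, generate_individual_series


@pytest.fixture
def rng():
    return np.random.default_rng(20230412)


@pytest.fixture
def linear_series():
    """Noisy linear-trend series (fixed seed)."""
    return generate_individual_series(
        CurveParams("linear", (0.2, 0.02)), 60, 0.3, seed=11,
        individual="lin", group="test",
    )


def make_series(individual, group, day, km):
    return DisplacementSeries(
        individual=individual, group=group,
        day=np.asarray(day), km=np.asarray(km, dtype=float),
    )
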
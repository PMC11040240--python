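import numpy as np
import pytest
from hypothesis import settings

from roostfinder.survey_io import Detector, SurveySet

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def make_survey(positions, total_calls, nights=1, roost=None) -> SurveySet:
    """Build a SurveySet directly from arrays (test helper)."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    total_calls = np.asarray(total_calls, dtype=int)
    nights = np.broadcast_to(np.asarray(nights, dtype=int), total_calls.shape)
    detectors = [
        Detector(
            id=f"d{i}",
            easting=float(x),
            northing=float(y),
            nights_active=int(nights[i]),
            total_calls=int(total_calls[i]),
        )
        for i, (x, y) in enumerate(positions)
    ]
    return SurveySet(detectors=detectors, roost_known=roost)


@pytest.fixture
def ring_positions():
    """20 detectors on a 1.5 km radius ring (3 km extent)."""
    theta = 2 * np.pi * np.arange(20) / 20
    return 1500.0 * np.stack([np.cos(theta), np.sin(theta)], axis=1)


@pytest.fixture
def ring_survey(ring_positions):
    """A noiseless survey whose counts follow the forward model exactly
    (equal counts by symmetry: every detector is equidistant from centre)."""
    return make_survey(ring_positions, np.full(20, 50), nights=1, roost=(0.0, 0.0))
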
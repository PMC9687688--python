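import datetime as dt

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from wavetap import (
    FeatureMatrix,
    KeystrokeEvent,
    SubjectLog,
    separated_scenario,
    simulate_cohort,
)


def make_log(subject_id="s1", label="healthy", events=None):
    """Hand-built log: fixed regions/timings, strictly increasing times."""
    if events is None:
        spec = [
            ("L", "LL", 100.0, 150.0, 80.0),
            ("L", "LL", 200.0, 160.0, 90.0),
            ("R", "LR", 300.0, 170.0, 100.0),
            ("R", "RR", 120.0, 180.0, 110.0),
            ("S", "RS", 50.0, 190.0, 120.0),
            ("L", "SL", 140.0, 200.0, 130.0),
        ]
        events = [
            KeystrokeEvent(
                subject_id=subject_id,
                date=dt.date(2020, 1, 6),
                time=dt.time(9, 0, i, 500000),
                region=r,
                hold_time=h,
                transition=tr,
                latency=lat,
                flight=fl,
            )
            for i, (r, tr, h, lat, fl) in enumerate(spec)
        ]
    return SubjectLog(subject_id=subject_id, label=label, events=events)


@pytest.fixture
def tiny_log():
    return make_log()


@pytest.fixture
def small_cohort():
    """Six-subject balanced cohort with strong class separation."""
    return simulate_cohort(separated_scenario(n_per_class=3, seed=7))


@pytest.fixture
def random_matrix():
    rng = np.random.default_rng(3)
    n_maj, n_min = 30, 12
    values = np.vstack(
        [rng.normal(0, 1, size=(n_maj, 6)), rng.normal(3, 1, size=(n_min, 6))]
    )
    labels = np.array(["parkinson"] * n_maj + ["healthy"] * n_min, dtype=object)
    sids = np.array([f"s{i}" for i in range(n_maj + n_min)], dtype=object)
    return FeatureMatrix(values, [f"f{i}" for i in range(6)], labels, sids)
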
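import logging

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from carbonylome import InjectionSchedule, generate_batch, make_schedule
from carbonylome.io import CONTROL, QC, TREATED


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    """Keep expected clamp/skip warnings out of the test output."""
    caplog.set_level(logging.ERROR)
    yield


@pytest.fixture(scope="session")
def schedule():
    return make_schedule(seed=7)


@pytest.fixture(scope="session")
def small_batch():
    """A 12-feature batch with all four kinetic classes."""
    sched = make_schedule(seed=7)
    records, truths = generate_batch(
        sched,
        n_features=12,
        class_counts={"I": 3, "II": 4, "III": 2, "steady": 3},
        seed=7,
    )
    return sched, records, truths


@pytest.fixture()
def toy_schedule():
    """Two QCs bracketing four samples on a tiny grid."""
    return InjectionSchedule((
        ("QC01", 0.0, QC),
        ("C01", 10.0, CONTROL),
        ("T01", 20.0, TREATED),
        ("C02", 30.0, CONTROL),
        ("T02", 40.0, TREATED),
        ("QC02", 50.0, QC),
    ))
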
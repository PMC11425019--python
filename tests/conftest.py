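"""Shared fixtures: small hand-built logs and one simulated study."""

from __future__ import annotations

import datetime as dt

import pytest

from appuse.event_model import (
    AnalysisConfig,
    MSStatus,
    ParticipantRecord,
    Test,
    TestEvent,
    validate_log,
)
from appuse.synthetic_data import UTC, SimulationConfig, simulate_study

ACT = dt.date(2019, 1, 2)


def make_record(pid: str, activation: dt.date | None = ACT, ms: MSStatus = MSStatus.MS) -> ParticipantRecord:
    reg = activation or ACT
    return ParticipantRecord(
        participant_id=pid,
        registration_date=reg,
        consent_date=reg if activation is not None else None,
        activation_date=activation,
        ms_status=ms,
    )


def make_event(pid: str, day_offset: int, test: Test, hour: int = 12, anchor: dt.date = ACT) -> TestEvent:
    d = anchor + dt.timedelta(days=day_offset)
    return TestEvent(pid, dt.datetime(d.year, d.month, d.day, hour, 0, tzinfo=UTC), test)


def events_for_days(pid: str, day_offsets, tests, anchor: dt.date = ACT) -> list[TestEvent]:
    out = []
    for off in day_offsets:
        for i, t in enumerate(tests):
            d = anchor + dt.timedelta(days=off)
            out.append(TestEvent(pid, dt.datetime(d.year, d.month, d.day, 12, i, tzinfo=UTC), t))
    return out


@pytest.fixture(scope="session")
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def simulated_study():
    """One deterministic paper-like study dataset shared across tests."""
    return simulate_study(SimulationConfig(seed=20240911))


@pytest.fixture(scope="session")
def simulated_log(simulated_study):
    log, report = validate_log(simulated_study.registry, simulated_study.events)
    assert not report.quarantined
    return log
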
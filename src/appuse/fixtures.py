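"""Desk-scale fixture construction from published summary counts.

The study that motivates this package reported every headline rate with its
numerator and denominator (conversion funnels, day-n retention tables,
day-1 completion rates).  Under the default retention definition the
retention curve is the complementary cumulative distribution of each
participant's last active day, so a printed retention row determines a
last-active-day multiset exactly; this module reverses that mapping and
builds a minimal synthetic registry/event log whose pipeline output
reproduces the printed numbers.  Every dataset built here is synthetic: it
realizes the published counts, not the underlying participant data.
"""

from __future__ import annotations

import datetime as dt
from typing import Mapping, Optional, Sequence

from .event_model import MSStatus, ParticipantRecord, TestEvent
from .sessionization import Series
from .synthetic_data import DA_REQUIRED, DAX_REQUIRED, UTC
from .event_model import Test

# Published summary counts (numerator/denominator) used as worked examples.
REPORTED_FUNNELS = {
    "original_journey": {"registered": 608, "consented": 608, "activated": 328},  # 53.9%
    "seamless_journey": {"registered": 481, "consented": 481, "activated": 359},  # 74.6%
}

#: Day-n retention numerators by cohort and series (denominators 350 / 172).
REPORTED_RETENTION = {
    "without_reminders": {
        "N": 350,
        Series.DA: {1: 216, 3: 112, 7: 82, 14: 57, 30: 34},
        Series.DAx: {1: 290, 3: 171, 7: 121, 14: 98, 30: 60},
        Series.TwoMWT: {1: 113, 3: 64, 7: 50, 14: 39, 30: 22},
    },
    "with_reminders": {
        "N": 172,
        Series.DA: {1: 113, 3: 63, 7: 56, 14: 53, 30: 53},
        Series.DAx: {1: 137, 3: 88, 7: 63, 14: 53, 30: 53},
        Series.TwoMWT: {1: 70, 3: 56, 7: 49, 14: 42, 30: 39},
    },
}

#: Participants with >= 1 completed series (the day-1 completion-rate counts).
REPORTED_ANY_SERIES = {
    "without_reminders": {Series.DA: 234, Series.DAx: 301, Series.TwoMWT: 122},
    "with_reminders": {Series.DA: 113, Series.DAx: 140, Series.TwoMWT: 72},
}

_FIXTURE_ACTIVATION = {
    "without_reminders": dt.date(2019, 1, 2),
    "with_reminders": dt.date(2020, 3, 2),
}


def funnel_registry(
    n_registered: int,
    n_consented: int,
    n_activated: int,
    registration_date: dt.date,
    id_prefix: str = "F",
) -> list[ParticipantRecord]:
    """A registry realizing given nested milestone counts on one date."""
    if not n_registered >= n_consented >= n_activated >= 0:
        raise ValueError("milestone counts must be nested")
    out = []
    for i in range(n_registered):
        consented = i < n_consented
        activated = i < n_activated
        out.append(
            ParticipantRecord(
                participant_id=f"{id_prefix}{i:05d}",
                registration_date=registration_date,
                consent_date=registration_date if consented else None,
                activation_date=registration_date if activated else None,
            )
        )
    return out


def last_day_multiset(
    day_counts: Mapping[int, int], n_any: int, cohort_size: int
) -> list[Optional[int]]:
    """Last-active-day per participant (descending; None = no completion).

    ``day_counts[d]`` is the number of participants retained at day d
    (last active day >= d); ``n_any`` the number with >= 1 completion.
    """
    days = sorted(day_counts, reverse=True)
    values: list[Optional[int]] = []
    prev_count = 0
    for d in days:
        c = day_counts[d] - prev_count
        if c < 0:
            raise ValueError("retained counts must be non-increasing in day")
        values.extend([d] * c)
        prev_count = day_counts[d]
    n_day0_only = n_any - prev_count
    if n_day0_only < 0:
        raise ValueError("n_any must be >= retained count at the earliest day")
    values.extend([0] * n_day0_only)
    if len(values) > cohort_size:
        raise ValueError("counts exceed cohort size")
    values.extend([None] * (cohort_size - len(values)))
    return values


def _series_day_events(pid: str, day: dt.date, series: Series, minute: int) -> list[TestEvent]:
    if series == Series.DA:
        tests: Sequence[Test] = (*DA_REQUIRED, Test.IPS)
    elif series == Series.DAx:
        tests = (*DAX_REQUIRED, Test.IPS)
    else:
        tests = (Test.TwoMWT,)
    base = dt.datetime(day.year, day.month, day.day, 12, minute, tzinfo=UTC)
    return [TestEvent(pid, base + dt.timedelta(seconds=30 * k), t) for k, t in enumerate(tests)]


def cohort_fixture(
    cohort_size: int,
    retention_counts: Mapping[Series, Mapping[int, int]],
    any_series_counts: Mapping[Series, int],
    activation_date: dt.date,
    id_prefix: str = "R",
) -> tuple[list[ParticipantRecord], list[TestEvent]]:
    """Build a registry/event log realizing printed retention and
    completion-rate counts for all three series at once.

    DA and DAx last days are paired in descending order, which preserves
    the structural constraint that a DA completion day is also a DAx
    completion day (possible because the printed DAx counts dominate the DA
    counts at every day).  Participants with no completions at all get a
    single mood-questionnaire event on the activation day so that they
    count as study activity (cohort denominator) without completing any
    series.
    """
    da = last_day_multiset(retention_counts[Series.DA], any_series_counts[Series.DA], cohort_size)
    dax = last_day_multiset(retention_counts[Series.DAx], any_series_counts[Series.DAx], cohort_size)
    mwt = last_day_multiset(
        retention_counts[Series.TwoMWT], any_series_counts[Series.TwoMWT], cohort_size
    )
    registry: list[ParticipantRecord] = []
    events: list[TestEvent] = []
    for i in range(cohort_size):
        pid = f"{id_prefix}{i:05d}"
        registry.append(
            ParticipantRecord(
                participant_id=pid,
                registration_date=activation_date,
                consent_date=activation_date,
                activation_date=activation_date,
                ms_status=MSStatus.MS,
            )
        )
        d_da, d_dax, d_mwt = da[i], dax[i], mwt[i]
        if d_da is not None and (d_dax is None or d_dax < d_da):
            raise ValueError(
                "printed DAx retention must dominate DA retention; pairing failed"
            )
        if d_da is not None:
            events.extend(
                _series_day_events(pid, activation_date + dt.timedelta(days=d_da), Series.DA, 0)
            )
        if d_dax is not None and d_dax != d_da:
            events.extend(
                _series_day_events(pid, activation_date + dt.timedelta(days=d_dax), Series.DAx, 10)
            )
        if d_mwt is not None:
            events.extend(
                _series_day_events(pid, activation_date + dt.timedelta(days=d_mwt), Series.TwoMWT, 20)
            )
        if d_da is None and d_dax is None and d_mwt is None:
            events.append(
                TestEvent(
                    pid,
                    dt.datetime(
                        activation_date.year, activation_date.month, activation_date.day,
                        12, 30, tzinfo=UTC,
                    ),
                    Test.DMQ,
                )
            )
    events.sort(key=lambda e: (e.participant_id, e.timestamp.isoformat()))
    return registry, events


def reported_cohort_fixture(cohort: str) -> tuple[list[ParticipantRecord], list[TestEvent]]:
    """The fixture realizing the published retention table for one cohort
    ('without_reminders' or 'with_reminders'), activation-dated inside the
    matching study window."""
    table = REPORTED_RETENTION[cohort]
    return cohort_fixture(
        cohort_size=table["N"],
        retention_counts={s: table[s] for s in Series},
        any_series_counts=REPORTED_ANY_SERIES[cohort],
        activation_date=_FIXTURE_ACTIVATION[cohort],
        id_prefix="W" if cohort == "without_reminders" else "N",
    )


def reported_study_fixture() -> tuple[list[ParticipantRecord], list[TestEvent]]:
    """Both reminder cohorts combined into one registry/event log."""
    reg_wo, ev_wo = reported_cohort_fixture("without_reminders")
    reg_w, ev_w = reported_cohort_fixture("with_reminders")
    return reg_wo + reg_w, sorted(
        ev_wo + ev_w, key=lambda e: (e.participant_id, e.timestamp.isoformat())
    )
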
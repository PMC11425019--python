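"""Day-level aggregation of test events and series-completion detection.

A *series completion* is the unit every engagement metric counts: a
(participant, calendar day, series) triple.  Three series are tracked:

* ``DA``   - the full fixed daily sequence (DMQ, IPS, IPS Digit-Digit, PT,
  DaS, SBT, UTT).  The IPS has a weekly cadence, so by default it credits
  the series if completed within the trailing ``ips_weekly_window_days``.
* ``DAx``  - DA without the balance/gait tests (SBT, UTT).
* ``TwoMWT`` - the Two-Minute Walk Test on its own.

Because DAx's requirements are a subset of DA's, every DA completion day is
also a DAx completion day; downstream metrics rely on this dominance.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import enum
from collections import defaultdict
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .event_model import AnalysisConfig, StudyLog, Test


class Series(str, enum.Enum):
    DA = "DA"
    DAx = "DAx"
    TwoMWT = "TwoMWT"


@dataclasses.dataclass(frozen=True)
class DailyActivityProfile:
    """The set of tests one participant completed on one calendar day."""

    participant_id: str
    date: dt.date
    tests_completed: frozenset[Test]

    def __post_init__(self) -> None:
        if not self.tests_completed:
            raise ValueError("tests_completed must be non-empty")


@dataclasses.dataclass(frozen=True)
class SeriesDefinition:
    """What a day must contain to count as a completion of a series.

    ``required_daily`` tests must all appear on the day itself;
    ``weekly_credit`` tests must each appear on the day or within the
    trailing ``ips_weekly_window_days`` window.
    """

    series: Series
    required_daily: frozenset[Test]
    weekly_credit: frozenset[Test] = frozenset()


@dataclasses.dataclass(frozen=True, order=True)
class SeriesCompletion:
    participant_id: str
    date: dt.date
    series: Series


def default_series_definitions(config: Optional[AnalysisConfig] = None) -> dict[Series, SeriesDefinition]:
    """The standard three series.

    With ``ips_weekly_window_days == 0`` (strict mode) the IPS moves into the
    daily requirement of DA and DAx.
    """
    config = config or AnalysisConfig()
    da_daily = {Test.DMQ, Test.IPSDD, Test.PT, Test.DaS, Test.SBT, Test.UTT}
    dax_daily = {Test.DMQ, Test.IPSDD, Test.PT, Test.DaS}
    weekly = {Test.IPS}
    if config.ips_weekly_window_days == 0:
        da_daily |= weekly
        dax_daily |= weekly
        weekly = set()
    return {
        Series.DA: SeriesDefinition(Series.DA, frozenset(da_daily), frozenset(weekly)),
        Series.DAx: SeriesDefinition(Series.DAx, frozenset(dax_daily), frozenset(weekly)),
        Series.TwoMWT: SeriesDefinition(Series.TwoMWT, frozenset({Test.TwoMWT})),
    }


def build_daily_profiles(log: StudyLog, config: Optional[AnalysisConfig] = None) -> list[DailyActivityProfile]:
    """Group events into per-(participant, day) test sets, sorted."""
    config = config or AnalysisConfig()
    grouped: dict[tuple[str, dt.date], set[Test]] = defaultdict(set)
    for e in log.events:
        grouped[(e.participant_id, e.date(config.timezone_policy))].add(e.test)
    return [
        DailyActivityProfile(pid, day, frozenset(tests))
        for (pid, day), tests in sorted(grouped.items())
    ]


def detect_series_completions(
    profiles: Sequence[DailyActivityProfile],
    definitions: Optional[Mapping[Series, SeriesDefinition]] = None,
    config: Optional[AnalysisConfig] = None,
) -> list[SeriesCompletion]:
    """Emit at most one completion per (participant, day, series).

    A weekly-credit test satisfies its series if it appears in any profile of
    the same participant dated within ``ips_weekly_window_days`` ending on
    the day under consideration (the day itself included).
    """
    config = config or AnalysisConfig()
    definitions = definitions or default_series_definitions(config)
    window = config.ips_weekly_window_days

    by_pid: dict[str, list[DailyActivityProfile]] = defaultdict(list)
    for p in profiles:
        by_pid[p.participant_id].append(p)

    completions: list[SeriesCompletion] = []
    for pid, plist in by_pid.items():
        plist = sorted(plist, key=lambda p: p.date)
        last_seen: dict[Test, dt.date] = {}
        for profile in plist:
            for t in profile.tests_completed:
                last_seen[t] = profile.date
            for sdef in definitions.values():
                if not sdef.required_daily <= profile.tests_completed:
                    continue
                ok = True
                for t in sdef.weekly_credit:
                    seen = last_seen.get(t)
                    if seen is None or (profile.date - seen).days > max(window - 1, 0):
                        ok = False
                        break
                if ok:
                    completions.append(SeriesCompletion(pid, profile.date, sdef.series))
    completions.sort()
    return completions


def completions_frame(completions: Iterable[SeriesCompletion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"participant_id": c.participant_id, "date": c.date.isoformat(), "series": c.series.value}
            for c in completions
        ],
        columns=["participant_id", "date", "series"],
    )


def write_completions(completions: Iterable[SeriesCompletion], path) -> None:
    completions_frame(completions).to_csv(path, index=False)
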
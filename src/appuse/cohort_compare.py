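"""Calendar-window cohort assignment and side-by-side metric reports.

The study design compares engagement before and after the introduction of
configurable reminders and push notifications, using calendar windows.  A
participant may belong to both observation periods; their events are clipped
to each window independently.  The reminder-cohort metrics are restricted to
participants with self-declared MS, while the user-journey funnel cohorts
include everyone (MS status was only collected post-activation).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .event_model import (
    AnalysisConfig,
    CohortWindow,
    MSStatus,
    ParticipantRecord,
    StudyLog,
    TestEvent,
)
from .funnel import FunnelCounts, compute_funnel, funnel_report
from .engagement_metrics import (
    CCDFCurve,
    RetentionCurve,
    completion_rate_curve,
    inactivity_ccdf,
    retention_curve,
    summarize_cohort,
    usage_ccdf,
)
from .sessionization import (
    Series,
    build_daily_profiles,
    default_series_definitions,
    detect_series_completions,
)
from .util import format_pct

# Study window presets.  The reminders/notifications feature shipped on
# 2019-10-21 (iOS) and 2020-02-19 (Android); the two gaps below exclude the
# mixed-availability periods.  The without-reminders window end is printed
# inconsistently in the study's own summaries (Oct 20 vs Oct 21, 2019); the
# preset uses Oct 20 inclusive.
JOURNEY_ORIGINAL = CohortWindow("original_journey", dt.date(2018, 11, 12), dt.date(2019, 7, 17))
JOURNEY_SEAMLESS = CohortWindow("seamless_journey", dt.date(2019, 10, 21), dt.date(2021, 11, 2))
WITHOUT_REMINDERS = CohortWindow("without_reminders", dt.date(2018, 11, 12), dt.date(2019, 10, 20))
WITH_REMINDERS = CohortWindow("with_reminders", dt.date(2020, 2, 19), dt.date(2021, 11, 2))


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """A window plus assignment policy.

    ``basis='activity'``: membership requires >= 1 event dated in-window
    (reminder cohorts).  ``basis='registration'``: membership by
    registration date (journey funnel cohorts).
    """

    window: CohortWindow
    basis: str = "activity"
    ms_only: bool = False

    @property
    def label(self) -> str:
        return self.window.label


def default_study_specs() -> list[CohortSpec]:
    return [
        CohortSpec(JOURNEY_ORIGINAL, basis="registration", ms_only=False),
        CohortSpec(JOURNEY_SEAMLESS, basis="registration", ms_only=False),
        CohortSpec(WITHOUT_REMINDERS, basis="activity", ms_only=True),
        CohortSpec(WITH_REMINDERS, basis="activity", ms_only=True),
    ]


@dataclasses.dataclass
class CohortAssignment:
    participant_id: str
    cohorts: list[str]
    clip: dict[str, tuple[dt.date, dt.date]]


def assign_cohorts(
    log: StudyLog,
    specs: Sequence[CohortSpec],
    config: Optional[AnalysisConfig] = None,
) -> list[CohortAssignment]:
    """Assign each participant to every cohort whose criteria they meet."""
    config = config or AnalysisConfig()
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise ValueError(f"cohort labels must be unique, got {labels}")
    events_by_pid: dict[str, list[TestEvent]] = {}
    for e in log.events:
        events_by_pid.setdefault(e.participant_id, []).append(e)
    out = []
    for r in log.registry:
        cohorts, clip = [], {}
        for spec in specs:
            if spec.ms_only and r.ms_status != MSStatus.MS:
                continue
            if spec.basis == "registration":
                member = spec.window.contains(r.registration_date)
            else:
                member = any(
                    spec.window.contains(e.date(config.timezone_policy))
                    for e in events_by_pid.get(r.participant_id, [])
                )
            if member:
                cohorts.append(spec.label)
                clip[spec.label] = (spec.window.start_date, spec.window.end_date)
        if cohorts:
            out.append(CohortAssignment(r.participant_id, cohorts, clip))
    return out


def clip_events(
    events: Sequence[TestEvent], window: CohortWindow, config: Optional[AnalysisConfig] = None
) -> list[TestEvent]:
    """Events whose calendar day falls inside the window (inclusive)."""
    config = config or AnalysisConfig()
    return [e for e in events if window.contains(e.date(config.timezone_policy))]


@dataclasses.dataclass
class CohortSection:
    """All metrics for one cohort."""

    label: str
    participants: list[ParticipantRecord]
    usage: dict[Series, CCDFCurve]
    usage_pooled: dict[Series, CCDFCurve]
    inactivity: dict[Series, CCDFCurve]
    completion: dict[Series, CCDFCurve]
    retention: dict[Series, RetentionCurve]
    max_run: dict[Series, int]
    max_gap: dict[Series, int]
    max_series_count: dict[Series, int]
    funnel: Optional[FunnelCounts] = None

    @property
    def empty(self) -> bool:
        return not self.participants


@dataclasses.dataclass
class ComparisonReport:
    sections: dict[str, CohortSection]
    config: AnalysisConfig
    retention_days: tuple[int, ...] = (1, 3, 7, 14, 30)

    def curves_frame(self) -> pd.DataFrame:
        frames = []
        for label, sec in self.sections.items():
            for group in (sec.usage, sec.usage_pooled, sec.inactivity, sec.completion):
                for curve in group.values():
                    if curve.is_empty:
                        continue
                    df = curve.to_frame()
                    df.insert(0, "cohort", label)
                    frames.append(df)
            for series, rc in sec.retention.items():
                df = rc.to_frame().rename(
                    columns={"day": "n", "retained": "numerator", "cohort_size": "denominator",
                             "fraction": "probability"}
                )
                df.insert(0, "cohort", label)
                df.insert(1, "unit", "days_since_activation")
                frames.append(df[["cohort", "unit", "series", "n", "numerator", "denominator",
                                  "probability"]])
        if not frames:
            return pd.DataFrame(
                columns=["cohort", "unit", "series", "n", "numerator", "denominator", "probability"]
            )
        return pd.concat(frames, ignore_index=True)

    def retention_table(self) -> pd.DataFrame:
        """Cohort x series rows; 'pct (num/denom)' cells at the standard days."""
        rows = []
        for label, sec in self.sections.items():
            for series in Series:
                rc = sec.retention.get(series)
                row = {"cohort": label, "series": series.value}
                for d in self.retention_days:
                    if rc is None or rc.cohort_size == 0:
                        row[f"day_{d}"] = "censored"
                        continue
                    try:
                        num, denom, _ = rc.at(d)
                    except KeyError:
                        row[f"day_{d}"] = "censored"
                        continue
                    row[f"day_{d}"] = f"{format_pct(num, denom)[:-1]} ({num}/{denom})"
                rows.append(row)
        return pd.DataFrame(rows)

    def summary_dict(self) -> dict:
        out = {}
        for label, sec in self.sections.items():
            entry: dict = {"n_participants": len(sec.participants), "empty": sec.empty}
            entry["max_run"] = {s.value: sec.max_run[s] for s in sec.max_run}
            entry["max_gap"] = {s.value: sec.max_gap[s] for s in sec.max_gap}
            entry["max_series_count"] = {s.value: sec.max_series_count[s] for s in sec.max_series_count}
            if sec.funnel is not None:
                entry["funnel"] = funnel_report([sec.funnel])[label]
            out[label] = entry
        return out

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.curves_frame().to_csv(outdir / "curves.csv", index=False)
        self.retention_table().to_csv(outdir / "retention_table.csv", index=False)
        funnels = [sec.funnel for sec in self.sections.values() if sec.funnel is not None]
        with open(outdir / "funnel.json", "w") as fh:
            json.dump(funnel_report(funnels), fh, indent=2, sort_keys=True)
            fh.write("\n")
        with open(outdir / "summary.json", "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        with open(outdir / "config.json", "w") as fh:
            cfg = dataclasses.asdict(self.config)
            cfg["cohort_windows"] = [
                {"label": w.label, "start_date": w.start_date.isoformat(),
                 "end_date": w.end_date.isoformat()}
                for w in self.config.cohort_windows
            ]
            json.dump(cfg, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")


def compare(
    log: StudyLog,
    config: Optional[AnalysisConfig] = None,
    specs: Optional[Sequence[CohortSpec]] = None,
    retention_days: Sequence[int] = (1, 3, 7, 14, 30),
) -> ComparisonReport:
    """Compute every metric for every cohort in ``specs``.

    Empty cohorts yield an empty section; the run continues.  Retention
    curves are computed over all days 0..max plus the requested table days.
    """
    config = config or AnalysisConfig()
    specs = list(specs) if specs is not None else default_study_specs()
    assignments = assign_cohorts(log, specs, config)
    member_ids: dict[str, set[str]] = {s.label: set() for s in specs}
    for a in assignments:
        for label in a.cohorts:
            member_ids[label].add(a.participant_id)

    definitions = default_series_definitions(config)
    sections: dict[str, CohortSection] = {}
    for spec in specs:
        participants = [r for r in log.registry if r.participant_id in member_ids[spec.label]]
        clipped = clip_events(
            [e for e in log.events if e.participant_id in member_ids[spec.label]],
            spec.window,
            config,
        )
        sub = StudyLog(registry=participants, events=clipped)
        profiles = build_daily_profiles(sub, config)
        completions = detect_series_completions(profiles, definitions, config)
        usage, usage_pooled, inactivity, completion, retention = {}, {}, {}, {}, {}
        max_run, max_gap, max_count = {}, {}, {}
        for series in Series:
            summaries = summarize_cohort(completions, participants, series, config)
            usage[series] = usage_ccdf(summaries, "participant_max_run", config)
            usage_pooled[series] = usage_ccdf(summaries, "pooled_episodes", config)
            inactivity[series] = inactivity_ccdf(summaries, config)
            completion[series] = completion_rate_curve(completions, participants, series)
            # extend the retention curve to every requested table day that is
            # observable within the window span; later days stay censored
            span = (spec.window.end_date - spec.window.start_date).days
            rc = retention_curve(completions, participants, series, config)
            needed = [d for d in retention_days if d <= span]
            if needed and (rc.days.size == 0 or max(needed) > rc.days.max()):
                top = max([*needed, int(rc.days.max()) if rc.days.size else 0])
                rc = retention_curve(
                    completions, participants, series, config, days=range(0, top + 1)
                )
            retention[series] = rc
            max_run[series] = max((s.max_run for s in summaries), default=0)
            max_gap[series] = max((g for s in summaries for g in s.gaps), default=0)
            cc = completion[series]
            max_count[series] = int(cc.support[-1]) if not cc.is_empty else 0
        fun = compute_funnel(participants, spec.window) if spec.basis == "registration" else None
        sections[spec.label] = CohortSection(
            label=spec.label,
            participants=participants,
            usage=usage,
            usage_pooled=usage_pooled,
            inactivity=inactivity,
            completion=completion,
            retention=retention,
            max_run=max_run,
            max_gap=max_gap,
            max_series_count=max_count,
            funnel=fun,
        )
    return ComparisonReport(sections=sections, config=config, retention_days=tuple(retention_days))
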
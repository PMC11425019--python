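"""Domain types, file I/O, and validation for test-battery engagement logs.

The atomic record is a completed smartphone test (a :class:`TestEvent`);
participants are described by funnel milestones (registration, e-consent,
app activation) in a :class:`ParticipantRecord`.  All downstream metrics are
day-granular, so the only timestamp semantics that matter here are (a) how a
timestamp maps to a calendar day (``timezone_policy``) and (b) ordering.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import enum
import re
import warnings
from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd


class Test(str, enum.Enum):
    """The smartphone test battery.

    DMQ (Daily Mood Questionnaire), IPS (Information Processing Speed),
    IPSDD (IPS Digit-Digit), PT (Pinching Test), DaS (Draw a Shape),
    SBT (Static Balance Test), UTT (U-Turn Test) form the fixed daily
    sequence; the Two-Minute Walk Test (TwoMWT) is administered separately.
    """

    DMQ = "DMQ"
    IPS = "IPS"
    IPSDD = "IPSDD"
    PT = "PT"
    DaS = "DaS"
    SBT = "SBT"
    UTT = "UTT"
    TwoMWT = "TwoMWT"


def _norm(name: str) -> str:
    return re.sub(r"[^A-Z0-9]", "", name.upper())


#: Synonym table for test names as they appear in exported logs.
TEST_SYNONYMS: dict[str, Test] = {}
for _t in Test:
    TEST_SYNONYMS[_norm(_t.value)] = _t
TEST_SYNONYMS.update(
    {
        "2MWT": Test.TwoMWT,
        "TWOMWT": Test.TwoMWT,
        "TWOMINUTEWALKTEST": Test.TwoMWT,
        "TWOMINUTEWALK": Test.TwoMWT,
        "2MINUTEWALKTEST": Test.TwoMWT,
        "DAILYMOODQUESTIONNAIRE": Test.DMQ,
        "MOOD": Test.DMQ,
        "INFORMATIONPROCESSINGSPEED": Test.IPS,
        "IPSDIGITDIGIT": Test.IPSDD,
        "INFORMATIONPROCESSINGSPEEDDIGITDIGIT": Test.IPSDD,
        "PINCHING": Test.PT,
        "PINCHINGTEST": Test.PT,
        "DRAWASHAPE": Test.DaS,
        "DRAWASHAPETEST": Test.DaS,
        "STATICBALANCE": Test.SBT,
        "STATICBALANCETEST": Test.SBT,
        "UTURN": Test.UTT,
        "UTURNTEST": Test.UTT,
    }
)


def resolve_test_name(name: str, extra_synonyms: Optional[Mapping[str, Test]] = None) -> Optional[Test]:
    """Map a raw test name to the enum, or None if unrecognised."""
    key = _norm(name)
    if extra_synonyms:
        extras = {_norm(k): v for k, v in extra_synonyms.items()}
        if key in extras:
            return extras[key]
    return TEST_SYNONYMS.get(key)


class MSStatus(str, enum.Enum):
    MS = "MS"
    non_MS = "non_MS"
    unknown = "unknown"


class Platform(str, enum.Enum):
    ios = "ios"
    android = "android"
    unknown = "unknown"


class SchemaError(ValueError):
    """A required column is missing or the file is structurally wrong."""


class RowError(ValueError):
    """A row-level parse failure (carries the 1-based line number)."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclasses.dataclass(frozen=True, order=True)
class TestEvent:
    """One completed test by one participant at one timestamp."""

    participant_id: str
    timestamp: dt.datetime
    test: Test

    def __post_init__(self) -> None:
        if not self.participant_id:
            raise ValueError("participant_id must be non-empty")

    def date(self, timezone_policy: str = "utc") -> dt.date:
        """Calendar day of the event under the given timezone policy."""
        ts = self.timestamp
        if ts.tzinfo is not None:
            if timezone_policy == "utc":
                ts = ts.astimezone(dt.timezone.utc)
            # source_local: keep the wall-clock time as shipped
        return ts.date()


@dataclasses.dataclass(frozen=True)
class ParticipantRecord:
    """Funnel milestones and attributes for one registrant.

    Milestones are nested: activation requires consent, consent requires
    registration, and dates must be non-decreasing along the funnel.
    """

    participant_id: str
    registration_date: dt.date
    consent_date: Optional[dt.date] = None
    activation_date: Optional[dt.date] = None
    ms_status: MSStatus = MSStatus.unknown
    platform: Platform = Platform.unknown

    def __post_init__(self) -> None:
        if not self.participant_id:
            raise ValueError("participant_id must be non-empty")
        if self.activation_date is not None and self.consent_date is None:
            raise ValueError("activation requires consent")
        if self.consent_date is not None and self.registration_date > self.consent_date:
            raise ValueError("registration_date must be <= consent_date")
        if (
            self.activation_date is not None
            and self.consent_date is not None
            and self.consent_date > self.activation_date
        ):
            raise ValueError("consent_date must be <= activation_date")

    @property
    def consented(self) -> bool:
        return self.consent_date is not None

    @property
    def activated(self) -> bool:
        return self.activation_date is not None


@dataclasses.dataclass
class StudyLog:
    """A validated registry + event log pair."""

    registry: list[ParticipantRecord]
    events: list[TestEvent]

    def __post_init__(self) -> None:
        self._by_id = {r.participant_id: r for r in self.registry}

    def participant(self, pid: str) -> ParticipantRecord:
        return self._by_id[pid]

    @property
    def participant_ids(self) -> list[str]:
        return [r.participant_id for r in self.registry]


@dataclasses.dataclass(frozen=True)
class CohortWindow:
    """A labelled inclusive calendar-date window."""

    label: str
    start_date: dt.date
    end_date: dt.date

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise ValueError(f"{self.label}: start_date must be <= end_date")

    def contains(self, d: dt.date) -> bool:
        return self.start_date <= d <= self.end_date


@dataclasses.dataclass
class AnalysisConfig:
    """Options that govern day derivation, truncation, and metric definitions.

    truncation_days limits continuous-usage and inactivity measurement to the
    first N days of each participant's data (default 343); retention and
    completion curves are not truncated.  ips_weekly_window_days is the
    trailing window within which a weekly-cadence test (IPS) credits the
    daily series; 0 means the test must be completed the same day.
    """

    timezone_policy: str = "utc"  # "utc" | "source_local"
    day0_is_activation: bool = True
    truncation_days: int = 343
    ips_weekly_window_days: int = 7
    retention_definition: str = "still_active_at_or_after_n"  # | "active_exactly_day_n"
    usage_unit: str = "participant_max_run"  # | "pooled_episodes"
    rounding: str = "half_up_1dp"
    cohort_windows: list[CohortWindow] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if self.truncation_days <= 0:
            raise ValueError("truncation_days must be > 0")
        if self.ips_weekly_window_days < 0:
            raise ValueError("ips_weekly_window_days must be >= 0")
        if self.timezone_policy not in ("utc", "source_local"):
            raise ValueError(f"unknown timezone_policy {self.timezone_policy!r}")
        if self.retention_definition not in (
            "still_active_at_or_after_n",
            "active_exactly_day_n",
        ):
            raise ValueError(f"unknown retention_definition {self.retention_definition!r}")


# ---------------------------------------------------------------------------
# Readers / writers

REGISTRY_COLUMNS = (
    "participant_id",
    "registration_date",
    "consent_date",
    "activation_date",
    "ms_status",
    "platform",
)
EVENT_COLUMNS = ("participant_id", "test", "timestamp")

_MS_SYNONYMS = {
    "MS": MSStatus.MS,
    "YES": MSStatus.MS,
    "TRUE": MSStatus.MS,
    "1": MSStatus.MS,
    "NONMS": MSStatus.non_MS,
    "NOMS": MSStatus.non_MS,
    "NO": MSStatus.non_MS,
    "FALSE": MSStatus.non_MS,
    "0": MSStatus.non_MS,
    "HEALTHY": MSStatus.non_MS,
}


def _parse_date(value, line: int, column: str) -> Optional[dt.date]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or str(value).strip() == "":
        return None
    try:
        return pd.Timestamp(str(value)).date()
    except (ValueError, TypeError) as exc:
        raise RowError(f"unparseable date in column {column!r}: {value!r}", line) from exc


def _resolve_columns(df: pd.DataFrame, required: Sequence[str], optional: Sequence[str], dialect: Optional[Mapping[str, str]]) -> dict[str, str]:
    dialect = dict(dialect or {})
    mapping = {}
    for canon in (*required, *optional):
        source = dialect.get(canon, canon)
        if source in df.columns:
            mapping[canon] = source
        elif canon in required:
            raise SchemaError(f"missing required column {source!r} (for {canon!r})")
    return mapping


def read_registry(
    path: str | Path,
    dialect: Optional[Mapping[str, str]] = None,
    on_invalid: str = "reject",
) -> list[ParticipantRecord]:
    """Read a participant registry from delimited text.

    dialect maps canonical column names to the file's column names.  Rows
    violating milestone invariants (e.g. activation without consent) are
    rejected with a warning under ``on_invalid="reject"`` or raise under
    ``on_invalid="error"``.  Unparseable dates always raise a RowError with
    the offending line number.
    """
    df = pd.read_csv(path, dtype=str)
    cols = _resolve_columns(df, ["participant_id", "registration_date"],
                            ["consent_date", "activation_date", "ms_status", "platform"], dialect)
    records: list[ParticipantRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        get = lambda canon: getattr(row, cols[canon]) if canon in cols else None
        pid = str(get("participant_id") or "").strip()
        reg = _parse_date(get("registration_date"), line, "registration_date")
        if reg is None:
            raise RowError("missing registration_date", line)
        ms_raw = _norm(str(get("ms_status") or ""))
        platform_raw = _norm(str(get("platform") or ""))
        try:
            record = ParticipantRecord(
                participant_id=pid,
                registration_date=reg,
                consent_date=_parse_date(get("consent_date"), line, "consent_date"),
                activation_date=_parse_date(get("activation_date"), line, "activation_date"),
                ms_status=_MS_SYNONYMS.get(ms_raw, MSStatus.unknown),
                platform={"IOS": Platform.ios, "ANDROID": Platform.android}.get(platform_raw, Platform.unknown),
            )
        except ValueError as exc:
            if on_invalid == "error":
                raise RowError(str(exc), line) from exc
            warnings.warn(f"registry line {line} rejected: {exc}", stacklevel=2)
            continue
        records.append(record)
    return records


def read_event_log(
    path: str | Path,
    dialect: Optional[Mapping[str, str]] = None,
    test_synonyms: Optional[Mapping[str, Test]] = None,
    quarantine: Optional[list[dict]] = None,
) -> list[TestEvent]:
    """Read a test-completion event log; returns events sorted by
    (participant_id, timestamp).

    Unknown test names are quarantined (appended to ``quarantine`` if given,
    and reported in a warning) rather than silently dropped.  If more than
    half of the rows carry unknown test names the file is assumed to be the
    wrong one and a SchemaError is raised.
    """
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        warnings.warn(f"{path}: empty event log", stacklevel=2)
        return []
    cols = _resolve_columns(df, ["participant_id", "test", "timestamp"], [], dialect)
    events: list[TestEvent] = []
    unknown = 0
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        pid = str(getattr(row, cols["participant_id"]) or "").strip()
        raw_test = str(getattr(row, cols["test"]) or "")
        test = resolve_test_name(raw_test, test_synonyms)
        if test is None:
            unknown += 1
            if quarantine is not None:
                quarantine.append({"line": line, "participant_id": pid, "test": raw_test,
                                   "reason": "unknown_test_name"})
            continue
        raw_ts = str(getattr(row, cols["timestamp"]))
        try:
            ts = pd.Timestamp(raw_ts).to_pydatetime()
        except (ValueError, TypeError) as exc:
            raise RowError(f"unparseable timestamp {raw_ts!r}", line) from exc
        events.append(TestEvent(participant_id=pid, timestamp=ts, test=test))
    if unknown:
        if unknown > len(df) / 2:
            raise SchemaError(
                f"{unknown}/{len(df)} rows have unknown test names; this does not look like an event log"
            )
        warnings.warn(f"{path}: {unknown} rows with unknown test names quarantined", stacklevel=2)
    events.sort(key=lambda e: (e.participant_id, e.timestamp.isoformat()))
    return events


def write_registry(records: Iterable[ParticipantRecord], path: str | Path) -> None:
    rows = [
        {
            "participant_id": r.participant_id,
            "registration_date": r.registration_date.isoformat(),
            "consent_date": r.consent_date.isoformat() if r.consent_date else "",
            "activation_date": r.activation_date.isoformat() if r.activation_date else "",
            "ms_status": r.ms_status.value,
            "platform": r.platform.value,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(REGISTRY_COLUMNS)).to_csv(path, index=False)


def write_event_log(events: Iterable[TestEvent], path: str | Path) -> None:
    rows = [
        {
            "participant_id": e.participant_id,
            "test": e.test.value,
            "timestamp": e.timestamp.isoformat(),
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=["participant_id", "test", "timestamp"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Validation


@dataclasses.dataclass
class ValidationReport:
    """Partition of the raw events into kept / quarantined, with reasons."""

    n_input: int
    n_kept: int
    quarantined: list[tuple[TestEvent, str]]
    n_deduplicated: int = 0

    @property
    def counts_by_reason(self) -> dict[str, int]:
        return dict(Counter(reason for _, reason in self.quarantined))

    def write_quarantine(self, path: str | Path) -> None:
        rows = [
            {
                "participant_id": e.participant_id,
                "test": e.test.value,
                "timestamp": e.timestamp.isoformat(),
                "reason": reason,
            }
            for e, reason in self.quarantined
        ]
        pd.DataFrame(rows, columns=["participant_id", "test", "timestamp", "reason"]).to_csv(
            path, index=False
        )


def validate_log(
    registry: Sequence[ParticipantRecord],
    events: Sequence[TestEvent],
    config: Optional[AnalysisConfig] = None,
) -> tuple[StudyLog, ValidationReport]:
    """Check events against the registry; never raises.

    Exact duplicates (same participant, test, timestamp) are dropped and
    counted.  Events from unregistered participants, from participants who
    never activated, or dated before activation are quarantined with a
    reason; everything else is kept.
    """
    config = config or AnalysisConfig()
    by_id = {r.participant_id: r for r in registry}
    kept: list[TestEvent] = []
    quarantined: list[tuple[TestEvent, str]] = []
    seen: set[tuple[str, str, Test]] = set()
    n_dup = 0
    for e in events:
        key = (e.participant_id, e.timestamp.isoformat(), e.test)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        record = by_id.get(e.participant_id)
        if record is None:
            quarantined.append((e, "unknown_participant"))
        elif record.activation_date is None:
            quarantined.append((e, "not_activated"))
        elif e.date(config.timezone_policy) < record.activation_date:
            quarantined.append((e, "pre_activation"))
        else:
            kept.append(e)
    report = ValidationReport(
        n_input=len(events), n_kept=len(kept), quarantined=quarantined, n_deduplicated=n_dup
    )
    return StudyLog(registry=list(registry), events=kept), report
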
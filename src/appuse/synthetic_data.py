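"""Stochastic generator of registries and event logs with the statistical
structure the analysis pipeline assumes.

The behavioral model is an alternating renewal process per activated
participant, starting on the activation day:

* streaks (runs of consecutive active days) extend with probability
  ``streak_continue_p`` per day, i.e. run lengths are geometric;
* each active day carries a per-day permanent-abandonment hazard;
* when a streak ends, the participant returns with probability ``p_return``
  after a gap drawn from a discrete power law whose CCDF slope is
  ``gap_exponent`` (heavy-tailed inactivity), else abandons for good;
* each active day realizes series completions: a DAx day with probability
  ``p_dax_given_active``, a DA day as a sub-event of a DAx day (conditional
  probability ``p_da / p_dax``, which enforces DA-implies-DAx by
  construction), and an independent Two-Minute Walk Test day.

The reminders/notifications feature acts through parameter modifiers
(longer streaks, lower dropout, more walk tests) rather than a mechanistic
notification-response model; notification events themselves are emitted by
:func:`simulate_notifications` for policy testing and realism.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import enum
from collections import defaultdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .event_model import (
    MSStatus,
    ParticipantRecord,
    Platform,
    Test,
    TestEvent,
    write_event_log,
    write_registry,
)
from .cohort_compare import JOURNEY_ORIGINAL, JOURNEY_SEAMLESS
from .event_model import CohortWindow

UTC = dt.timezone.utc

DA_REQUIRED = (Test.DMQ, Test.IPSDD, Test.PT, Test.DaS, Test.SBT, Test.UTT)
DAX_REQUIRED = (Test.DMQ, Test.IPSDD, Test.PT, Test.DaS)


@dataclasses.dataclass(frozen=True)
class ReminderEffect:
    """Multiplicative modifiers encoding the engagement uplift of
    reminders/notifications.  All values 1 (and uplift 0) = no effect."""

    streak_continue_multiplier: float = 1.5
    dropout_hazard_multiplier: float = 0.2
    p_2mwt_uplift: float = 0.10


@dataclasses.dataclass
class SimulationConfig:
    """Full parameterization of the funnel + behavior generator.

    Defaults encode the study conditions: the base activation probability
    and deep-link odds factor reproduce the published conversion rates
    (53.9% original journey, 74.6% seamless; the odds factor 2.512 maps the
    former onto the latter); gap lengths follow a discrete power law with
    CCDF slope 0.96 (the published inactivity-tail coefficient); streak,
    return and dropout parameters are set so that the without-reminders
    condition yields roughly one participant in ten with a 3-day streak and
    single-digit day-30 retention, and the reminder modifiers lift both by
    several-fold, matching the reported contrast.
    """

    seed: int = 0
    n_registrants: int = 500
    p_consent: float = 1.0
    p_activate_base: float = 0.539
    deep_link_effect: float = 2.512  # multiplicative odds factor on activation
    activation_code_expiry_h: int = 48
    study_span_days: int = 1085
    streak_continue_p: float = 0.27
    gap_exponent: float = 0.96
    p_return: float = 0.85
    dropout_hazard: float = 0.24
    p_da_given_active: float = 0.65
    p_dax_given_active: float = 0.85
    p_2mwt_given_active: float = 0.35
    p_ms: float = 0.75
    p_ios: float = 0.81
    ips_weekly_window_days: int = 7
    reminder_effect: ReminderEffect = dataclasses.field(default_factory=ReminderEffect)
    notifications_enabled: bool = False

    def __post_init__(self) -> None:
        for name in (
            "p_consent",
            "p_activate_base",
            "streak_continue_p",
            "p_return",
            "dropout_hazard",
            "p_da_given_active",
            "p_dax_given_active",
            "p_2mwt_given_active",
            "p_ms",
            "p_ios",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        if self.p_da_given_active > self.p_dax_given_active:
            raise ValueError("p_da_given_active must be <= p_dax_given_active")
        if self.gap_exponent <= 0:
            raise ValueError("gap_exponent must be > 0")
        if self.deep_link_effect <= 0:
            raise ValueError("deep_link_effect must be > 0")
        if self.n_registrants < 0:
            raise ValueError("n_registrants must be >= 0")

    def effective_params(self) -> tuple[float, float, float]:
        """(streak_continue_p, dropout_hazard, p_2mwt) after reminder effect."""
        if not self.notifications_enabled:
            return self.streak_continue_p, self.dropout_hazard, self.p_2mwt_given_active
        eff = self.reminder_effect
        return (
            min(self.streak_continue_p * eff.streak_continue_multiplier, 0.99),
            self.dropout_hazard * eff.dropout_hazard_multiplier,
            min(self.p_2mwt_given_active + eff.p_2mwt_uplift, 1.0),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "reminder_effect" in d and isinstance(d["reminder_effect"], dict):
            d["reminder_effect"] = ReminderEffect(**d["reminder_effect"])
        return cls(**d)


def draw_powerlaw_gaps(n: int, ccdf_exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Draw integer gap lengths with exactly P(X >= k) = k**(-ccdf_exponent).

    Inverse-CCDF sampling: X = floor(U**(-1/s)) for U ~ Uniform(0, 1], so
    P(X >= k) = P(U <= k**(-s)) = k**(-s) for every integer k >= 1.
    """
    if ccdf_exponent <= 0:
        raise ValueError("ccdf_exponent must be > 0")
    u = 1.0 - rng.random(n)  # in (0, 1]
    return np.floor(u ** (-1.0 / ccdf_exponent)).astype(np.int64)


def _odds_scale(p: float, factor: float) -> float:
    odds = p / (1.0 - p) * factor if p < 1.0 else np.inf
    return float(odds / (1.0 + odds)) if np.isfinite(odds) else 1.0


def simulate_funnel(
    config: SimulationConfig,
    journey: str = "original",
    window: Optional[CohortWindow] = None,
    rng: Optional[np.random.Generator] = None,
    id_prefix: str = "P",
) -> list[ParticipantRecord]:
    """Generate registrants with funnel milestones.

    Registration dates are uniform over the window; consent happens in the
    same web flow (same day) with probability ``p_consent``; activation
    succeeds with ``p_activate_base`` for the original journey, odds-scaled
    by ``deep_link_effect`` for the seamless one.  Successful activators
    activate within the 48-hour code validity (0-1 days after consent); a
    minority re-request a code and activate 2-3 days later.
    """
    if journey not in ("original", "seamless"):
        raise ValueError(f"journey must be 'original' or 'seamless', got {journey!r}")
    if window is None:
        window = JOURNEY_ORIGINAL if journey == "original" else JOURNEY_SEAMLESS
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    p_act = config.p_activate_base
    if journey == "seamless":
        p_act = _odds_scale(p_act, config.deep_link_effect)
    span = (window.end_date - window.start_date).days
    records = []
    expiry_days = max(config.activation_code_expiry_h // 24, 1)
    for i in range(config.n_registrants):
        reg = window.start_date + dt.timedelta(days=int(rng.integers(0, span + 1)))
        consent = reg if rng.random() < config.p_consent else None
        activation = None
        if consent is not None and rng.random() < p_act:
            if rng.random() < 0.9:  # within the code validity window
                delay = int(rng.integers(0, expiry_days))
            else:  # stalled, re-requested a code
                delay = expiry_days + int(rng.integers(0, 2))
            activation = consent + dt.timedelta(days=delay)
        records.append(
            ParticipantRecord(
                participant_id=f"{id_prefix}{i:05d}",
                registration_date=reg,
                consent_date=consent,
                activation_date=activation,
                ms_status=MSStatus.MS if rng.random() < config.p_ms else MSStatus.non_MS,
                platform=Platform.ios if rng.random() < config.p_ios else Platform.android,
            )
        )
    return records


def _emit_day_events(
    pid: str,
    day: dt.date,
    da_day: bool,
    dax_day: bool,
    mwt_day: bool,
    last_ips_day: Optional[int],
    day_index: int,
    ips_window: int,
    rng: np.random.Generator,
) -> tuple[list[TestEvent], Optional[int]]:
    hour = int(rng.integers(8, 19))
    minute = int(rng.integers(0, 60))
    base = dt.datetime(day.year, day.month, day.day, hour, minute, tzinfo=UTC)
    if da_day:
        tests: list[Test] = list(DA_REQUIRED)
    elif dax_day:
        tests = list(DAX_REQUIRED)
    else:
        tests = [Test.DMQ]  # opened the app, logged mood only
    if da_day or dax_day:
        stale = last_ips_day is None or (day_index - last_ips_day) > max(ips_window - 1, 0)
        if stale:
            tests.insert(1, Test.IPS)
            last_ips_day = day_index
    if mwt_day:
        tests.append(Test.TwoMWT)
    events = [
        TestEvent(pid, base + dt.timedelta(minutes=2 * k), t) for k, t in enumerate(tests)
    ]
    return events, last_ips_day


def simulate_behavior(
    registry: Sequence[ParticipantRecord],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    close_date: Optional[dt.date] = None,
) -> list[TestEvent]:
    """Generate test events for every activated participant.

    The per-participant horizon is ``study_span_days`` from activation,
    additionally capped at ``close_date`` if given.  Every emitted event is
    valid by construction (activated participant, on/after activation day).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    streak_p, hazard, p_mwt = config.effective_params()
    p_dax = config.p_dax_given_active
    p_da_given_dax = config.p_da_given_active / p_dax if p_dax > 0 else 0.0
    events: list[TestEvent] = []
    for r in registry:
        if r.activation_date is None:
            continue
        horizon = config.study_span_days
        if close_date is not None:
            horizon = min(horizon, (close_date - r.activation_date).days + 1)
        day_index = 0
        last_ips_day: Optional[int] = None
        while day_index < horizon:
            dax_day = rng.random() < p_dax
            da_day = dax_day and rng.random() < p_da_given_dax
            mwt_day = rng.random() < p_mwt
            day = r.activation_date + dt.timedelta(days=day_index)
            day_events, last_ips_day = _emit_day_events(
                r.participant_id, day, da_day, dax_day, mwt_day,
                last_ips_day, day_index, config.ips_weekly_window_days, rng,
            )
            events.extend(day_events)
            if rng.random() < hazard:
                break  # permanent abandonment
            if rng.random() < streak_p:
                day_index += 1  # streak continues
            else:
                if rng.random() < config.p_return:
                    gap = int(draw_powerlaw_gaps(1, config.gap_exponent, rng)[0])
                    day_index += gap + 1
                else:
                    break
    events.sort(key=lambda e: (e.participant_id, e.timestamp.isoformat()))
    return events


# ---------------------------------------------------------------------------
# Notification policy engine


class NotificationKind(str, enum.Enum):
    incomplete_daily = "incomplete_daily"
    completed_only_da = "completed_only_da"
    incomplete_2mwt = "incomplete_2mwt"
    completed_only_2mwt = "completed_only_2mwt"
    encouragement_streak = "encouragement_streak"
    encouragement_lapse = "encouragement_lapse"
    acknowledgment = "acknowledgment"


#: Kinds that re-engage an interrupted session; never sent at/after 7 PM.
REENGAGEMENT_KINDS = frozenset(
    {
        NotificationKind.incomplete_daily,
        NotificationKind.completed_only_da,
        NotificationKind.incomplete_2mwt,
        NotificationKind.completed_only_2mwt,
    }
)

_CAP = dt.time(18, 59)  # "7 PM at the latest", strictly before 19:00


@dataclasses.dataclass(frozen=True)
class NotificationEvent:
    participant_id: str
    timestamp: dt.datetime
    kind: NotificationKind


def _reengagement_time(last_event: dt.datetime) -> dt.datetime:
    candidate = last_event + dt.timedelta(hours=4)
    cap = last_event.replace(hour=_CAP.hour, minute=_CAP.minute, second=0, microsecond=0)
    return min(candidate, cap)


def simulate_notifications(
    events: Sequence[TestEvent],
    config: SimulationConfig,
    registry: Optional[Sequence[ParticipantRecord]] = None,
) -> list[NotificationEvent]:
    """Apply the notification trigger policy to simulated day timelines.

    Rules: a re-engagement notification 4 hours after the last completed
    test of an interrupted day, capped strictly before 7 PM; a streak
    encouragement at 10 AM the day after 3 consecutive fully-completed days
    (at most twice per calendar week); a lapse encouragement at 10 AM the
    day after 3 consecutive inactive days; an acknowledgment every 14 days
    at 6 PM.  Globally at most 2 notifications per participant per day,
    re-engagement kinds taking priority.
    """
    if not config.notifications_enabled:
        return []
    activation: dict[str, dt.date] = {}
    if registry is not None:
        activation = {
            r.participant_id: r.activation_date for r in registry if r.activation_date is not None
        }
    by_pid_day: dict[str, dict[dt.date, list[TestEvent]]] = defaultdict(lambda: defaultdict(list))
    for e in events:
        by_pid_day[e.participant_id][e.date("utc")].append(e)

    out: list[NotificationEvent] = []
    da_set = set(DA_REQUIRED)
    for pid, days in by_pid_day.items():
        active_days = sorted(days)
        first, last = active_days[0], active_days[-1]
        anchor = activation.get(pid, first)
        candidates: dict[dt.date, list[NotificationEvent]] = defaultdict(list)

        full_da_days: set[dt.date] = set()
        for day in active_days:
            tests = {e.test for e in days[day]}
            last_ts = max(e.timestamp for e in days[day])
            da_done = da_set <= tests
            if da_done:
                full_da_days.add(day)
            any_da_tests = bool(tests - {Test.TwoMWT})
            mwt_done = Test.TwoMWT in tests
            kind = None
            if any_da_tests and not da_done:
                kind = NotificationKind.incomplete_daily
            elif da_done and not mwt_done:
                kind = NotificationKind.completed_only_da
            elif mwt_done and not any_da_tests:
                kind = NotificationKind.completed_only_2mwt
            if kind is not None:
                ts = _reengagement_time(last_ts)
                candidates[day].append(NotificationEvent(pid, ts, kind))

        # streak encouragement: day after 3 consecutive fully-completed days
        active = set(active_days)
        sent_weekly: list[dt.date] = []
        d = first + dt.timedelta(days=3)
        horizon = last + dt.timedelta(days=1)
        while d <= horizon:
            prev3 = [d - dt.timedelta(days=k) for k in (1, 2, 3)]
            if all(p in full_da_days for p in prev3):
                recent = [s for s in sent_weekly if (d - s).days < 7]
                if len(recent) < 2:
                    ts = dt.datetime(d.year, d.month, d.day, 10, 0, tzinfo=UTC)
                    candidates[d].append(
                        NotificationEvent(pid, ts, NotificationKind.encouragement_streak)
                    )
                    sent_weekly.append(d)
            d += dt.timedelta(days=1)

        # lapse encouragement: day after exactly 3 consecutive inactive days
        d = first + dt.timedelta(days=4)
        while d <= last:
            prev3 = [d - dt.timedelta(days=k) for k in (1, 2, 3)]
            before = d - dt.timedelta(days=4)
            if all(p not in active for p in prev3) and before in active:
                ts = dt.datetime(d.year, d.month, d.day, 10, 0, tzinfo=UTC)
                candidates[d].append(
                    NotificationEvent(pid, ts, NotificationKind.encouragement_lapse)
                )
            d += dt.timedelta(days=1)

        # acknowledgment every 14 days from activation while still engaged
        k = 14
        while anchor + dt.timedelta(days=k) <= last:
            d = anchor + dt.timedelta(days=k)
            ts = dt.datetime(d.year, d.month, d.day, 18, 0, tzinfo=UTC)
            candidates[d].append(NotificationEvent(pid, ts, NotificationKind.acknowledgment))
            k += 14

        priority = {
            NotificationKind.incomplete_daily: 0,
            NotificationKind.completed_only_da: 0,
            NotificationKind.incomplete_2mwt: 0,
            NotificationKind.completed_only_2mwt: 0,
            NotificationKind.encouragement_streak: 1,
            NotificationKind.encouragement_lapse: 1,
            NotificationKind.acknowledgment: 2,
        }
        for day, items in candidates.items():
            items.sort(key=lambda n: (priority[n.kind], n.timestamp))
            out.extend(items[:2])  # never more than twice per day
    out.sort(key=lambda n: (n.participant_id, n.timestamp.isoformat()))
    return out


# ---------------------------------------------------------------------------
# Scenario assembly and persistence


@dataclasses.dataclass
class StudyDataset:
    registry: list[ParticipantRecord]
    events: list[TestEvent]
    notifications: list[NotificationEvent]
    config: SimulationConfig


def simulate_study(
    config: Optional[SimulationConfig] = None,
    n_original: int = 608,
    n_seamless: int = 481,
    close_date: dt.date = dt.date(2021, 11, 2),
) -> StudyDataset:
    """Simulate the full two-journey, two-reminder-cohort study.

    Registrants in the original-journey window behave without
    reminders/notifications; registrants in the seamless window behave with
    them (the feature shipped between the windows).  Behavior runs from
    activation to the study close date.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)

    cfg_orig = dataclasses.replace(config, n_registrants=n_original, notifications_enabled=False)
    cfg_seam = dataclasses.replace(config, n_registrants=n_seamless, notifications_enabled=True)

    reg_orig = simulate_funnel(cfg_orig, "original", JOURNEY_ORIGINAL, rng, id_prefix="O")
    reg_seam = simulate_funnel(cfg_seam, "seamless", JOURNEY_SEAMLESS, rng, id_prefix="S")

    ev_orig = simulate_behavior(reg_orig, cfg_orig, rng, close_date=close_date)
    ev_seam = simulate_behavior(reg_seam, cfg_seam, rng, close_date=close_date)

    notif = simulate_notifications(ev_seam, cfg_seam, reg_seam)
    registry = reg_orig + reg_seam
    events = sorted(ev_orig + ev_seam, key=lambda e: (e.participant_id, e.timestamp.isoformat()))
    return StudyDataset(registry=registry, events=events, notifications=notif, config=config)


def write_dataset(dataset: StudyDataset, outdir: str | Path) -> dict[str, Path]:
    """Write registry.csv, events.csv, notifications.csv and scenario.yaml."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "registry": outdir / "registry.csv",
        "events": outdir / "events.csv",
        "notifications": outdir / "notifications.csv",
        "scenario": outdir / "scenario.yaml",
    }
    write_registry(dataset.registry, paths["registry"])
    write_event_log(dataset.events, paths["events"])
    import pandas as pd

    pd.DataFrame(
        [
            {
                "participant_id": n.participant_id,
                "timestamp": n.timestamp.isoformat(),
                "kind": n.kind.value,
            }
            for n in dataset.notifications
        ],
        columns=["participant_id", "timestamp", "kind"],
    ).to_csv(paths["notifications"], index=False)
    with open(paths["scenario"], "w") as fh:
        yaml.safe_dump(dataset.config.to_dict(), fh, sort_keys=True)
    return paths
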
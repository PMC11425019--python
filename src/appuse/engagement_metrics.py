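"""The four engagement metrics, each as a complementary cumulative
distribution, plus the power-law tail fit.

* continuous usage time - maximal runs of consecutive active days;
* inactivity time       - gaps strictly between two runs;
* test completion rate  - P(participant completed >= n series) over the
  observation window;
* user retention rate   - fraction of the cohort still active on or after
  day n post-activation (the CCDF of the last active day).

Runs and gaps are measured over the first ``truncation_days`` days of each
participant's data (default 343) so that cohorts observed for different
lengths of time remain comparable; completion and retention curves are not
truncated.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from collections import defaultdict
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .event_model import AnalysisConfig, ParticipantRecord
from .sessionization import Series, SeriesCompletion


# ---------------------------------------------------------------------------
# Runs and gaps


@dataclasses.dataclass
class RunGapSummary:
    """Alternating run/gap decomposition of one participant's active days.

    ``runs`` are (start_date, length) pairs of maximal stretches of
    consecutive active days; ``gaps`` are the inactive stretches strictly
    between two runs (a trailing inactive period is censored, not a gap).
    """

    participant_id: str
    series: Series
    runs: list[tuple[dt.date, int]]
    gaps: list[int]
    truncated_at: Optional[int] = None

    @property
    def run_lengths(self) -> list[int]:
        return [length for _, length in self.runs]

    @property
    def max_run(self) -> int:
        return max(self.run_lengths, default=0)

    @property
    def n_active_days(self) -> int:
        return sum(self.run_lengths)


def runs_and_gaps(
    completions: Iterable[SeriesCompletion],
    participant_id: str,
    series: Series,
    activation_date: Optional[dt.date] = None,
    config: Optional[AnalysisConfig] = None,
) -> RunGapSummary:
    """Decompose one participant's completion days into runs and gaps.

    Activity after ``activation_date + truncation_days - 1`` is discarded
    and flagged via ``truncated_at`` (the first discarded day index).  When
    no activation date is given, truncation is anchored at the first active
    day.
    """
    config = config or AnalysisConfig()
    days = sorted(
        {c.date for c in completions if c.participant_id == participant_id and c.series == series}
    )
    truncated_at = None
    if days:
        anchor = activation_date if activation_date is not None else days[0]
        limit = anchor + dt.timedelta(days=config.truncation_days - 1)
        if days[-1] > limit:
            truncated_at = config.truncation_days
            days = [d for d in days if d <= limit]
    runs: list[tuple[dt.date, int]] = []
    gaps: list[int] = []
    for d in days:
        if runs and (d - runs[-1][0]).days == runs[-1][1]:
            runs[-1] = (runs[-1][0], runs[-1][1] + 1)
        else:
            if runs:
                prev_end = runs[-1][0] + dt.timedelta(days=runs[-1][1] - 1)
                gaps.append((d - prev_end).days - 1)
            runs.append((d, 1))
    return RunGapSummary(participant_id, series, runs, gaps, truncated_at)


def summarize_cohort(
    completions: Sequence[SeriesCompletion],
    participants: Sequence[ParticipantRecord],
    series: Series,
    config: Optional[AnalysisConfig] = None,
) -> list[RunGapSummary]:
    """Run/gap summaries for every cohort participant (zero-activity included)."""
    config = config or AnalysisConfig()
    by_pid: dict[str, list[SeriesCompletion]] = defaultdict(list)
    for c in completions:
        if c.series == series:
            by_pid[c.participant_id].append(c)
    out = []
    for r in participants:
        out.append(
            runs_and_gaps(by_pid.get(r.participant_id, []), r.participant_id, series,
                          r.activation_date, config)
        )
    return out


# ---------------------------------------------------------------------------
# CCDF curves


@dataclasses.dataclass
class CCDFCurve:
    """P(X >= n) over integer support, with per-point counts.

    ``numerator[i]`` is the number of units with value >= support[i];
    ``denominator`` is the (constant) number of units.
    """

    unit: str
    support: np.ndarray
    numerator: np.ndarray
    denominator: int
    series: Optional[Series] = None

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=int)
        # counts for empirical curves; floats allowed for analytic curves
        self.numerator = np.asarray(self.numerator)
        if self.support.size and np.any(np.diff(self.support) <= 0):
            raise ValueError("support must be strictly increasing")
        if np.any(np.diff(self.numerator) > 0):
            raise ValueError("CCDF numerators must be non-increasing")

    @property
    def probability(self) -> np.ndarray:
        if self.denominator == 0:
            return np.zeros_like(self.support, dtype=float)
        return self.numerator / self.denominator

    @property
    def is_empty(self) -> bool:
        return self.support.size == 0

    def at(self, n: int) -> float:
        """P(X >= n): the tail count at the smallest support value >= n."""
        if self.denominator == 0:
            return 0.0
        if n <= 0:
            return 1.0
        idx = np.searchsorted(self.support, n, side="left")
        if idx >= self.support.size:
            return 0.0
        return float(self.numerator[idx] / self.denominator)

    @classmethod
    def from_values(
        cls,
        values: Iterable[int],
        unit: str,
        denominator: Optional[int] = None,
        series: Optional[Series] = None,
    ) -> "CCDFCurve":
        """Empirical CCDF of an integer multiset at its distinct values >= 1.

        ``denominator`` defaults to the number of values; pass a larger
        cohort size to count units that scored zero in the denominator only.
        """
        vals = np.asarray(sorted(values), dtype=int)
        vals = vals[vals >= 1]
        denom = denominator if denominator is not None else int(vals.size)
        if vals.size == 0:
            return cls(unit, np.array([], int), np.array([], int), denom, series)
        support, counts = np.unique(vals, return_counts=True)
        tail = np.cumsum(counts[::-1])[::-1]
        return cls(unit, support, tail, denom, series)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "unit": self.unit,
                "series": self.series.value if self.series else "",
                "n": self.support,
                "numerator": self.numerator,
                "denominator": self.denominator,
                "probability": self.probability,
            }
        )


def usage_ccdf(
    summaries: Sequence[RunGapSummary],
    unit: str = "participant_max_run",
    config: Optional[AnalysisConfig] = None,
) -> CCDFCurve:
    """Continuous-usage CCDF.

    ``participant_max_run``: P over participants that the longest run is
    >= n (participants with no activity stay in the denominator).
    ``pooled_episodes``: P over all run episodes that an episode lasts >= n.
    """
    series = summaries[0].series if summaries else None
    if unit == "participant_max_run":
        values = [s.max_run for s in summaries]
        return CCDFCurve.from_values(values, unit, denominator=len(summaries), series=series)
    if unit == "pooled_episodes":
        episodes = [length for s in summaries for length in s.run_lengths]
        return CCDFCurve.from_values(episodes, unit, series=series)
    raise ValueError(f"unknown usage unit {unit!r}")


def inactivity_ccdf(
    summaries: Sequence[RunGapSummary], config: Optional[AnalysisConfig] = None
) -> CCDFCurve:
    """CCDF of pooled gap lengths (inactive stretches between two runs)."""
    series = summaries[0].series if summaries else None
    gaps = [g for s in summaries for g in s.gaps]
    return CCDFCurve.from_values(gaps, "pooled_gaps", series=series)


# ---------------------------------------------------------------------------
# Power-law tail fit


@dataclasses.dataclass(frozen=True)
class PowerLawFit:
    """CCDF-slope parameterization: P(X >= n) ~ n**(-alpha) above xmin.

    Note the density-exponent convention differs by one: a discrete
    power-law pmf p(n) ~ n**(-a) has CCDF exponent alpha = a - 1.
    """

    alpha: float
    xmin: int
    method: str
    goodness: float

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.xmin < 1:
            raise ValueError("xmin must be >= 1")


class FitUndefinedError(ValueError):
    """Too few usable support points to fit a slope."""


def fit_powerlaw(curve: CCDFCurve, xmin: int = 1, method: str = "loglog_ls") -> PowerLawFit:
    """Fit the tail exponent of a CCDF curve.

    ``loglog_ls``: weighted least-squares slope of log P(X>=n) against log n
    over support >= xmin, each point weighted by the square root of its tail
    count (singleton extreme-tail points otherwise dominate the fit);
    goodness is the weighted r-squared.

    ``discrete_mle``: maximum-likelihood exponent of a zeta (discrete
    power-law) distribution on the pointwise counts, reported on the CCDF
    scale (density exponent minus one); goodness is the Kolmogorov-Smirnov
    distance between the empirical and fitted CCDFs.
    """
    mask = (curve.support >= xmin) & (curve.numerator > 0)
    n = curve.support[mask]
    tail = curve.numerator[mask]
    if n.size < 3:
        raise FitUndefinedError(
            f"need >= 3 support points >= xmin={xmin} with positive probability, have {n.size}"
        )
    prob = tail / curve.denominator
    if method == "loglog_ls":
        x = np.log(n.astype(float))
        y = np.log(prob)
        w = np.sqrt(tail.astype(float))
        coef = np.polyfit(x, y, 1, w=w)
        slope, intercept = coef
        yhat = slope * x + intercept
        ybar = np.average(y, weights=w**2)
        ss_res = np.sum(w**2 * (y - yhat) ** 2)
        ss_tot = np.sum(w**2 * (y - ybar) ** 2)
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return PowerLawFit(alpha=abs(float(slope)), xmin=xmin, method=method, goodness=float(r2))
    if method == "discrete_mle":
        counts = tail.copy()
        counts[:-1] = tail[:-1] - tail[1:]  # pointwise counts from tail counts
        total = counts.sum()

        def nll(a: float) -> float:
            return a * np.sum(counts * np.log(n)) + total * np.log(special.zeta(a, xmin))

        res = optimize.minimize_scalar(nll, bounds=(1.0001, 20.0), method="bounded")
        a_hat = float(res.x)
        # KS distance between empirical and fitted CCDF over the support
        fitted_tail = np.array([special.zeta(a_hat, k) for k in n]) / special.zeta(a_hat, xmin)
        emp_tail = tail / tail[0]
        ks = float(np.max(np.abs(emp_tail - fitted_tail)))
        return PowerLawFit(alpha=a_hat - 1.0, xmin=xmin, method=method, goodness=ks)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Completion-rate and retention curves


def completion_rate_curve(
    completions: Sequence[SeriesCompletion],
    participants: Sequence[ParticipantRecord],
    series: Series,
) -> CCDFCurve:
    """P(participant completed >= n series) over the whole observation window.

    The denominator is the cohort size; participants with zero completions
    count only there.  The largest support value is the maximum number of
    series any participant completed.
    """
    counts: dict[str, int] = defaultdict(int)
    for c in completions:
        if c.series == series:
            counts[c.participant_id] += 1
    values = [counts.get(r.participant_id, 0) for r in participants]
    return CCDFCurve.from_values(values, "series_count", denominator=len(participants), series=series)


@dataclasses.dataclass
class RetentionCurve:
    """Fraction of the cohort retained at day n post-activation (day 0 =
    activation day).  Denominator is constant across n."""

    series: Series
    days: np.ndarray
    retained: np.ndarray
    cohort_size: int
    definition: str = "still_active_at_or_after_n"
    n_excluded: int = 0

    @property
    def fraction(self) -> np.ndarray:
        if self.cohort_size == 0:
            return np.zeros_like(self.days, dtype=float)
        return self.retained / self.cohort_size

    def at(self, day: int) -> tuple[int, int, float]:
        """(retained count, cohort size, fraction) at the given day."""
        idx = np.where(self.days == day)[0]
        if idx.size == 0:
            raise KeyError(f"day {day} not in curve")
        r = int(self.retained[idx[0]])
        return r, self.cohort_size, (r / self.cohort_size if self.cohort_size else 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "series": self.series.value,
                "day": self.days,
                "retained": self.retained,
                "cohort_size": self.cohort_size,
                "fraction": self.fraction,
            }
        )


def retention_curve(
    completions: Sequence[SeriesCompletion],
    participants: Sequence[ParticipantRecord],
    series: Series,
    config: Optional[AnalysisConfig] = None,
    days: Optional[Sequence[int]] = None,
) -> RetentionCurve:
    """Day-n retention for one series.

    Default definition ``still_active_at_or_after_n``: a participant is
    retained at day n if they completed the series on any day >= activation
    + n — the CCDF of the last active day, hence non-increasing in n.  The
    alternative ``active_exactly_day_n`` counts only day-n completions.
    Participants without an activation date are excluded and counted in
    ``n_excluded``.
    """
    config = config or AnalysisConfig()
    usable = [r for r in participants if r.activation_date is not None]
    n_excluded = len(participants) - len(usable)
    by_pid: dict[str, list[dt.date]] = defaultdict(list)
    for c in completions:
        if c.series == series:
            by_pid[c.participant_id].append(c.date)

    offsets: dict[str, list[int]] = {}
    for r in usable:
        ds = by_pid.get(r.participant_id, [])
        offsets[r.participant_id] = [(d - r.activation_date).days for d in ds]

    last_day = {pid: max(o, default=None) for pid, o in offsets.items()}
    max_last = max((v for v in last_day.values() if v is not None), default=0)
    if days is None:
        days_arr = np.arange(0, max_last + 1)
    else:
        days_arr = np.asarray(sorted(days), dtype=int)

    retained = np.zeros(days_arr.size, dtype=int)
    if config.retention_definition == "still_active_at_or_after_n":
        lasts = np.array([v for v in last_day.values() if v is not None])
        for i, n in enumerate(days_arr):
            retained[i] = int(np.sum(lasts >= n)) if lasts.size else 0
    else:  # active_exactly_day_n
        day_sets = [set(o) for o in offsets.values()]
        for i, n in enumerate(days_arr):
            retained[i] = sum(1 for s in day_sets if int(n) in s)
    return RetentionCurve(
        series=series,
        days=days_arr,
        retained=retained,
        cohort_size=len(usable),
        definition=config.retention_definition,
        n_excluded=n_excluded,
    )
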
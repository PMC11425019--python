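"""Runs/gaps, CCDF curves, power-law fits, completion and retention."""

from __future__ import annotations

import datetime as dt
import random

import numpy as np
import pytest

from appuse.engagement_metrics import (
    CCDFCurve,
    FitUndefinedError,
    RunGapSummary,
    completion_rate_curve,
    fit_powerlaw,
    inactivity_ccdf,
    retention_curve,
    runs_and_gaps,
    summarize_cohort,
    usage_ccdf,
)
from appuse.event_model import AnalysisConfig
from appuse.sessionization import Series, SeriesCompletion
from appuse.synthetic_data import draw_powerlaw_gaps
from conftest import ACT, make_record


def completions_for(days, pid="A", series=Series.DA, anchor=ACT):
    return [SeriesCompletion(pid, anchor + dt.timedelta(days=d), series) for d in days]


def brute_force_runs_gaps(days: set[int]) -> tuple[list[int], list[int]]:
    """Day-by-day scan over the active-day set."""
    if not days:
        return [], []
    runs, gaps = [], []
    cur = gap = 0
    for d in range(min(days), max(days) + 1):
        if d in days:
            if gap:
                gaps.append(gap)
                gap = 0
            cur += 1
        else:
            if cur:
                runs.append(cur)
                cur = 0
            gap += 1
    if cur:
        runs.append(cur)
    return runs, gaps


class TestRunsAndGaps:
    def test_hand_checked_pattern(self):
        s = runs_and_gaps(completions_for([1, 2, 3, 7]), "A", Series.DA, ACT)
        assert s.run_lengths == [3, 1]
        assert s.gaps == [3]

    def test_single_active_day(self):
        s = runs_and_gaps(completions_for([4]), "A", Series.DA, ACT)
        assert s.run_lengths == [1] and s.gaps == []

    def test_no_activity_is_empty_not_error(self):
        s = runs_and_gaps([], "A", Series.DA, ACT)
        assert s.runs == [] and s.gaps == [] and s.max_run == 0

    def test_trailing_inactivity_is_not_a_gap(self):
        s = runs_and_gaps(completions_for([0, 1]), "A", Series.DA, ACT)
        assert s.gaps == []

    def test_truncation_discards_and_flags(self):
        cfg = AnalysisConfig(truncation_days=10)
        s = runs_and_gaps(completions_for([0, 5, 9, 10, 20]), "A", Series.DA, ACT, cfg)
        assert s.truncated_at == 10
        assert sum(s.run_lengths) == 3  # days 0, 5, 9 kept

    def test_200_random_patterns_match_brute_force(self):
        rng = random.Random(11)
        for _ in range(200):
            days = {rng.randrange(0, 60) for _ in range(rng.randrange(0, 25))}
            s = runs_and_gaps(completions_for(sorted(days)), "A", Series.DA, ACT)
            runs, gaps = brute_force_runs_gaps(days)
            assert s.run_lengths == runs and s.gaps == gaps

    def test_conservation_runs_plus_gaps_equal_span(self):
        rng = random.Random(5)
        for _ in range(50):
            days = {rng.randrange(0, 80) for _ in range(rng.randrange(1, 30))}
            s = runs_and_gaps(completions_for(sorted(days)), "A", Series.DA, ACT)
            span = max(days) - min(days) + 1
            assert sum(s.run_lengths) + sum(s.gaps) == span
            assert sum(s.run_lengths) == len(days)


def summary(pid, run_lengths, gaps):
    runs = [(ACT, n) for n in run_lengths]
    return RunGapSummary(pid, Series.DA, runs, gaps)


class TestUsageCCDF:
    def test_participant_max_run_headline(self):
        """10 participants, 3 with a 3-day-or-longer streak -> P(>=3)=0.30."""
        summaries = [summary(f"P{i}", [3 if i < 3 else 1], []) for i in range(10)]
        curve = usage_ccdf(summaries, "participant_max_run")
        assert curve.at(3) == pytest.approx(0.30)
        assert curve.at(1) == pytest.approx(1.0)

    def test_all_runs_length_one(self):
        summaries = [summary(f"P{i}", [1, 1], []) for i in range(4)]
        curve = usage_ccdf(summaries, "pooled_episodes")
        assert curve.at(1) == pytest.approx(1.0)
        assert curve.at(2) == pytest.approx(0.0)

    def test_pooled_episodes_match_direct_counting(self):
        rng = random.Random(2)
        summaries = [
            summary(f"P{i}", [rng.randrange(1, 9) for _ in range(rng.randrange(1, 5))], [])
            for i in range(40)
        ]
        curve = usage_ccdf(summaries, "pooled_episodes")
        episodes = [n for s in summaries for n in s.run_lengths]
        for n in range(1, 10):
            assert curve.at(n) == pytest.approx(
                sum(e >= n for e in episodes) / len(episodes)
            )

    def test_zero_activity_participants_stay_in_denominator(self):
        summaries = [summary("P0", [2], []), summary("P1", [], [])]
        curve = usage_ccdf(summaries, "participant_max_run")
        assert curve.at(1) == pytest.approx(0.5)


class TestInactivityCCDF:
    def test_small_gap_multiset(self):
        summaries = [summary("A", [1, 1, 1], [1, 1, 2])]
        curve = inactivity_ccdf(summaries)
        assert curve.at(1) == pytest.approx(1.0)
        assert curve.at(2) == pytest.approx(1 / 3)

    def test_no_pauses_degenerate(self):
        curve = inactivity_ccdf([summary("A", [5], [])])
        assert curve.is_empty

    def test_pooling_equals_concatenation(self):
        rng = random.Random(8)
        summaries = [
            summary(f"P{i}", [1], [rng.randrange(1, 20) for _ in range(rng.randrange(0, 6))])
            for i in range(30)
        ]
        pooled = [g for s in summaries for g in s.gaps]
        curve = inactivity_ccdf(summaries)
        for n in range(1, 21):
            expected = sum(g >= n for g in pooled) / len(pooled)
            assert curve.at(n) == pytest.approx(expected)


def exact_powerlaw_curve(alpha: float, n_max: int = 50) -> CCDFCurve:
    support = np.arange(1, n_max + 1)
    prob = support.astype(float) ** (-alpha)
    return CCDFCurve("pooled_gaps", support, prob, 1)


class TestPowerLawFit:
    @pytest.mark.parametrize("alpha", [0.96, 2.0])
    def test_exact_curve_recovered_to_machine_precision(self, alpha):
        fit = fit_powerlaw(exact_powerlaw_curve(alpha), xmin=1, method="loglog_ls")
        assert fit.alpha == pytest.approx(alpha, abs=1e-6)
        assert fit.goodness == pytest.approx(1.0, abs=1e-9)

    def test_sampled_gaps_recover_generator_exponent(self):
        rng = np.random.default_rng(96)
        gaps = draw_powerlaw_gaps(20_000, 0.96, rng)
        curve = CCDFCurve.from_values(gaps.tolist(), "pooled_gaps")
        fit = fit_powerlaw(curve, xmin=1, method="loglog_ls")
        assert fit.alpha == pytest.approx(0.96, abs=0.05)

    def test_discrete_mle_on_zeta_sample(self):
        from scipy.stats import zipf

        sample = zipf(a=2.5).rvs(size=5000, random_state=1)
        curve = CCDFCurve.from_values(sample.tolist(), "pooled_gaps")
        fit = fit_powerlaw(curve, xmin=1, method="discrete_mle")
        # CCDF-scale exponent = density exponent - 1
        assert fit.alpha == pytest.approx(1.5, abs=0.1)

    def test_too_few_points_is_undefined(self):
        curve = CCDFCurve.from_values([1, 1, 2], "pooled_gaps")
        with pytest.raises(FitUndefinedError):
            fit_powerlaw(curve, xmin=1)


class TestCompletionRate:
    def test_day_one_headline_counts(self):
        """350 participants, 234 with at least one DA series -> 66.9%."""
        participants = [make_record(f"P{i}") for i in range(350)]
        comps = []
        for i in range(234):
            comps += completions_for([0], pid=f"P{i}")
        curve = completion_rate_curve(comps, participants, Series.DA)
        assert curve.at(1) == pytest.approx(234 / 350)

    def test_nobody_completes_anything(self):
        participants = [make_record(f"P{i}") for i in range(5)]
        curve = completion_rate_curve([], participants, Series.DA)
        assert curve.is_empty and curve.at(1) == 0.0

    def test_matches_sort_and_count_oracle(self):
        rng = random.Random(4)
        participants = [make_record(f"P{i}") for i in range(30)]
        comps = []
        counts = {}
        for i in range(30):
            k = rng.randrange(0, 12)
            counts[f"P{i}"] = k
            comps += completions_for(range(k), pid=f"P{i}")
        curve = completion_rate_curve(comps, participants, Series.DA)
        for n in range(1, 13):
            expected = sum(c >= n for c in counts.values()) / 30
            assert curve.at(n) == pytest.approx(expected)


class TestRetention:
    def test_day0_only_user_not_retained_at_day1(self):
        participants = [make_record("A")]
        rc = retention_curve(completions_for([0]), participants, Series.DA)
        assert rc.at(0)[0] == 1
        assert rc.at(0)[2] == 1.0
        assert rc.days.max() == 0  # nothing beyond activation day

    def test_default_definition_matches_last_active_oracle(self):
        rng = random.Random(13)
        participants = [make_record(f"P{i}") for i in range(40)]
        comps, last = [], {}
        for i in range(40):
            days = sorted({rng.randrange(0, 50) for _ in range(rng.randrange(0, 8))})
            if days:
                last[f"P{i}"] = days[-1]
                comps += completions_for(days, pid=f"P{i}")
        rc = retention_curve(comps, participants, Series.DA, days=range(0, 51))
        for n in range(0, 51):
            assert rc.at(n)[0] == sum(ld >= n for ld in last.values())

    def test_default_curve_is_non_increasing(self):
        rng = random.Random(14)
        participants = [make_record(f"P{i}") for i in range(25)]
        comps = []
        for i in range(25):
            days = sorted({rng.randrange(0, 40) for _ in range(rng.randrange(0, 6))})
            comps += completions_for(days, pid=f"P{i}")
        rc = retention_curve(comps, participants, Series.DA)
        assert np.all(np.diff(rc.retained) <= 0)

    def test_exact_day_definition(self):
        cfg = AnalysisConfig(retention_definition="active_exactly_day_n")
        participants = [make_record("A"), make_record("B")]
        comps = completions_for([0, 5], pid="A") + completions_for([0], pid="B")
        rc = retention_curve(comps, participants, Series.DA, cfg, days=[0, 1, 5])
        assert rc.at(0)[0] == 2 and rc.at(1)[0] == 0 and rc.at(5)[0] == 1

    def test_missing_activation_excluded_with_count(self):
        participants = [make_record("A"), make_record("B", activation=None)]
        rc = retention_curve(completions_for([0]), participants, Series.DA)
        assert rc.cohort_size == 1 and rc.n_excluded == 1

    def test_retention_day1_never_exceeds_completion_ge1(self, simulated_log, config):
        from appuse.sessionization import build_daily_profiles, detect_series_completions

        comps = detect_series_completions(build_daily_profiles(simulated_log, config))
        activated = [r for r in simulated_log.registry if r.activated]
        for series in Series:
            rc = retention_curve(comps, activated, series, config, days=[1])
            cc = completion_rate_curve(comps, activated, series)
            assert rc.at(1)[2] <= cc.at(1) + 1e-12
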
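# appuse

Engagement and retention analytics for smartphone test-battery event logs,
built around the quantitative user-experience analysis of the Floodlight
Open study — a global, open-access, digital-only observational study in
multiple sclerosis whose app administers a fixed daily sequence of
smartphone sensor-based tests (DMQ, IPS, IPS Digit–Digit, Pinching, Draw a
Shape, Static Balance, U-Turn) plus a separately taken Two-Minute Walk Test
(2MWT). The package is for digital-health researchers and data scientists
who need to quantify user acquisition, engagement, and retention for such
tools from raw telemetry, and to compare cohorts before and after a UX
change (here: a deep-linked activation journey, and configurable reminders
with push notifications).

## What it computes

From a participant registry and a test-completion event log:

* **Conversion funnel** — registration → e-consent → app activation, with
  the conversion rate activated/registered per calendar-window cohort.
* **Series completions** — day-level sessionization into three series:
  DA (the full fixed sequence, with the weekly-cadence IPS credited inside
  a trailing 7-day window), DAx (DA without the balance/gait tests SBT and
  UTT), and 2MWT. Structurally, every DA day is a DAx day.
* **Four engagement metrics**, each a complementary cumulative
  distribution P(X ≥ n):
  * *continuous usage time* — runs of consecutive active days
    (per-participant maximum, or pooled episodes);
  * *inactivity time* — gap lengths strictly between two runs, with a
    power-law tail fit P(X ≥ n) ∝ n^(−α) (log-log least squares and
    discrete MLE);
  * *test completion rate* — P(participant completed ≥ n series);
  * *user retention rate* — fraction of activated participants still
    performing the series on or after day n post-activation (the CCDF of
    the last active day).
* **Cohort comparison** — window-based cohort assignment with per-cohort
  event clipping and a side-by-side report, including the retention table
  at days 1, 3, 7, 14, 30 in `pct (n/N)` cell format.
* **Synthetic study data** — an alternating renewal-process simulator
  (geometric streaks, power-law gaps, per-day dropout hazard, funnel with
  deep-link odds effect, notification policy engine) that generates
  registries and event logs with the statistical structure the analysis
  assumes.

See `docs/methods.md` for the precise definitions, parameter rationale,
and limitations.

## Worked example

The published funnel counts make a one-liner worked example — conversion
on the original activation journey versus the seamless deep-linked one:

```python
>>> from appuse.funnel import FunnelCounts, conversion_rate
>>> conversion_rate(FunnelCounts("original", 608, 608, 328))
(0.5394736842105263, '53.9%')
>>> conversion_rate(FunnelCounts("seamless", 481, 481, 359))
(0.7463617463617463, '74.6%')
```

End to end, `analysis/05_reported_rates.py` rebuilds both reminder cohorts
from the published retention numerators, runs the full validate →
sessionize → metrics → compare pipeline, and prints the recomputed table:

```
           cohort series          day_1          day_3          day_7        day_14        day_30
without_reminders     DA 61.7 (216/350) 32.0 (112/350)  23.4 (82/350) 16.3 (57/350)  9.7 (34/350)
without_reminders    DAx 82.9 (290/350) 48.9 (171/350) 34.6 (121/350) 28.0 (98/350) 17.1 (60/350)
without_reminders TwoMWT 32.3 (113/350)  18.3 (64/350)  14.3 (50/350) 11.1 (39/350)  6.3 (22/350)
   with_reminders     DA 65.7 (113/172)  36.6 (63/172)  32.6 (56/172) 30.8 (53/172) 30.8 (53/172)
   with_reminders    DAx 79.7 (137/172)  51.2 (88/172)  36.6 (63/172) 30.8 (53/172) 30.8 (53/172)
   with_reminders TwoMWT  40.7 (70/172)  32.6 (56/172)  28.5 (49/172) 24.4 (42/172) 22.7 (39/172)
```

Each cell is the user retention rate at day n: the percentage (half-up,
one decimal) and the count of cohort participants whose last completion of
that series fell on or after day n post-activation. The with-reminders
plateau from day 14 to day 30 (30.8% for DA and DAx) is the signature of
the retention definition: users surviving the early drop-off keep going.

## The analysis chain

Numbered drivers under `analysis/` (run from that directory, in order or
individually — each regenerates what it needs):

1. `01_simulate_study.py` — simulate the two-journey, two-cohort study
   (608 + 481 registrants) into `results/data/`;
2. `02_user_journey_funnel.py` — conversion funnels, simulated and from
   the published milestone counts;
3. `03_engagement_metrics.py` — streak/gap CCDFs and the inactivity
   power-law fits per cohort and series;
4. `04_cohort_comparison.py` — the full side-by-side report bundle;
5. `05_reported_rates.py` — the published-rate reconstruction shown above.

A thin CLI wraps the same pipeline: `appuse simulate`, `appuse analyze
<registry.csv> <events.csv> --out <dir>`, and `appuse demo`.

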
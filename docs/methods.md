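# Methods

This note documents the statistical definitions the package implements, the
behavioral model behind the synthetic-data generator, the numerical choices,
and the known limitations. It is written for users who need to know exactly
what each number means before citing it.

## Data model

The pipeline operates on two delimited-text inputs: a **participant
registry** (one row per registrant with registration, e-consent, and app
activation dates, self-declared MS status, platform) and a **test-completion
event log** (one row per completed test: participant id, test name,
timestamp). Eight tests are recognised: DMQ, IPS, IPS Digit–Digit (IPSDD),
PT, DaS, SBT, UTT, and the Two-Minute Walk Test (2MWT). Test names are
resolved through a case- and punctuation-insensitive synonym table; unknown
names are quarantined, never silently dropped, and a file in which more than
half the rows fail resolution is rejected outright as the wrong file.

Milestones are nested by construction: activation requires consent, and
dates must be non-decreasing along registration → consent → activation.
Validation partitions events into kept and quarantined (unknown participant,
participant never activated, event predating activation) and deduplicates
exact repeats; it never raises, it reports.

**Calendar days.** All metrics are day-granular. Timestamps are mapped to
calendar days under a configurable `timezone_policy`: `utc` (default)
converts timezone-aware stamps to UTC before taking the date; `source_local`
keeps the wall-clock date as shipped. Public app-telemetry exports rarely
state their clock convention, so neither policy is asserted as ground truth;
`utc` is the default because it is deterministic for mixed-zone data.
Within-day event ordering is never used by any metric: series completion is
set-based, because the app enforces the fixed test sequence but an export
may not preserve it.

## Series completion

A *series completion* is a (participant, calendar day, series) triple, the
unit all four engagement metrics count. Three series are defined:

| series | required on the day | weekly credit |
|--------|--------------------|---------------|
| DA     | DMQ, IPSDD, PT, DaS, SBT, UTT | IPS |
| DAx    | DMQ, IPSDD, PT, DaS | IPS |
| 2MWT   | 2MWT               | —   |

The IPS has a weekly cadence while every other test is daily. A literal
all-seven-daily reading of DA would make streaks longer than seven days
impossible, yet multi-month DA streaks are observed in this kind of data;
the package therefore credits the IPS toward DA/DAx if it was completed on
the day itself or within the trailing `ips_weekly_window_days` window
(default 7, i.e. the day plus the six days before it). Setting the window
to 0 gives the strict all-daily reading. Because DAx's requirements are a
subset of DA's, every DA completion day is also a DAx completion day; this
dominance is asserted as a property test and exploited by the fixture
builder. Tests skipped for safety reasons (SBT, UTT, 2MWT may be skipped
when conditions are unsafe) simply count as non-completions; nothing is
imputed.

## The four engagement metrics

All four are reported as complementary cumulative distributions (CCDF,
P(X ≥ n)) over integer support, with per-point numerators and a constant
denominator.

**Continuous usage time.** Maximal runs of consecutive active days per
participant and series. Two units are exposed: `participant_max_run`
(P over participants that the longest streak is ≥ n — the unit behind
"share of participants with ≥ 3 consecutive days"; participants with no
activity stay in the denominator) and `pooled_episodes` (P over all run
episodes). Published usage curves do not always state which unit they use,
so both are first-class outputs.

**Inactivity time.** Gap lengths pooled over participants, where a gap is
an inactive stretch *strictly between* two runs. A trailing inactive period
after the last active day is right-censored, not a gap — the definition
requires a return. Runs and gaps satisfy, per participant, Σ runs = number
of active days and Σ runs + Σ gaps = span from first to last active day.

**Truncation.** Usage and inactivity are measured over the first
`truncation_days` days of each participant's data (default 343), so cohorts
observed for different lengths of time remain comparable; activity beyond
the limit is discarded and flagged. Completion and retention curves are not
truncated: they are normalised by cohort size, not by observation span.

**Test completion rate.** P(participant completed ≥ n series) over the
whole observation window, denominator the cohort size. The support maximum
is the largest number of series any participant completed.

**User retention rate.** The fraction of activated participants retained at
day n post-activation, day 0 being the activation day. The default
definition, `still_active_at_or_after_n`, counts a participant as retained
at day n if they completed the series on any day ≥ n — equivalently, the
CCDF of the last active day. This reading is chosen because (a) the four
metrics are presented as complementary cumulative distributions, and (b)
observed retention tables plateau across days 14–30, which a same-day
definition cannot produce structurally (a plateau would require the same
participants to be active on exactly those days). The same-day alternative
(`active_exactly_day_n`) is retained as a config option. Under the default,
retention(1) ≤ completion(≥1) always: day-0-only users count in the latter
but not the former.

**Rounding.** Percentages are rendered half-up at one decimal
(`"30.8 (53/172)"` cell format). Published tables of this kind are not
always internally consistent (e.g. 39/172 printed as 22.6 where half-up
gives 22.7), so comparisons against printed values should allow ±0.1
percentage point.

## Power-law tail fit

The inactivity CCDF is heavy-tailed; the package fits
P(X ≥ n) ∝ n^(−α) above a cutoff `xmin` (default 1) and reports α on the
**CCDF-slope scale**. Note the density convention differs by one: a
discrete pmf p(n) ∝ n^(−a) has CCDF exponent α = a − 1.

Two estimators are provided:

* `loglog_ls` (default): least squares of log P(X ≥ n) on log n over the
  support ≥ xmin, each point weighted by √(tail count). Unweighted least
  squares over distinct observed values is dominated by singleton
  extreme-tail points and misses a true exponent of 0.96 by up to ±0.09 at
  20,000 draws; the √count weighting brings recovery within ±0.02 across
  seeds while leaving the estimator exact (to machine precision) on pure
  power-law curves. Goodness is the weighted r².
* `discrete_mle`: the zeta-distribution maximum-likelihood exponent on the
  pointwise counts, converted to the CCDF scale (a − 1), with the
  Kolmogorov–Smirnov distance as goodness. It is reported alongside for
  robustness; on windows-clipped or truncated gap sets it is biased low and
  should be read as a sensitivity check, not the headline.

Fits with fewer than three usable support points raise a fit-undefined
error. No power-law-versus-lognormal model comparison is attempted; the
claim supported is "approximate power law", nothing stronger.

## Cohorts and comparison

Cohorts are inclusive calendar-date windows. Two assignment bases exist:
**registration** (journey funnel cohorts — the journey variant a registrant
experiences is fixed at registration) and **activity** (reminder cohorts —
membership requires at least one in-window event, and each member's events
are clipped to the window independently, so one participant may contribute
to both observation periods with disjoint data). Reminder-cohort metrics
are restricted to participants with self-declared MS; journey funnels
include everyone, because MS status is only collected post-activation.

The shipped window preset is: original journey 2018-11-12 → 2019-07-17;
seamless journey 2019-10-21 → 2021-11-02; without reminders 2018-11-12 →
2019-10-20; with reminders 2020-02-19 → 2021-11-02. The two gaps exclude
periods of mixed feature availability across iOS and Android. Published
descriptions of the without-reminders window end disagree by one day
(Oct 20 vs Oct 21, 2019); the preset uses Oct 20 inclusive. All windows are
overridable — they are study constants, not code constants.

The comparison report computes, per cohort and series: both usage CCDFs,
the inactivity CCDF, the completion-rate curve, the retention curve
(extended to every requested table day observable within the window span;
later days render as "censored"), and the maxima (longest run, longest gap,
largest series count). Reports are deterministic: identical inputs and
configuration produce byte-identical CSV/JSON, which is asserted by test.
The run manifest records the configuration hash, input digests and package
version; its creation timestamp is the one non-reproducible field and is
excluded from determinism checks.

## Synthetic behavior generator

The generator exists so every pipeline stage is testable without the
original study's data. Per activated participant it runs an alternating
renewal process from the activation day:

1. the participant is active on day 0;
2. after each active day, with probability `dropout_hazard` they abandon
   permanently; otherwise the streak continues next day with probability
   `streak_continue_p` (geometric run lengths — consistent with the fast
   early falloff of usage CCDFs);
3. when a streak ends, they return with probability `p_return` after a gap
   drawn from a discrete power law with CCDF exponent `gap_exponent`, else
   abandon permanently.

Gap sampling is exact by inverse-CCDF: X = ⌊U^(−1/s)⌋ gives
P(X ≥ k) = k^(−s) for every integer k ≥ 1, so the generator/estimator round
trip has no discretisation bias. Each active day realizes series: a DAx day
with probability `p_dax_given_active`, a DA day as a sub-event of a DAx day
(conditional probability p_da/p_dax, which enforces DA ⊆ DAx by
construction), and an independent 2MWT day. A DA day emits the six daily
tests plus the IPS whenever its weekly credit would otherwise lapse; a
DAx-only day emits the four-test subset with the same IPS bookkeeping; an
active day that realizes no series emits a lone DMQ (the participant opened
the app). The funnel stage draws registration dates uniformly in the
journey window, consent in the same web flow with probability `p_consent`,
and activation with probability `p_activate_base`, odds-scaled by
`deep_link_effect` for the seamless journey; 90% of activators activate
within the 48-hour code validity, the rest re-request a code.

Reminders and notifications act through three parameter modifiers
(`streak_continue_multiplier`, `dropout_hazard_multiplier`,
`p_2mwt_uplift`), applied only when `notifications_enabled` is set. With
all modifiers at 1 (and uplift 0) the with/without conditions are
exchangeable — at a fixed seed they produce identical event streams, which
is asserted by test. Notification *events* are emitted by a separate policy
engine for realism and policy testing; they do not feed back into behavior.
The policy engine implements the trigger rules: re-engagement 4 hours after
an interrupted day's last test, capped strictly before 7 PM (18:59, so that
"at 7 PM at the latest" and "never after 7 PM" both hold); streak
encouragement at 10 AM after three consecutive fully-completed days, at
most twice per week; lapse encouragement at 10 AM after exactly three
consecutive inactive days; an acknowledgment every 14 days at 6 PM; and a
global cap of two notifications per participant per day, re-engagement
kinds taking priority. Abandonment *within* a 2MWT attempt is below the
day-level resolution of the generator, so the incomplete-2MWT trigger
exists in the policy engine but is never fired by generated data.

### Default parameters

| parameter | default | rationale |
|-----------|---------|-----------|
| `p_consent` | 1.0 | e-consent is part of the registration flow; registries of this design show no consent attrition |
| `p_activate_base` | 0.539 | the published original-journey conversion rate |
| `deep_link_effect` | 2.512 | odds factor mapping 53.9% onto the published seamless rate of 74.6% |
| `activation_code_expiry_h` | 48 | the activation-code validity |
| `gap_exponent` | 0.96 | the published inactivity-tail CCDF slope |
| `streak_continue_p` | 0.27 | with the two parameters below: ~10% of without-reminders participants reach a 3-day streak, day-30 retention in the single digits |
| `dropout_hazard` | 0.24 | most abandoners quit within the first days; the hazard is per *active* day |
| `p_return` | 0.85 | most streak ends are pauses, not churn |
| `reminder_effect` | (1.5, 0.2, +0.10) | lifts streaks and day-30 retention several-fold, reproducing the direction and rough size of the published with/without contrast |
| `p_da/p_dax/p_2mwt_given_active` | 0.65 / 0.85 / 0.35 | active days usually yield the short series, less often the full sequence or a walk test |
| `p_ms`, `p_ios` | 0.75, 0.81 | cohort composition of the motivating study population |

The calibration targets are the *magnitudes* of the published results
(conversion rates, streak shares, day-30 retention contrast), not their
exact values; the simulator's sanity checks are directional and
coarse-grained, while exact reproduction of printed rates is done from the
printed numerators/denominators by the fixture builder (below).

### What the generator does not emulate

Homogeneous participants (no age/sex/severity covariate effects, no
per-participant frailty); no weekday/holiday seasonality; no
notification→behavior feedback beyond the three modifiers; no test-level
abandonment within a day; no withdrawal events, only silent abandonment;
independence of the 2MWT from the daily series, where real walk-test
behavior likely correlates with overall engagement. Passing tests on
simulated data therefore demonstrate the pipeline's correctness and the
recoverability of the generator's parameters — not that real engagement
data follow this process.

## Fixture reconstruction of published rates

Under the default retention definition a printed retention row
(retained counts at days 1, 3, 7, 14, 30 out of N) determines the cohort's
last-active-day multiset exactly; together with the printed
number-of-participants-with-≥1-series it also pins down the day-0-only
count. The fixture builder inverts this: it assigns each participant a last
active day per series (DA and DAx paired in descending order, which is
valid precisely because the printed DAx counts dominate the DA counts at
every day), emits the minimal event days realizing those assignments, and
gives completion-free participants a lone day-0 DMQ so they count as cohort
activity without completing anything. Running the full pipeline on these
fixtures reproduces every printed numerator exactly and every printed
percentage to ±0.1 point (the residual being the source tables' own
rounding inconsistencies).

## Problem sizes

The bundled analysis chain simulates 1,089 registrants (≈700 activators,
≈20,000 events); power-law recovery uses 20,000 gap draws; oracle
cross-checks run at 1,500–4,000 participants. These sizes put Monte Carlo
error well inside every asserted tolerance while keeping the full test and
analysis chain runnable in minutes on a single CPU.
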
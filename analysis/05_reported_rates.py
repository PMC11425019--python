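#!/usr/bin/env python
"""Reproduce the published headline rates from their printed counts.

Builds the desk-scale fixtures that realize the published retention and
completion numerators/denominators, runs them through the full pipeline,
and prints the recomputed rates next to the published ones.
"""

from common import RESULTS

from appuse.cohort_compare import WITH_REMINDERS, WITHOUT_REMINDERS, CohortSpec, compare
from appuse.event_model import validate_log
from appuse.fixtures import (
    REPORTED_ANY_SERIES,
    REPORTED_RETENTION,
    reported_study_fixture,
)
from appuse.sessionization import Series
from appuse.util import pct_value

OUT = RESULTS / "reported"


def main() -> None:
    registry, events = reported_study_fixture()
    log, report = validate_log(registry, events)
    assert not report.quarantined
    specs = [CohortSpec(WITHOUT_REMINDERS, ms_only=True), CohortSpec(WITH_REMINDERS, ms_only=True)]
    comparison = compare(log, specs=specs)
    comparison.write(OUT)

    print("recomputed retention table (pct (n/N)):")
    print(comparison.retention_table().to_string(index=False))

    print("\nday-1 completion rates (participants with >= 1 series):")
    for cohort in ("without_reminders", "with_reminders"):
        sec = comparison.sections[cohort]
        n = len(sec.participants)
        for series in Series:
            got = round(sec.completion[series].at(1) * n)
            want = REPORTED_ANY_SERIES[cohort][series]
            print(
                f"  {cohort:<18} {series.value:<6} {got}/{n} = "
                f"{pct_value(got, n)}%  (published count {want})"
            )
    print(f"\nreport bundle -> {OUT}")


if __name__ == "__main__":
    main()
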
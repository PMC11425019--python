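#!/usr/bin/env python
"""Generate the synthetic study dataset every later step analyzes.

Simulates 608 registrants through the original user journey (no reminders/
notifications) and 481 through the seamless deep-linked journey (reminders
on), with activity from activation to the study close date, and writes
registry.csv / events.csv / notifications.csv under results/data/.
"""

from common import DATA_DIR, SEED

from appuse.event_model import validate_log
from appuse.synthetic_data import SimulationConfig, simulate_study, write_dataset


def main() -> None:
    dataset = simulate_study(SimulationConfig(seed=SEED))
    write_dataset(dataset, DATA_DIR)
    n_act = sum(1 for r in dataset.registry if r.activated)
    _, report = validate_log(dataset.registry, dataset.events)
    print(f"simulated {len(dataset.registry)} registrants ({n_act} activated)")
    print(f"events: {len(dataset.events)}; notifications: {len(dataset.notifications)}")
    print(f"validation: {report.n_kept} kept, {len(report.quarantined)} quarantined "
          f"(a clean generator must quarantine zero)")
    print(f"dataset -> {DATA_DIR}")


if __name__ == "__main__":
    main()
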
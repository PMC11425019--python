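"""Shared plumbing for the analysis drivers: locations and dataset loading."""

from __future__ import annotations

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
DATA_DIR = RESULTS / "data"

SEED = 20240911  # one seed for the whole analysis chain


def load_or_simulate():
    """Load the simulated study from results/data, generating it if absent."""
    from appuse.event_model import read_event_log, read_registry
    from appuse.synthetic_data import SimulationConfig, simulate_study, write_dataset

    if not (DATA_DIR / "registry.csv").exists():
        dataset = simulate_study(SimulationConfig(seed=SEED))
        write_dataset(dataset, DATA_DIR)
    registry = read_registry(DATA_DIR / "registry.csv")
    events = read_event_log(DATA_DIR / "events.csv")
    return registry, events
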
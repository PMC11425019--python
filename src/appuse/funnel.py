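"""Registration -> consent -> activation conversion-funnel analysis.

Cohort membership for the funnel is decided by registration date: the
journey variant a registrant experiences is fixed at the moment they
register, so calendar windows partition registrants, not activity.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional, Sequence

from .event_model import CohortWindow, ParticipantRecord
from .util import format_pct


@dataclasses.dataclass(frozen=True)
class FunnelCounts:
    """Nested milestone counts: activated <= consented <= registered."""

    label: str
    registered: int
    consented: int
    activated: int

    def __post_init__(self) -> None:
        if not (self.registered >= self.consented >= self.activated >= 0):
            raise ValueError(
                f"funnel counts must be nested: {self.registered} >= "
                f"{self.consented} >= {self.activated} >= 0"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class UndefinedRateError(ZeroDivisionError):
    """Conversion rate is undefined for an empty funnel."""


def compute_funnel(
    registry: Sequence[ParticipantRecord], window: Optional[CohortWindow] = None
) -> FunnelCounts:
    """Count registrants in the window by the furthest milestone reached.

    Milestones are nested by construction of :class:`ParticipantRecord`
    (activation implies consent), so the three counts are cumulative
    memberships, not disjoint buckets.
    """
    label = window.label if window else "all"
    in_window = [
        r for r in registry if window is None or window.contains(r.registration_date)
    ]
    return FunnelCounts(
        label=label,
        registered=len(in_window),
        consented=sum(1 for r in in_window if r.consented),
        activated=sum(1 for r in in_window if r.activated),
    )


def conversion_rate(funnel: FunnelCounts) -> tuple[float, str]:
    """Activated / registered, as a fraction and a half-up 1-dp percentage."""
    if funnel.registered == 0:
        raise UndefinedRateError(f"{funnel.label}: no registrants; conversion undefined")
    frac = funnel.activated / funnel.registered
    return frac, format_pct(funnel.activated, funnel.registered)


def funnel_report(funnels: Sequence[FunnelCounts]) -> dict:
    """JSON-ready report with counts and conversion for each funnel."""
    out = {}
    for f in funnels:
        entry = f.to_dict()
        if f.registered > 0:
            frac, pct = conversion_rate(f)
            entry["conversion_fraction"] = frac
            entry["conversion_pct"] = pct
        out[f.label] = entry
    return out


def render_funnel_diagram(funnel: FunnelCounts) -> str:
    """Plain-text three-step conversion diagram."""
    lines = [f"[{funnel.label}]"]
    steps = [
        ("registered", funnel.registered, funnel.registered),
        ("consented", funnel.consented, funnel.registered),
        ("activated", funnel.activated, funnel.registered),
    ]
    for name, n, base in steps:
        pct = format_pct(n, base) if base else "n/a"
        lines.append(f"  {name:<10} {n:>6}  ({pct})")
        if name != "activated":
            lines.append("      |")
            lines.append("      v")
    return "\n".join(lines)


def write_funnel_report(funnels: Sequence[FunnelCounts], path) -> None:
    with open(path, "w") as fh:
        json.dump(funnel_report(funnels), fh, indent=2, sort_keys=True)
        fh.write("\n")
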
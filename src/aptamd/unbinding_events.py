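"""Unbinding/rebinding event detection and front/back-door classification.

A trajectory starts in the bound (IN) state.  The first frame with
r ≥ r_unbind (default 9 Å) emits an *unbind* event and switches to OUT; the
first subsequent frame with r ≤ r_rebind (default 1 Å) emits a *rebind* and
switches back to IN.  Because a biased simulation expels the ligand almost
immediately, counting conventionally starts at the first rebind
(``skip_initial_unbind``).  Each event is classified through the front door
(z > 0 at the event frame, ties counting as front) or the back door (z < 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .pocket_geometry import CVTrace

__all__ = ["EventRecord", "EventTable", "detect_events", "tabulate_events"]


@dataclass(frozen=True)
class EventRecord:
    frame: int
    time: float  # ps
    kind: str  # "unbind" | "rebind"
    door: str  # "front" | "back"
    z_at_event: float


@dataclass
class EventTable:
    """Per-label counts of unbinding and rebinding events by door."""

    table: pd.DataFrame  # columns: ligand, unbind_front, unbind_back, rebind_front, rebind_back

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def detect_events(
    trace: CVTrace,
    r_unbind: float = 9.0,
    r_rebind: float = 1.0,
    skip_initial_unbind: bool = True,
) -> list[EventRecord]:
    """Run the two-threshold state machine over a CV trace."""
    if r_rebind >= r_unbind:
        raise ValueError("r_rebind must be smaller than r_unbind")
    events: list[EventRecord] = []
    state = "IN"
    for i, (r, z, t) in enumerate(zip(trace.r, trace.z, trace.times)):
        if state == "IN" and r >= r_unbind:
            events.append(_record(i, t, "unbind", z))
            state = "OUT"
        elif state == "OUT" and r <= r_rebind:
            events.append(_record(i, t, "rebind", z))
            state = "IN"
    if skip_initial_unbind and events and events[0].kind == "unbind":
        events = events[1:]
    return events


def _record(frame: int, time: float, kind: str, z: float) -> EventRecord:
    door = "front" if z >= 0 else "back"
    return EventRecord(frame=frame, time=float(time), kind=kind, door=door, z_at_event=float(z))


def _validate_alternation(events: Sequence[EventRecord], label: str) -> None:
    kinds = [e.kind for e in events]
    for a, b in zip(kinds, kinds[1:]):
        if a == b:
            raise ValueError(f"{label}: events do not alternate ({a!r} repeated)")


def tabulate_events(
    event_lists: Iterable[Sequence[EventRecord]] | dict[str, Iterable[Sequence[EventRecord]]],
    labels: Sequence[str] | None = None,
) -> EventTable:
    """Aggregate per-trajectory event lists into door-resolved counts.

    Accepts either a mapping ``{ligand label: [list of per-trajectory event
    lists]}`` or a flat iterable of per-trajectory lists with a parallel
    ``labels`` sequence.  Within each trajectory events must strictly
    alternate; a violation (possible only for externally supplied lists)
    raises a validation error.
    """
    if isinstance(event_lists, dict):
        grouped = {k: list(v) for k, v in event_lists.items()}
    else:
        event_lists = list(event_lists)
        if labels is None:
            labels = ["all"] * len(event_lists)
        grouped = {}
        for lab, ev in zip(labels, event_lists):
            grouped.setdefault(lab, []).append(ev)
    rows = []
    for lab, trajs in grouped.items():
        counts = {"unbind_front": 0, "unbind_back": 0, "rebind_front": 0, "rebind_back": 0}
        for k, events in enumerate(trajs):
            _validate_alternation(events, f"{lab}[{k}]")
            for e in events:
                counts[f"{e.kind}_{e.door}"] += 1
        rows.append({"ligand": lab, **counts})
    return EventTable(table=pd.DataFrame(rows))
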
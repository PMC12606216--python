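"""Reading and writing the package's plain-text formats.

Touch-event logs travel as CSV with header ``t_ms,x,y,phase,touch_id``
(blank ``touch_id`` allowed).  Coordinates may be stored normalised or in
device points; pass a :class:`~playnet.zones.ZoneMap` (whose
``screen_size`` is used) to normalise on read.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .swipes import TouchEvent, validate_events
from .zones import ZoneMap

__all__ = ["read_touch_log", "write_touch_log"]

_COLUMNS = ["t_ms", "x", "y", "phase", "touch_id"]


def read_touch_log(
    path: str | Path, zone_map: ZoneMap | None = None
) -> list[TouchEvent]:
    """Read a touch-event CSV; validates time ordering and coordinate
    ranges.  If ``zone_map`` is given, x/y are treated as device points
    and divided by its screen size."""
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"touch log {path} missing columns {missing}")
    if "touch_id" not in df.columns:
        df["touch_id"] = pd.NA
    sx, sy = (zone_map.screen_size if zone_map is not None else (1.0, 1.0))
    events = [
        TouchEvent(
            t=float(r.t_ms),
            x=float(r.x) / sx,
            y=float(r.y) / sy,
            phase=str(r.phase),
            touch_id=None if pd.isna(r.touch_id) else int(r.touch_id),
        )
        for r in df.itertuples()
    ]
    validate_events(events)
    return events


def write_touch_log(
    events: Sequence[TouchEvent], path: str | Path
) -> None:
    """Write normalised events in the same CSV dialect."""
    df = pd.DataFrame(
        {
            "t_ms": [e.t for e in events],
            "x": [e.x for e in events],
            "y": [e.y for e in events],
            "phase": [e.phase for e in events],
            "touch_id": [e.touch_id for e in events],
        }
    )
    df.to_csv(path, index=False)
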
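"""Assembly of raw touch contacts into swipes.

A *swipe* is a continuous screen contact: it begins when a finger touches
the screen (a ``down`` event) and ends when that contact is removed (the
first subsequent ``up`` event assigned to it).  With several fingers or
hands on the screen the log interleaves contacts from simultaneous swipes;
when the hardware supplies a stable touch id it is trusted, and when it
does not, each unassigned contact is matched to the concurrent swipe whose
*predicted* next location is nearest.

The predictor fits a cubic curve through a swipe's four most recent
contacts, parameterised by timestamp, and extrapolates it to the incoming
event's timestamp.  When four contacts are not yet available the last two
are extrapolated linearly, and a single contact predicts itself.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "TouchEvent",
    "Swipe",
    "predict_next_location",
    "assemble_swipes",
]

logger = logging.getLogger(__name__)

_PHASES = ("down", "move", "up")


class TouchEvent(NamedTuple):
    """One contact sample: time (ms since session start), normalised
    position, event phase and the hardware touch id if the device
    reported one."""

    t: float
    x: float
    y: float
    phase: str
    touch_id: int | None = None


@dataclass
class Swipe:
    """A time-ordered trajectory of contact samples from touch-down to
    touch-up."""

    swipe_id: int
    contacts: list[TouchEvent] = field(default_factory=list)

    @property
    def start_t(self) -> float:
        return self.contacts[0].t

    @property
    def end_t(self) -> float:
        return self.contacts[-1].t

    @property
    def first(self) -> TouchEvent:
        return self.contacts[0]

    @property
    def last(self) -> TouchEvent:
        return self.contacts[-1]

    def __len__(self) -> int:
        return len(self.contacts)


def validate_events(events: Sequence[TouchEvent]) -> None:
    """Check the touch-event invariants: non-decreasing time, coordinates
    in the unit square, known phases."""
    prev_t = -math.inf
    for ev in events:
        if ev.t < 0:
            raise ValueError(f"negative timestamp {ev.t}")
        if ev.t < prev_t:
            raise ValueError(f"events not time-ordered at t={ev.t}")
        if not (0.0 <= ev.x <= 1.0 and 0.0 <= ev.y <= 1.0):
            raise ValueError(f"event at t={ev.t} outside normalised screen")
        if ev.phase not in _PHASES:
            raise ValueError(f"unknown phase {ev.phase!r}")
        prev_t = ev.t


def predict_next_location(
    recent_contacts: Sequence[TouchEvent], t_next: float
) -> tuple[float, float]:
    """Predict where a swipe's next contact will land at time ``t_next``.

    With at least four prior contacts, the unique cubic polynomial through
    the last four (x and y each as functions of time) is evaluated at
    ``t_next``; on four points this coincides with the standard
    (not-a-knot) cubic spline, so collinear constant-speed contacts
    extrapolate along their line and contacts on a parabolic arc follow
    the parabola.  With two or three contacts the curve cannot be
    generated and the last two contacts are extrapolated linearly; a
    single contact predicts its own position.
    """
    if not recent_contacts:
        raise ValueError("recent_contacts must be non-empty")
    if len(recent_contacts) == 1:
        c = recent_contacts[-1]
        return (c.x, c.y)

    if len(recent_contacts) >= 4:
        window = recent_contacts[-4:]
        t = np.array([c.t for c in window], dtype=float)
        # normalise the time axis for conditioning; distinct times needed
        span = t[-1] - t[0]
        if span > 0 and len(set(t.tolist())) == 4:
            u = (t - t[0]) / span
            V = np.vander(u, 4, increasing=True)
            try:
                coef = np.linalg.solve(
                    V, np.array([[c.x, c.y] for c in window], dtype=float)
                )
            except np.linalg.LinAlgError:
                coef = None
            if coef is not None:
                un = (t_next - t[0]) / span
                powers = un ** np.arange(4)
                px, py = powers @ coef
                return (float(px), float(py))

    a, b = recent_contacts[-2], recent_contacts[-1]
    if b.t == a.t:
        return (b.x, b.y)
    frac = (t_next - a.t) / (b.t - a.t)
    return (a.x + frac * (b.x - a.x), a.y + frac * (b.y - a.y))


def assemble_swipes(
    events: Iterable[TouchEvent],
    *,
    use_touch_ids: bool = True,
    max_assignment_distance: float = 0.25,
    validate: bool = True,
) -> list[Swipe]:
    """Group a session's touch events into swipes.

    Every event (except dropped orphan ``up`` events) ends up in exactly
    one swipe.  A ``down`` event always opens a new swipe.  ``move`` and
    ``up`` events carrying a hardware touch id join the open swipe with
    that id (when ``use_touch_ids``); events without an id join the open
    swipe whose predicted next location is nearest in Euclidean distance.
    An ``up`` event closes its swipe.

    A ``move`` event farther than ``max_assignment_distance`` from every
    prediction (or arriving with no swipe open) starts a recovery swipe,
    so logs with dropped ``down``/``up`` events cannot chain distant
    contacts; an orphan ``up`` event is dropped with a warning.

    Returns swipes ordered by start time.
    """
    events = list(events)
    if validate:
        validate_events(events)

    swipes: list[Swipe] = []
    open_by_id: dict[int, Swipe] = {}
    open_anonymous: list[Swipe] = []

    def new_swipe(ev: TouchEvent) -> Swipe:
        sw = Swipe(swipe_id=len(swipes))
        sw.contacts.append(ev)
        swipes.append(sw)
        return sw

    def nearest_open(ev: TouchEvent) -> tuple[Swipe | None, float]:
        best: Swipe | None = None
        best_d = math.inf
        for sw in open_anonymous:
            px, py = predict_next_location(sw.contacts, ev.t)
            d = math.hypot(ev.x - px, ev.y - py)
            if d < best_d:
                best, best_d = sw, d
        return best, best_d

    for ev in events:
        keyed = use_touch_ids and ev.touch_id is not None
        if ev.phase == "down":
            sw = new_swipe(ev)
            if keyed:
                if ev.touch_id in open_by_id:
                    # stale open swipe with the same id: close it silently
                    del open_by_id[ev.touch_id]
                open_by_id[ev.touch_id] = sw
            else:
                open_anonymous.append(sw)
        elif keyed:
            sw = open_by_id.get(ev.touch_id)
            if sw is None:
                if ev.phase == "up":
                    logger.warning(
                        "dropping orphan up event at t=%s (touch id %s)",
                        ev.t, ev.touch_id,
                    )
                    continue
                sw = new_swipe(ev)
                open_by_id[ev.touch_id] = sw
            else:
                sw.contacts.append(ev)
            if ev.phase == "up":
                del open_by_id[ev.touch_id]
        else:
            sw, dist = nearest_open(ev)
            if sw is None or dist > max_assignment_distance:
                if ev.phase == "up":
                    logger.warning("dropping orphan up event at t=%s", ev.t)
                    continue
                sw = new_swipe(ev)
                open_anonymous.append(sw)
            else:
                sw.contacts.append(ev)
                if ev.phase == "up":
                    open_anonymous.remove(sw)

    swipes.sort(key=lambda s: (s.start_t, s.swipe_id))
    for i, sw in enumerate(swipes):
        sw.swipe_id = i
    return swipes
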
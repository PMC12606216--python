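"""Synthetic touchscreen gameplay: sessions and cohorts.

The study's participant data are access-restricted, so this module
generates touch-event logs with the structure the analysis assumes: a
5-minute session of game *cycles*, each presenting one food item that
splits into four pieces to be dragged from the foreground food zone onto
the four characters' plates.  A cycle is either *direct* (each piece
delivered straight to its own plate) or *stacked* (all four pieces piled
on one plate, then redistributed with three inter-plate swipes).  Around
the deliveries the generator sprinkles off-task between-zone swipes, taps,
within-zone wiggles and optional overlapping (multi-touch) swipes.

Every generated swipe carries a ground-truth label, so the swipe
assembler, the transition-network counts and the cohort statistics can be
checked against what was actually simulated.  Cohorts draw per-participant
ages and map them to strategy parameters through per-group linear
age-response slopes, which is what lets recovery experiments reproduce the
qualitative group and age effects of interest (direct players vs stackers,
stacking probability rising with age).

What this generator does *not* emulate: real finger kinematics, game
animations and their timing feedback, or clinical heterogeneity — see the
methods note for the implications.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .swipes import TouchEvent
from .zones import Zone, ZoneMap, default_zone_map

__all__ = [
    "StrategyProfile",
    "GroupSpec",
    "CohortSpec",
    "SwipeTruth",
    "simulate_session",
    "simulate_cohort",
    "simulate_multitouch_stream",
    "direct_profile",
    "stacker_profile",
    "offtask_heavy_profile",
    "degenerate_profile",
    "recovery_cohort_spec",
    "age_trend_cohort_spec",
]

TRUTH_LABELS = (
    "direct_delivery",
    "stack_delivery",
    "inter_plate",
    "offtask",
    "tap",
    "within_zone",
)


@dataclass(frozen=True)
class StrategyProfile:
    """Per-participant gameplay parameters.

    Parameters
    ----------
    n_cycles:
        Food cycles in a session (default 12, the nominal 5-minute game).
    p_direct:
        Probability a piece in a non-stacked cycle is delivered straight
        to its target plate; otherwise it is dropped on another plate and
        redistributed with one inter-plate swipe.
    p_stack:
        Probability a cycle is played stack-then-redistribute.
    offtask_rate / tap_rate / within_zone_rate:
        Expected off-task between-zone swipes, taps and within-zone swipes
        per cycle (Poisson).
    multitouch_prob:
        Probability a swipe's start is pulled back to overlap the previous
        swipe in time (simultaneous contacts).
    contact_hz:
        Sampling rate of move events (default 60 Hz, typical touch panel).
    noise_sd:
        Positional jitter of interior samples, normalised units.
    """

    n_cycles: int = 12
    p_direct: float = 1.0
    p_stack: float = 0.2
    offtask_rate: float = 1.0
    tap_rate: float = 0.0
    within_zone_rate: float = 0.0
    multitouch_prob: float = 0.0
    contact_hz: float = 60.0
    noise_sd: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_direct", "p_stack", "multitouch_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("offtask_rate", "tap_rate", "within_zone_rate", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be >= 0")
        if self.contact_hz <= 0:
            raise ValueError("contact_hz must be positive")


class SwipeTruth(NamedTuple):
    """Ground-truth record for one generated swipe."""

    label: str
    origin_vertex: int
    destination_vertex: int
    start_t: float


# ---------------------------------------------------------------------------
# low-level trajectory synthesis

def _point_in(zone: Zone, rng: np.random.Generator, margin: float = 0.2):
    x0, y0, x1, y1 = zone.rectangle
    dx, dy = x1 - x0, y1 - y0
    return (
        rng.uniform(x0 + margin * dx, x1 - margin * dx),
        rng.uniform(y0 + margin * dy, y1 - margin * dy),
    )


def _trajectory(
    p0: tuple[float, float],
    p1: tuple[float, float],
    t0: float,
    rng: np.random.Generator,
    contact_hz: float,
    noise_sd: float,
    touch_id: int,
) -> tuple[list[TouchEvent], float]:
    """Smooth quadratic-Bezier drag from p0 to p1 starting at t0; interior
    samples get jitter, the endpoints stay exact.  Returns the events and
    the end time."""
    dist = float(np.hypot(p1[0] - p0[0], p1[1] - p0[1]))
    dur = rng.uniform(250.0, 450.0) * (0.5 + dist)
    n = max(2, int(round(dur / 1000.0 * contact_hz)))
    u = np.linspace(0.0, 1.0, n)
    # control point: midpoint pushed sideways for a natural curve
    mid = np.array([(p0[0] + p1[0]) / 2, (p0[1] + p1[1]) / 2])
    normal = np.array([-(p1[1] - p0[1]), p1[0] - p0[0]])
    ctrl = mid + normal * rng.normal(0.0, 0.15)
    pts = (
        np.outer((1 - u) ** 2, p0)
        + np.outer(2 * u * (1 - u), ctrl)
        + np.outer(u**2, p1)
    )
    if noise_sd > 0 and n > 2:
        pts[1:-1] += rng.normal(0.0, noise_sd, size=(n - 2, 2))
    pts = np.clip(pts, 0.0, 1.0)
    times = t0 + u * dur
    events = []
    for i in range(n):
        phase = "down" if i == 0 else ("up" if i == n - 1 else "move")
        events.append(
            TouchEvent(float(times[i]), float(pts[i, 0]), float(pts[i, 1]), phase, touch_id)
        )
    return events, float(times[-1])


# ---------------------------------------------------------------------------
# session synthesis

def simulate_session(
    profile: StrategyProfile, zm: ZoneMap | None = None
) -> tuple[list[TouchEvent], list[SwipeTruth]]:
    """Generate one session's touch-event log and per-swipe truth labels.

    Deliveries end inside plate rectangles and redistribution swipes start
    inside them, so on a noise-free log the assembled endpoint counts
    recover the truth labels exactly.  Fully reproducible from
    ``profile.seed``; truth records are sorted by swipe start time, the
    same order in which the assembler returns swipes.
    """
    zm = zm if zm is not None else default_zone_map()
    rng = np.random.default_rng(profile.seed)
    food = zm.zone(zm.food_vertex)
    plates = [zm.zone(v) for v in sorted(zm.plate_vertices)]
    others = [z for z in zm.zones if z.role == "other"]

    planned: list[tuple[str, Zone, Zone]] = []  # (label, origin zone, dest zone)
    for _ in range(profile.n_cycles):
        cycle: list[tuple[str, Zone, Zone]] = []
        if rng.random() < profile.p_stack:
            k = int(rng.integers(4))
            for _ in range(4):
                cycle.append(("stack_delivery", food, plates[k]))
            for j in rng.permutation([i for i in range(4) if i != k]):
                cycle.append(("inter_plate", plates[k], plates[int(j)]))
        else:
            order = rng.permutation(4)
            for i in order:
                if rng.random() < profile.p_direct:
                    cycle.append(("direct_delivery", food, plates[int(i)]))
                else:
                    j = int(rng.choice([v for v in range(4) if v != i]))
                    cycle.append(("stack_delivery", food, plates[j]))
                    cycle.append(("inter_plate", plates[j], plates[int(i)]))
        extras: list[tuple[str, Zone, Zone]] = []
        for _ in range(rng.poisson(profile.offtask_rate)):
            o, d = rng.choice(len(others), size=2, replace=False)
            extras.append(("offtask", others[int(o)], others[int(d)]))
        for _ in range(rng.poisson(profile.tap_rate)):
            z = others[int(rng.integers(len(others)))]
            extras.append(("tap", z, z))
        for _ in range(rng.poisson(profile.within_zone_rate)):
            extras.append(("within_zone", food, food))
        # deliveries keep their order (the game's narrative); extras are
        # spliced in at random positions
        for ex in extras:
            pos = int(rng.integers(len(cycle) + 1))
            cycle.insert(pos, ex)
        planned.extend(cycle)

    events: list[TouchEvent] = []
    truth: list[SwipeTruth] = []
    t = 0.0
    prev_start, prev_end = 0.0, 0.0
    for touch_id, (label, zo, zd) in enumerate(planned):
        t0 = t + rng.uniform(80.0, 300.0)
        if (
            profile.multitouch_prob > 0
            and truth
            and rng.random() < profile.multitouch_prob
            and prev_end > prev_start
        ):
            # overlap the previous swipe in time
            t0 = prev_start + rng.uniform(0.2, 0.6) * (prev_end - prev_start)
            t0 = max(t0, prev_start + 1.0)
        if label == "tap":
            x, y = _point_in(zo, rng)
            dur = rng.uniform(40.0, 120.0)
            ev = [
                TouchEvent(t0, x, y, "down", touch_id),
                TouchEvent(t0 + dur, x, y, "up", touch_id),
            ]
            end = t0 + dur
        else:
            p0 = _point_in(zo, rng)
            p1 = _point_in(zd, rng)
            if label == "within_zone":
                # a short wiggle that stays inside the zone
                p1 = _point_in(zo, rng)
            ev, end = _trajectory(
                p0, p1, t0, rng, profile.contact_hz, profile.noise_sd, touch_id
            )
        events.extend(ev)
        truth.append(
            SwipeTruth(label, zo.vertex_index, zd.vertex_index, t0)
        )
        prev_start, prev_end = t0, end
        t = max(t, end)

    events.sort(key=lambda e: e.t)
    truth.sort(key=lambda s: s.start_t)
    return events, truth


def simulate_multitouch_stream(
    n_pairs: int,
    seed: int = 0,
    separation: float = 0.15,
    contact_hz: float = 60.0,
) -> list[TouchEvent]:
    """Pairs of simultaneous parallel drags confined to horizontal bands
    kept at least ``separation`` apart in y, with interleaved timestamps —
    the worst case for id-free contact-to-swipe assignment that is still
    unambiguous.  Events carry touch ids so assembly can be compared with
    ids kept vs stripped."""
    rng = np.random.default_rng(seed)
    events: list[TouchEvent] = []
    t = 0.0
    for pair in range(n_pairs):
        y_top = rng.uniform(0.05, 0.40)
        y_bot = y_top + separation + rng.uniform(0.05, 0.25)
        y_bot = min(y_bot, 0.95)
        t0 = t + rng.uniform(100.0, 300.0)
        for k, yy in enumerate((y_top, y_bot)):
            x_start = rng.uniform(0.05, 0.3)
            x_end = rng.uniform(0.7, 0.95)
            ev, end = _trajectory(
                (x_start, yy),
                (x_end, yy + rng.uniform(-0.02, 0.02)),
                t0 + k * rng.uniform(0.0, 30.0),
                rng,
                contact_hz,
                0.001,
                touch_id=2 * pair + k,
            )
            events.extend(ev)
            t = max(t, end)
    events.sort(key=lambda e: e.t)
    return events


# ---------------------------------------------------------------------------
# cohorts

@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: a base strategy profile plus linear age-response
    slopes (per month, centred on 51 months, the mid-range age).  Derived
    probabilities are clipped to [0,1] and rates to >= 0."""

    label: str
    n: int
    age_range: tuple[int, int] = (30, 72)
    base: dict = field(default_factory=dict)
    age_slopes: dict = field(default_factory=dict)
    sex_ratio: float = 0.5  # probability of "F"
    severity_probs: tuple[float, ...] | None = None  # levels 1..k

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("each group needs n >= 1")
        lo, hi = self.age_range
        if not (30 <= lo <= hi <= 72):
            raise ValueError("age range must lie within [30, 72] months")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    seed: int = 0


_AGE_CENTRE = 51.0


def _profile_for(
    group: GroupSpec, age: float, seed: int
) -> StrategyProfile:
    params = dict(group.base)
    for name, slope in group.age_slopes.items():
        params[name] = params.get(
            name, getattr(StrategyProfile, name)
        ) + slope * (age - _AGE_CENTRE)
    for name in ("p_direct", "p_stack", "multitouch_prob"):
        if name in params:
            params[name] = float(np.clip(params[name], 0.0, 1.0))
    for name in ("offtask_rate", "tap_rate", "within_zone_rate", "noise_sd"):
        if name in params:
            params[name] = max(0.0, float(params[name]))
    if "n_cycles" in params:
        params["n_cycles"] = max(0, int(round(params["n_cycles"])))
    return StrategyProfile(seed=seed, **params)


def simulate_cohort(
    spec: CohortSpec, zm: ZoneMap | None = None
) -> tuple[pd.DataFrame, dict[str, tuple[list[TouchEvent], list[SwipeTruth]]]]:
    """Generate a cohort: a participant manifest and per-participant logs.

    Ages are drawn uniformly (integer months) per group range; each
    participant's strategy profile is the group base adjusted by the age
    slopes; everything is deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    logs: dict[str, tuple[list[TouchEvent], list[SwipeTruth]]] = {}
    pid = 0
    for group in spec.groups:
        lo, hi = group.age_range
        for _ in range(group.n):
            age = int(rng.integers(lo, hi + 1))
            sex = "F" if rng.random() < group.sex_ratio else "M"
            severity = None
            if group.severity_probs is not None:
                p = np.asarray(group.severity_probs, dtype=float)
                severity = int(rng.choice(len(p), p=p / p.sum())) + 1
            part_seed = int(rng.integers(2**31))
            participant_id = f"P{pid:04d}"
            pid += 1
            profile = _profile_for(group, age, part_seed)
            logs[participant_id] = simulate_session(profile, zm)
            rows.append(
                {
                    "participant_id": participant_id,
                    "group": group.label,
                    "age_months": age,
                    "sex": sex,
                    "severity": severity,
                    "seed": part_seed,
                }
            )
    manifest = pd.DataFrame(rows)
    return manifest, logs


# ---------------------------------------------------------------------------
# presets: the study conditions used by tests, examples and the
# acceptance experiments

def direct_profile(seed: int = 0, **overrides) -> StrategyProfile:
    """A focused direct sharer: almost every cycle delivers each piece
    straight to its plate."""
    base = dict(n_cycles=12, p_direct=1.0, p_stack=0.05)
    base.update(overrides)
    return StrategyProfile(seed=seed, **base)


def stacker_profile(seed: int = 0, **overrides) -> StrategyProfile:
    """A stack-then-redistribute player: most cycles pile the four pieces
    on one plate before sharing them out."""
    base = dict(n_cycles=12, p_direct=1.0, p_stack=0.85)
    base.update(overrides)
    return StrategyProfile(seed=seed, **base)


def offtask_heavy_profile(seed: int = 0, **overrides) -> StrategyProfile:
    """A distractible player: deliveries diluted by many off-task swipes
    and taps."""
    base = dict(n_cycles=8, p_stack=0.2, offtask_rate=5.0, tap_rate=2.0)
    base.update(overrides)
    return StrategyProfile(seed=seed, **base)


def degenerate_profile(seed: int = 0, **overrides) -> StrategyProfile:
    """No between-zone swipes at all: taps and within-zone wiggles only."""
    base = dict(
        n_cycles=0, offtask_rate=0.0, tap_rate=0.0, within_zone_rate=0.0
    )
    base.update(overrides)
    return StrategyProfile(seed=seed, **base)


def recovery_cohort_spec(
    seed: int = 0, n_per_group: int = 100
) -> CohortSpec:
    """Two groups matched on everything except strategy: ``direct``
    players (p_stack 0.05) vs ``stacker`` players (p_stack 0.85)."""
    common = dict(n_cycles=12, offtask_rate=1.0, tap_rate=0.5)
    return CohortSpec(
        groups=(
            GroupSpec("direct", n_per_group, base=dict(common, p_stack=0.05)),
            GroupSpec("stacker", n_per_group, base=dict(common, p_stack=0.85)),
        ),
        seed=seed,
    )


def age_trend_cohort_spec(
    seed: int = 0, n: int = 100, trending: bool = True
) -> CohortSpec:
    """One group whose stacking probability either rises linearly with age
    (~0.1 at 30 months to ~0.6 at 72) or stays flat at the mid value."""
    if trending:
        group = GroupSpec(
            "trend",
            n,
            base=dict(n_cycles=12, p_stack=0.35),
            age_slopes=dict(p_stack=0.012),
        )
    else:
        group = GroupSpec("flat", n, base=dict(n_cycles=12, p_stack=0.35))
    return CohortSpec(groups=(group,), seed=seed)
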
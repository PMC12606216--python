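"""Screen-zone geometry for the food-sharing game.

The gameplay area is divided into 16 named rectangular zones, each
represented by a vertex of the swipe-transition network:

* one **food zone** ``f`` — the foreground serving area where food pieces
  appear;
* four **snap-to-plate zones** ``s`` — the regions around the four game
  characters within which a released food piece snaps onto that
  character's plate;
* four **plate zones** ``psi`` — smaller zones nested inside each
  snap-to-plate zone, centred on the plate and extended upward so that
  stacked food items remain inside;
* seven **other zones** — characters and background areas with no special
  role in food delivery.

Coordinates are normalised to ``[0, 1] x [0, 1]`` with the origin at the
top-left and y increasing downward (the usual touch-log convention); raw
logs recorded in device points are divided by the screen size on ingestion.

The published description of the game gives zone roles but no pixel
coordinates, so the geometry is configurable: :func:`load_zone_map` reads a
YAML/JSON file, and :func:`default_zone_map` ships a mutually consistent
layout in which the plate vertices are 4–7.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "Zone",
    "ZoneMap",
    "ZoneMapError",
    "default_zone_map",
    "load_zone_map",
    "classify_point",
]

N_ZONES = 16

#: role precedence used by :func:`classify_point`; lower value wins.
_ROLE_PRECEDENCE = {"plate": 0, "snap_to_plate": 1, "food": 2, "other": 3}
_VALID_ROLES = set(_ROLE_PRECEDENCE)


class ZoneMapError(ValueError):
    """Raised when a zone-map configuration violates a structural invariant."""


@dataclass(frozen=True)
class Zone:
    """A rectangular screen zone.

    The rectangle is ``(x0, y0, x1, y1)`` in normalised units with
    ``x0 < x1`` and ``y0 < y1``; containment is inclusive of all edges,
    with overlaps resolved by role precedence and then lower vertex index.
    """

    vertex_index: int
    name: str
    rectangle: tuple[float, float, float, float]
    role: str

    def contains(self, x: float, y: float) -> bool:
        x0, y0, x1, y1 = self.rectangle
        return x0 <= x <= x1 and y0 <= y <= y1


@dataclass(frozen=True)
class ZoneMap:
    """Validated 16-zone layout.

    Attributes
    ----------
    zones
        The 16 zones ordered by vertex index.
    plate_parent
        Bijection from each plate vertex to its enclosing snap-to-plate
        vertex.
    screen_size
        ``(width, height)`` in device points, used to normalise raw pixel
        logs.
    background_vertex
        The ``other`` vertex to which points falling in no configured zone
        are assigned.
    """

    zones: tuple[Zone, ...]
    plate_parent: dict[int, int]
    screen_size: tuple[float, float] = (768.0, 1024.0)
    background_vertex: int = field(default=-1)

    def __post_init__(self) -> None:
        _validate(self)

    # -- convenience vertex sets ------------------------------------------
    @property
    def food_vertex(self) -> int:
        return next(z.vertex_index for z in self.zones if z.role == "food")

    @property
    def plate_vertices(self) -> frozenset[int]:
        return frozenset(z.vertex_index for z in self.zones if z.role == "plate")

    @property
    def snap_vertices(self) -> frozenset[int]:
        return frozenset(
            z.vertex_index for z in self.zones if z.role == "snap_to_plate"
        )

    @property
    def snap_to_plate_child(self) -> dict[int, int]:
        """Inverse of ``plate_parent``: snap vertex -> nested plate vertex."""
        return {s: p for p, s in self.plate_parent.items()}

    def zone(self, vertex: int) -> Zone:
        return self.zones[vertex]


def _validate(zm: ZoneMap) -> None:
    zones = zm.zones
    if len(zones) != N_ZONES:
        raise ZoneMapError(f"expected {N_ZONES} zones, got {len(zones)}")
    for i, z in enumerate(zones):
        if z.vertex_index != i:
            raise ZoneMapError(
                f"zones must be ordered by vertex_index 0..15; "
                f"position {i} holds vertex {z.vertex_index}"
            )
        if z.role not in _VALID_ROLES:
            raise ZoneMapError(f"zone {z.name!r}: unknown role {z.role!r}")
        x0, y0, x1, y1 = z.rectangle
        if not (x0 < x1 and y0 < y1):
            raise ZoneMapError(f"zone {z.name!r}: degenerate rectangle")
        if not (0.0 <= x0 and x1 <= 1.0 and 0.0 <= y0 and y1 <= 1.0):
            raise ZoneMapError(f"zone {z.name!r}: rectangle outside [0,1]^2")

    by_role: dict[str, list[Zone]] = {r: [] for r in _VALID_ROLES}
    for z in zones:
        by_role[z.role].append(z)
    for role, expected in (("food", 1), ("snap_to_plate", 4), ("plate", 4)):
        if len(by_role[role]) != expected:
            raise ZoneMapError(
                f"expected {expected} {role} zone(s), got {len(by_role[role])}"
            )
    if len(by_role["other"]) != N_ZONES - 9:
        raise ZoneMapError(
            f"expected {N_ZONES - 9} 'other' zones, got {len(by_role['other'])}"
        )

    plate_ix = {z.vertex_index for z in by_role["plate"]}
    snap_ix = {z.vertex_index for z in by_role["snap_to_plate"]}
    if set(zm.plate_parent) != plate_ix or set(zm.plate_parent.values()) != snap_ix:
        raise ZoneMapError(
            "plate_parent must be a bijection between plate and "
            "snap-to-plate vertices"
        )
    for p, s in zm.plate_parent.items():
        px0, py0, px1, py1 = zones[p].rectangle
        sx0, sy0, sx1, sy1 = zones[s].rectangle
        if not (sx0 < px0 and px1 < sx1 and sy0 < py0 and py1 < sy1):
            raise ZoneMapError(
                f"plate zone {zones[p].name!r} is not strictly contained in "
                f"its snap-to-plate parent {zones[s].name!r}"
            )

    # same-role rectangles must be pairwise disjoint (interiors)
    for role, group in by_role.items():
        for i, a in enumerate(group):
            for b in group[i + 1 :]:
                ax0, ay0, ax1, ay1 = a.rectangle
                bx0, by0, bx1, by1 = b.rectangle
                if ax0 < bx1 and bx0 < ax1 and ay0 < by1 and by0 < ay1:
                    raise ZoneMapError(
                        f"{role} zones {a.name!r} and {b.name!r} overlap"
                    )

    w, h = zm.screen_size
    if not (w > 0 and h > 0):
        raise ZoneMapError("screen_size must be positive")
    bg = zm.background_vertex
    if bg != -1 and zones[bg].role != "other":
        raise ZoneMapError("background_vertex must be an 'other' zone")


def default_zone_map() -> ZoneMap:
    """The shipped default layout.

    A bottom band holds the food zone; the four snap-to-plate zones span
    the mid-screen in a row, each with a nested plate rectangle extended
    upward to keep piled food inside; four character zones sit above the
    snap-to-plate row and three background strips tile the top of the
    screen.  Vertex assignment: 0 = food, 1–3 = top background strips,
    4–7 = plates, 8–11 = snap-to-plate, 12–15 = characters.
    """
    zones: list[Zone] = [
        Zone(0, "food", (0.0, 0.70, 1.0, 1.0), "food"),
        Zone(1, "other_0", (0.0, 0.0, 1 / 3, 0.12), "other"),
        Zone(2, "other_1", (1 / 3, 0.0, 2 / 3, 0.12), "other"),
        Zone(3, "other_2", (2 / 3, 0.0, 1.0, 0.12), "other"),
    ]
    for k in range(4):
        x0 = 0.25 * k
        zones.append(
            Zone(4 + k, f"plate_{k}", (x0 + 0.07, 0.38, x0 + 0.18, 0.66), "plate")
        )
    for k in range(4):
        x0 = 0.25 * k
        zones.append(
            Zone(8 + k, f"snap_{k}", (x0, 0.35, x0 + 0.25, 0.70), "snap_to_plate")
        )
    for k in range(4):
        x0 = 0.25 * k
        zones.append(
            Zone(12 + k, f"other_{3 + k}", (x0, 0.12, x0 + 0.25, 0.35), "other")
        )
    plate_parent = {4 + k: 8 + k for k in range(4)}
    return ZoneMap(
        zones=tuple(zones),
        plate_parent=plate_parent,
        screen_size=(768.0, 1024.0),
        background_vertex=1,
    )


def _zone_map_from_dict(cfg: dict) -> ZoneMap:
    try:
        zones = tuple(
            Zone(
                vertex_index=int(z["vertex_index"]),
                name=str(z["name"]),
                rectangle=tuple(float(v) for v in z["rectangle"]),
                role=str(z["role"]),
            )
            for z in cfg["zones"]
        )
        plate_parent = {int(k): int(v) for k, v in cfg["plate_parent"].items()}
        screen_size = tuple(float(v) for v in cfg.get("screen_size", (768, 1024)))
        background = int(cfg.get("background_vertex", -1))
    except (KeyError, TypeError, ValueError) as exc:
        raise ZoneMapError(f"malformed zone-map configuration: {exc}") from exc
    zones = tuple(sorted(zones, key=lambda z: z.vertex_index))
    return ZoneMap(zones, plate_parent, screen_size, background)


def zone_map_to_dict(zm: ZoneMap) -> dict:
    """Serialisable representation accepted back by :func:`load_zone_map`."""
    return {
        "zones": [
            {
                "vertex_index": z.vertex_index,
                "name": z.name,
                "rectangle": list(z.rectangle),
                "role": z.role,
            }
            for z in zm.zones
        ],
        "plate_parent": {str(k): v for k, v in zm.plate_parent.items()},
        "screen_size": list(zm.screen_size),
        "background_vertex": zm.background_vertex,
    }


def load_zone_map(config_path: str | Path | None = None) -> ZoneMap:
    """Load and validate a zone map from a YAML or JSON file.

    With ``config_path=None`` the embedded default layout is returned.
    Raises :class:`ZoneMapError` naming the violated invariant on any
    structural problem.
    """
    if config_path is None:
        return default_zone_map()
    path = Path(config_path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ZoneMapError("zone-map configuration must be a mapping")
    return _zone_map_from_dict(cfg)


def classify_point(x: float, y: float, zm: ZoneMap) -> int:
    """Map a normalised screen point to the vertex of its most specific zone.

    Precedence is plate > snap-to-plate > food > other, then lower vertex
    index; this makes classification a total, deterministic function on
    ``[0,1]^2`` even on shared rectangle edges.  Points covered by no
    configured zone fall back to the designated background vertex.
    """
    if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
        raise ValueError(f"point ({x}, {y}) outside the normalised screen [0,1]^2")
    best: Zone | None = None
    for z in zm.zones:
        if z.contains(x, y):
            if best is None or (
                (_ROLE_PRECEDENCE[z.role], z.vertex_index)
                < (_ROLE_PRECEDENCE[best.role], best.vertex_index)
            ):
                best = z
    if best is None:
        if zm.background_vertex == -1:
            raise ZoneMapError(
                "point covered by no zone and no background_vertex configured"
            )
        return zm.background_vertex
    return best.vertex_index
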
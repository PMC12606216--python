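"""Zone-transition networks built from assembled swipes.

Each swipe that begins in one zone and ends in another contributes one
directed edge to a 16x16 swipe transition matrix ``T`` whose entry
``T[i, j]`` counts swipes from zone ``i`` to zone ``j``; taps and
within-zone swipes are excluded, so the diagonal is zero.

Two rewired variants encode the food-delivery narrative:

* **direct** (``T^D``): a delivery must originate in the food zone ``f``
  and end in a snap-to-plate or plate zone; its destination is unified to
  the plate vertex.  Any other swipe ending in a plate zone is reconnected
  to end at the enclosing snap-to-plate vertex, since it cannot be moving
  food.
* **indirect** (``T^I``): deliveries may also originate from plate zones
  (inter-plate redistribution of stacked food), again with plate-vertex
  destinations — except that a swipe from a plate to its *own* surrounding
  snap-to-plate zone keeps the snap-to-plate destination, because the food
  simply falls back onto the same plate.

Each variant is normalised by its total swipe count and a complete-graph
baseline ``C`` (uniform weight 0.01) is added, giving a strictly positive
adjacency matrix ``A = T / sum(T) + C`` comparable across participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .swipes import Swipe
from .zones import N_ZONES, ZoneMap, classify_point

__all__ = [
    "WITHIN_ZONE",
    "TransitionNetwork",
    "AdjacencyMatrix",
    "swipe_to_transition",
    "build_raw_network",
    "apply_direct_rules",
    "apply_indirect_rules",
    "normalise_with_baseline",
    "count_food_delivery_swipes",
    "count_inter_plate_swipes",
]

#: sentinel returned for swipes whose endpoints share a zone (incl. taps)
WITHIN_ZONE = None

DEFAULT_BASELINE = 0.01


@dataclass
class TransitionNetwork:
    """A 16x16 integer transition-count matrix plus the per-swipe endpoint
    list it was aggregated from (the rewiring rules need each swipe's true
    origin, so the endpoint list is retained)."""

    T: np.ndarray
    variant: str  # raw | direct | indirect
    zone_map: ZoneMap
    transitions: list[tuple[int, int]] = field(default_factory=list)

    @property
    def total(self) -> int:
        return int(self.T.sum())


@dataclass
class AdjacencyMatrix:
    """Normalised transition weights plus the uniform baseline graph."""

    A: np.ndarray
    baseline_weight: float
    variant: str
    zone_map: ZoneMap
    degenerate: bool = False


def swipe_to_transition(swipe: Swipe, zm: ZoneMap) -> tuple[int, int] | None:
    """Classify a swipe's endpoints; returns ``(origin, destination)``
    vertices or the :data:`WITHIN_ZONE` sentinel when both endpoints share
    a zone (which covers taps, whose single contact is both endpoints)."""
    o = classify_point(swipe.first.x, swipe.first.y, zm)
    d = classify_point(swipe.last.x, swipe.last.y, zm)
    if o == d:
        return WITHIN_ZONE
    return (o, d)


def _matrix_from_transitions(transitions: Iterable[tuple[int, int]]) -> np.ndarray:
    T = np.zeros((N_ZONES, N_ZONES), dtype=np.int64)
    for o, d in transitions:
        T[o, d] += 1
    return T


def build_raw_network(swipes: Sequence[Swipe], zm: ZoneMap) -> TransitionNetwork:
    """Count every between-zone swipe once; the diagonal stays zero."""
    transitions = [
        tr for sw in swipes if (tr := swipe_to_transition(sw, zm)) is not WITHIN_ZONE
    ]
    return TransitionNetwork(
        T=_matrix_from_transitions(transitions),
        variant="raw",
        zone_map=zm,
        transitions=transitions,
    )


def _rewire_direct(o: int, d: int, zm: ZoneMap) -> tuple[int, int]:
    f = zm.food_vertex
    psi = zm.plate_vertices
    s = zm.snap_vertices
    child = zm.snap_to_plate_child
    if o == f and (d in s or d in psi):
        return (o, d if d in psi else child[d])
    if d in psi and o != f:
        return (o, zm.plate_parent[d])
    return (o, d)


def _rewire_indirect(o: int, d: int, zm: ZoneMap) -> tuple[int, int]:
    f = zm.food_vertex
    psi = zm.plate_vertices
    s = zm.snap_vertices
    child = zm.snap_to_plate_child
    if o == f and (d in s or d in psi):
        return (o, d if d in psi else child[d])
    if o in psi:
        if d == zm.plate_parent[o]:
            # back onto its own plate: not a delivery, destination kept
            return (o, d)
        if d in s:
            return (o, child[d])
        if d in psi:
            return (o, d)
        return (o, d)
    if d in psi:
        # cannot be moving food: reconnect to the surrounding snap zone
        return (o, zm.plate_parent[d])
    return (o, d)


def _rewired(net: TransitionNetwork, variant: str, rule) -> TransitionNetwork:
    if net.variant != "raw":
        raise ValueError(f"rewiring expects a raw network, got {net.variant!r}")
    zm = net.zone_map
    transitions = [rule(o, d, zm) for o, d in net.transitions]
    return TransitionNetwork(
        T=_matrix_from_transitions(transitions),
        variant=variant,
        zone_map=zm,
        transitions=transitions,
    )


def apply_direct_rules(net: TransitionNetwork) -> TransitionNetwork:
    """Rewire a raw network so only food-zone origins deliver to plates."""
    return _rewired(net, "direct", _rewire_direct)


def apply_indirect_rules(net: TransitionNetwork) -> TransitionNetwork:
    """Rewire a raw network so food-zone and plate origins deliver to
    plates (with the own-parent exception)."""
    return _rewired(net, "indirect", _rewire_indirect)


def normalise_with_baseline(
    net: TransitionNetwork, baseline: float = DEFAULT_BASELINE
) -> AdjacencyMatrix:
    """``A = T / sum(T) + C`` with ``C_ij = baseline`` for all i, j
    (diagonal included, keeping A strictly positive so the leading left
    eigenvector is a simple positive Perron vector).  A session with no
    between-zone swipes yields ``A = C``, flagged degenerate."""
    if baseline < 0:
        raise ValueError("baseline weight must be non-negative")
    if net.variant not in ("direct", "indirect"):
        raise ValueError(
            f"normalisation expects a direct or indirect network, got {net.variant!r}"
        )
    total = net.total
    C = np.full((N_ZONES, N_ZONES), baseline, dtype=float)
    if total == 0:
        return AdjacencyMatrix(C, baseline, net.variant, net.zone_map, degenerate=True)
    A = net.T.astype(float) / total + C
    return AdjacencyMatrix(A, baseline, net.variant, net.zone_map)


def count_food_delivery_swipes(swipes: Sequence[Swipe], zm: ZoneMap) -> int:
    """Number of swipes from the food zone into a snap-to-plate or plate
    zone (direct food deliveries)."""
    f = zm.food_vertex
    targets = zm.plate_vertices | zm.snap_vertices
    n = 0
    for sw in swipes:
        tr = swipe_to_transition(sw, zm)
        if tr is not WITHIN_ZONE and tr[0] == f and tr[1] in targets:
            n += 1
    return n


def count_inter_plate_swipes(swipes: Sequence[Swipe], zm: ZoneMap) -> int:
    """Number of swipes that begin in a plate zone and end in a *different*
    character's snap-to-plate or plate zone (redistribution of stacked
    food); a swipe from a plate to its own surrounding snap-to-plate zone
    is not counted."""
    psi = zm.plate_vertices
    s = zm.snap_vertices
    n = 0
    for sw in swipes:
        tr = swipe_to_transition(sw, zm)
        if tr is WITHIN_ZONE:
            continue
        o, d = tr
        if o not in psi:
            continue
        if d == zm.plate_parent[o]:
            continue
        if d in psi or d in s:
            n += 1
    return n


# ---------------------------------------------------------------------------
# edge-list export / import

def write_edge_list(net: TransitionNetwork, csv_path: str | Path) -> None:
    """Write a weighted edge list ``origin,destination,weight`` plus a JSON
    sidecar (``<csv>.json``) with the variant and total swipe count; the
    round trip is bit-exact for integer counts."""
    import json

    path = Path(csv_path)
    lines = ["origin,destination,weight"]
    for o, d in zip(*np.nonzero(net.T)):
        lines.append(f"{o},{d},{net.T[o, d]}")
    path.write_text("\n".join(lines) + "\n")
    sidecar = {"variant": net.variant, "total": net.total}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_edge_list(csv_path: str | Path, zm: ZoneMap) -> TransitionNetwork:
    """Inverse of :func:`write_edge_list`.  The per-swipe endpoint list is
    reconstructed by repeating each edge ``weight`` times (sufficient for
    normalisation and scoring, which depend only on counts)."""
    import json

    path = Path(csv_path)
    T = np.zeros((N_ZONES, N_ZONES), dtype=np.int64)
    transitions: list[tuple[int, int]] = []
    for line in path.read_text().strip().splitlines()[1:]:
        o_s, d_s, w_s = line.split(",")
        o, d, w = int(o_s), int(d_s), int(w_s)
        T[o, d] = w
        transitions.extend([(o, d)] * w)
    sidecar_path = Path(str(path) + ".json")
    variant = "raw"
    if sidecar_path.exists():
        variant = json.loads(sidecar_path.read_text()).get("variant", "raw")
    return TransitionNetwork(T=T, variant=variant, zone_map=zm, transitions=transitions)
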
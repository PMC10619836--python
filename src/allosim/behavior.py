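"""Perception, target choice, carcass-site contests, and predation.

Allosaurs prioritize carrion: the nearest carcass within the olfactory
detection range wins over any prey, and prey are only targeted within the
much shorter binocular-vision radius.  At a carcass site, attendees feed
sequentially in descending dominance order, each taking up to its tailfat
intake cap from the mass standing above the 20% residual floor.  Pursued
prey flee directly away, slowed by the pursuer's hearing score; a kill
attempt fires when the pursuer closes to the capture radius and succeeds
with probability equal to its bite-force ability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .environment import GRID_KM, CarcassObject, Position, torus_distance

__all__ = [
    "CAPTURE_RADIUS_KM",
    "PerceivedTarget",
    "perceive",
    "resolve_feeding",
    "prey_flee_speed",
    "attempt_kill",
]

#: Distance defining a "terminal collision" on continuous coordinates.
CAPTURE_RADIUS_KM = 0.1


@dataclass(frozen=True)
class PerceivedTarget:
    kind: str  # "carcass" | "prey"
    id: int
    distance: float


def perceive(
    pos: Position,
    detection_range: float,
    binocular_vision: float,
    carcasses: Iterable,
    prey: Iterable,
    rng=None,
    preference: str = "carrion_first",
    exclude_prey: Optional[set] = None,
    size: float = GRID_KM,
) -> Optional[PerceivedTarget]:
    """Choose a feeding target from the agent's viewpoint.

    Returns the nearest carcass within ``detection_range`` if any; else
    the nearest prey within ``binocular_vision``; else None (random
    walk).  ``preference="nearest_any"`` instead picks the closer of the
    two candidates.  Exact distance ties are broken by list order (a
    measure-zero event on continuous coordinates).
    """
    best_c = None
    best_cd = detection_range
    for c in carcasses:
        if c.edible_mass <= 0.0:  # a bone pile at the residual floor draws nobody
            continue
        d = torus_distance(pos, c.pos, size)
        if d <= best_cd:
            best_cd = d
            best_c = c
    best_p = None
    best_pd = binocular_vision
    for p in prey:
        if exclude_prey and p.id in exclude_prey:
            continue
        d = torus_distance(pos, p.pos, size)
        if d <= best_pd:
            best_pd = d
            best_p = p
    if preference == "carrion_first":
        if best_c is not None:
            return PerceivedTarget("carcass", best_c.id, best_cd)
        if best_p is not None:
            return PerceivedTarget("prey", best_p.id, best_pd)
        return None
    if preference == "nearest_any":
        cands = []
        if best_c is not None:
            cands.append(PerceivedTarget("carcass", best_c.id, best_cd))
        if best_p is not None:
            cands.append(PerceivedTarget("prey", best_p.id, best_pd))
        if not cands:
            return None
        return min(cands, key=lambda t: t.distance)
    raise ValueError(f"unknown preference: {preference!r}")


def resolve_feeding(
    carcass: CarcassObject,
    attendees: Sequence,
    rng,
    mode: str = "shared",
) -> Dict[int, float]:
    """One day of contested feeding at a carcass site.

    ``attendees`` are agents standing at the carcass, each exposing
    ``.id``, ``.dominance`` and ``.tailfat``.  Under ``mode="shared"``
    they feed in descending dominance order (ties shuffled), each
    consuming min(tailfat cap, remaining edible mass above the 20%
    floor).  Under ``mode="exclusive"`` the top-dominance attendee holds
    the site and feeds alone; everyone else is displaced and gets
    nothing.  The carcass's ``current_mass`` is debited in place; the
    returned mapping gives each agent's intake in kg (one feeding event
    per agent per day).
    """
    if mode not in ("shared", "exclusive"):
        raise ValueError(f"unknown feeding mode: {mode!r}")
    order = list(attendees)
    rng.shuffle(order)  # randomizes ties before the stable sort
    order.sort(key=lambda a: a.dominance, reverse=True)
    if mode == "exclusive":
        order = order[:1]
    intakes: Dict[int, float] = {a.id: 0.0 for a in attendees}
    for agent in order:
        share = min(agent.tailfat, carcass.edible_mass)
        if share <= 0.0:
            continue
        carcass.current_mass -= share
        carcass.consumed_total += share
        intakes[agent.id] = share
    return intakes


def prey_flee_speed(hearing_ability: float, base_speed: float = 3.0) -> float:
    """Speed of a prey animal while pursued, km/day.

    The pursuer's hearing score h in [-0.7, 0.7] slows the prey to
    base_speed * clamp(1 - h, 0.3, 1.7): sharp-eared ambushers close the
    gap, dull-eared ones alert prey into outrunning them.
    """
    factor = 1.0 - hearing_ability
    factor = min(max(factor, 0.3), 1.7)
    return base_speed * factor


def attempt_kill(bite_force_ability: float, rng) -> bool:
    """Single kill attempt at capture range; success probability equals
    the bite-force ability (baseline 0.1 at a medium factor of 1.0)."""
    return rng.random() < bite_force_ability
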
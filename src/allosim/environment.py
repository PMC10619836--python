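"""Toroidal geometry, movement, the carcass calendar, and carcass lifecycle.

The landscape is a flat 70 x 70 km torus (4,900 km^2) with continuous
coordinates.  Sauropod carcasses (10,000-25,000 kg) appear at random
positions during three seasonal windows — the 1st quarter, the 3rd
quarter, and the final 45 days of the year — capped at 5 concurrent, and
calibrated to 15-28 spawns per year.  Carcasses lose mass to consumption
and decay, vanish at 20% of their initial mass (bones and low-value
remains), and additionally face a 0.02/day random-removal hazard that
keeps the resource unpredictable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

__all__ = [
    "GRID_KM",
    "SPAWN_WINDOWS",
    "Position",
    "CarcassObject",
    "Calendar",
    "torus_delta",
    "torus_distance",
    "wrap",
    "move",
    "in_spawn_window",
    "spawn_carcasses",
    "carcass_daily_update",
]

GRID_KM = 70.0

#: Half-open [start, stop) day-of-year windows on a 365-day calendar:
#: Q1 = days 0-90, Q3 = days 182-273, final 45 days = 320-364.
SPAWN_WINDOWS: Tuple[Tuple[int, int], ...] = ((0, 91), (182, 274), (320, 365))

Position = Tuple[float, float]


@dataclass
class CarcassObject:
    """A stationary, decaying meat pool.

    ``origin`` is "sauropod" for seasonal falls and "prey" for killed
    2,000 kg herbivores.  The object is removed once its mass drops below
    20% of the initial mass.  ``consumed_total`` / ``decayed_total`` form
    a conservation ledger.
    """

    id: int
    pos: Position
    initial_mass: float
    origin: str = "sauropod"
    spawn_day: int = 0
    current_mass: float = field(default=None)  # type: ignore[assignment]
    consumed_total: float = 0.0
    decayed_total: float = 0.0

    def __post_init__(self):
        if self.current_mass is None:
            self.current_mass = self.initial_mass

    @property
    def residual_floor(self) -> float:
        return 0.2 * self.initial_mass

    @property
    def edible_mass(self) -> float:
        """Mass available above the 20% removal floor."""
        return max(0.0, self.current_mass - self.residual_floor)


@dataclass
class Calendar:
    day_of_year: int = 0
    year: int = 0

    def advance(self, days_per_year: int = 365) -> None:
        self.day_of_year += 1
        if self.day_of_year >= days_per_year:
            self.day_of_year = 0
            self.year += 1


def torus_delta(p: Position, q: Position, size: float = GRID_KM) -> Tuple[float, float]:
    """Minimal-image displacement vector from p to q."""
    half = size / 2.0
    dx = q[0] - p[0]
    dy = q[1] - p[1]
    if dx > half:
        dx -= size
    elif dx < -half:
        dx += size
    if dy > half:
        dy -= size
    elif dy < -half:
        dy += size
    return dx, dy


def torus_distance(p: Position, q: Position, size: float = GRID_KM) -> float:
    dx, dy = torus_delta(p, q, size)
    return math.hypot(dx, dy)


def wrap(pos: Position, size: float = GRID_KM) -> Position:
    return (pos[0] % size, pos[1] % size)


def move(
    pos: Position,
    target: Optional[Position],
    max_step: float,
    rng,
    size: float = GRID_KM,
) -> Position:
    """One day of travel.

    With a target: advance along the minimal-image bearing by
    min(max_step, distance), landing exactly on the target when it is
    within reach.  Without: a step of max_step on a uniform random
    heading.  The result wraps on both axes.
    """
    if max_step <= 0:
        raise ValueError("max_step must be positive")
    if target is None:
        theta = 2.0 * math.pi * rng.random()
        return wrap((pos[0] + max_step * math.cos(theta), pos[1] + max_step * math.sin(theta)), size)
    dx, dy = torus_delta(pos, target, size)
    dist = math.hypot(dx, dy)
    if dist <= max_step:
        return wrap(target, size)
    f = max_step / dist
    return wrap((pos[0] + f * dx, pos[1] + f * dy), size)


def in_spawn_window(
    day_of_year: int, windows: Sequence[Tuple[int, int]] = SPAWN_WINDOWS
) -> bool:
    """True iff sauropod carcasses may appear on this calendar day."""
    return any(lo <= day_of_year < hi for lo, hi in windows)


def spawn_carcasses(
    day_of_year: int,
    sauropod_count: int,
    next_id: int,
    day: int,
    rng,
    spawn_prob: float = 0.12,
    max_concurrent: int = 5,
    mass_range: Tuple[float, float] = (10000.0, 25000.0),
    windows: Sequence[Tuple[int, int]] = SPAWN_WINDOWS,
    size: float = GRID_KM,
) -> List[CarcassObject]:
    """Daily sauropod-carcass spawning.

    Inside a spawn window, while fewer than ``max_concurrent`` sauropod
    carcasses stand, one spawns with probability ``spawn_prob`` at a
    uniform position with mass uniform on ``mass_range``.  The default
    probability is calibrated (by simulation, under the concurrency cap
    and removal hazard) to the 15-28 spawns-per-year regime.
    """
    if not in_spawn_window(day_of_year, windows):
        return []
    if sauropod_count >= max_concurrent:
        return []
    if rng.random() >= spawn_prob:
        return []
    lo, hi = mass_range
    mass = lo + (hi - lo) * rng.random()
    pos = (size * rng.random(), size * rng.random())
    return [CarcassObject(id=next_id, pos=pos, initial_mass=mass, spawn_day=day)]


def carcass_daily_update(
    c: CarcassObject,
    consumed_today: float,
    rng,
    decay_fraction: float = 0.005,
    removal_prob: float = 0.02,
    decay_model: str = "linear",
) -> Optional[CarcassObject]:
    """End-of-day carcass bookkeeping; returns None when the object is gone.

    Mass lost = consumption + decay.  Decay defaults to a linear
    0.5%-of-initial-mass per day (an unconsumed 10,000 kg fall persists
    ~160 days before hitting the 20% floor); ``decay_model="exponential"``
    instead removes the fraction of *current* mass.  Independently of
    mass, the carcass disappears with probability ``removal_prob`` per
    day.
    """
    if consumed_today < 0 or consumed_today > c.current_mass + 1e-9:
        raise ValueError("consumed_today must be within [0, current_mass]")
    if decay_model == "linear":
        decay = decay_fraction * c.initial_mass
    elif decay_model == "exponential":
        decay = decay_fraction * c.current_mass
    else:
        raise ValueError(f"unknown decay_model: {decay_model!r}")
    decay = min(decay, c.current_mass - consumed_today)
    c.current_mass -= consumed_today + decay
    c.consumed_total += consumed_today
    c.decayed_total += decay
    if c.current_mass < c.residual_floor:
        return None
    if rng.random() < removal_prob:
        return None
    return c
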
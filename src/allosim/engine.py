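"""Daily scheduler, population bookkeeping, and life-history recording.

Each simulated day runs a fixed phase order: (1) carcass spawning,
(2) perception, prey flight and movement, (3) carcass-site feeding
contests, (4) predation attempts, (5) metabolic update and starvation,
(6) births, (7) carcass decay/removal, (8) prey replenishment.  The run
is driven by a single seeded random stream; agent iteration order is
reshuffled with that stream every day, so identical (config, seed) pairs
give bit-identical trajectories.

Every allosaur ever created leaves one immutable life-history record —
genome, abilities, lifespan, final mass, offspring count, cause of death
— which is the substrate of the analysis layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import pandas as pd

from . import __version__
from .behavior import perceive, prey_flee_speed, resolve_feeding
from .config import SimConfig
from .environment import Calendar, CarcassObject, carcass_daily_update, spawn_carcasses
from .genetics import (
    CLASS_LABELS,
    TRAITS,
    GeneticsParams,
    genome_abilities,
    inherit_genome,
    sample_initial_genome,
)

__all__ = ["AllosaurAgent", "PreyAgent", "WorldState", "RunResult", "step_day", "run"]

_TWO_PI = 2.0 * math.pi


class AllosaurAgent:
    """A living allosaur: position, body-mass ledger, cached abilities."""

    __slots__ = (
        "id", "parent_id", "x", "y", "mass", "genome",
        "detection_range", "tailfat", "dominance",
        "bite_force", "hearing", "binocular_vision",
        "offspring_count", "born_day", "consumed_today",
        "target_kind", "target", "heading",
        "mass_sum", "mass_peak", "days_alive",
    )

    def __init__(self, id, parent_id, x, y, mass, genome, abilities, born_day, heading=0.0):
        self.id = id
        self.parent_id = parent_id
        self.x = x
        self.y = y
        self.mass = mass
        self.genome = genome
        self.detection_range = abilities["detection_range"]
        self.tailfat = abilities["tailfat"]
        self.dominance = abilities["dominance"]
        self.bite_force = abilities["bite_force"]
        self.hearing = abilities["hearing"]
        self.binocular_vision = abilities["binocular_vision"]
        self.offspring_count = 0
        self.born_day = born_day
        self.consumed_today = 0.0
        self.target_kind = None   # None | "carcass" | "prey"
        self.target = None
        self.heading = heading    # radians; persists across wandering days
        self.mass_sum = 0.0       # running lifetime ledger for the record
        self.mass_peak = mass
        self.days_alive = 0

    @property
    def pos(self):
        return (self.x, self.y)


class PreyAgent:
    """A 2,000 kg herbivore; wanders randomly, flees while pursued."""

    __slots__ = ("id", "x", "y", "alive", "heading")

    def __init__(self, id, x, y, heading=0.0):
        self.id = id
        self.x = x
        self.y = y
        self.alive = True
        self.heading = heading

    @property
    def pos(self):
        return (self.x, self.y)


@dataclass
class WorldState:
    config: SimConfig
    rng: object
    genetics: GeneticsParams
    calendar: Calendar = field(default_factory=Calendar)
    day: int = 0
    allosaurs: List[AllosaurAgent] = field(default_factory=list)
    prey: List[PreyAgent] = field(default_factory=list)
    carcasses: List[CarcassObject] = field(default_factory=list)
    records: List[dict] = field(default_factory=list)
    open_agents: Dict[int, AllosaurAgent] = field(default_factory=dict)
    yearly: List[dict] = field(default_factory=list)
    events: List[tuple] = field(default_factory=list)
    next_agent_id: int = 0
    next_prey_id: int = 0
    next_carcass_id: int = 0
    total_produced: int = 0
    total_kills: int = 0
    n_reseeds: int = 0
    total_intake: float = 0.0          # kg eaten by allosaurs, run total
    annual_spawn_counts: List[int] = field(default_factory=list)
    _spawns_this_year: int = 0

    def sauropod_carcass_count(self) -> int:
        return sum(1 for c in self.carcasses if c.origin == "sauropod")


def _close_record(state: WorldState, agent: AllosaurAgent, died_day, cause: str) -> None:
    rec = {
        "id": agent.id,
        "parent_id": agent.parent_id,
        "born_day": agent.born_day,
        "died_day": died_day,
        "cause": cause,
        "final_mass": agent.mass,
        "mean_mass": agent.mass_sum / agent.days_alive if agent.days_alive else agent.mass,
        "peak_mass": agent.mass_peak,
        "offspring": agent.offspring_count,
    }
    genes = agent.genome.genes
    for trait in TRAITS:
        g = genes[trait]
        rec[f"{trait}_class"] = g.expression
        rec[f"{trait}_factor"] = g.factor
        rec[f"{trait}_ability"] = getattr(agent, trait)
    state.records.append(rec)
    state.open_agents.pop(agent.id, None)


def _spawn_allosaur(state: WorldState, parent: Optional[AllosaurAgent]) -> AllosaurAgent:
    cfg = state.config
    rng = state.rng
    if parent is None:
        genome = sample_initial_genome(rng, state.genetics)
        x = cfg.grid_km * rng.random()
        y = cfg.grid_km * rng.random()
        parent_id = None
    else:
        genome = inherit_genome(parent.genome, rng, state.genetics)
        x, y = parent.x, parent.y
        parent_id = parent.id
    agent = AllosaurAgent(
        id=state.next_agent_id,
        parent_id=parent_id,
        x=x, y=y,
        mass=cfg.offspring_mass,
        genome=genome,
        abilities=genome_abilities(genome, state.genetics),
        born_day=state.day,
        heading=_TWO_PI * rng.random(),
    )
    state.next_agent_id += 1
    state.total_produced += 1
    state.allosaurs.append(agent)
    state.open_agents[agent.id] = agent
    return agent


def _init_state(config: SimConfig, seed: Optional[int] = None) -> WorldState:
    import random

    if seed is None:
        seed = config.seed
    rng = random.Random(seed)
    genetics = GeneticsParams(factor_mode=config.factor_mode, p_same=config.p_same)
    state = WorldState(config=config, rng=rng, genetics=genetics)
    # the carcass pool starts at its within-window steady state so that the
    # founding cohort faces the same resource regime as later generations
    for _ in range(config.initial_carcasses):
        mass = config.sauropod_mass_min + (
            config.sauropod_mass_max - config.sauropod_mass_min
        ) * rng.random()
        state.carcasses.append(
            CarcassObject(
                id=state.next_carcass_id,
                pos=(config.grid_km * rng.random(), config.grid_km * rng.random()),
                initial_mass=mass,
                spawn_day=0,
            )
        )
        state.next_carcass_id += 1
    for _ in range(config.init_allosaurs):
        _spawn_allosaur(state, None)
    for _ in range(config.min_prey):
        state.prey.append(
            PreyAgent(
                state.next_prey_id,
                config.grid_km * rng.random(),
                config.grid_km * rng.random(),
                heading=_TWO_PI * rng.random(),
            )
        )
        state.next_prey_id += 1
    return state


def step_day(state: WorldState) -> WorldState:
    """Advance the world by one day through the fixed phase order."""
    cfg = state.config
    rng = state.rng
    size = cfg.grid_km
    half = size / 2.0
    day = state.day
    log = state.events.append if cfg.log_events else None

    # --- phase 1: sauropod carcass spawning --------------------------------
    new_c = spawn_carcasses(
        state.calendar.day_of_year,
        state.sauropod_carcass_count(),
        state.next_carcass_id,
        day,
        rng,
        spawn_prob=cfg.spawn_prob,
        max_concurrent=cfg.max_sauropod_carcasses,
        mass_range=(cfg.sauropod_mass_min, cfg.sauropod_mass_max),
        windows=cfg.spawn_windows,
        size=size,
    )
    for c in new_c:
        state.next_carcass_id += 1
        state.carcasses.append(c)
        state._spawns_this_year += 1
        if log:
            log((day, "spawn", -1, c.id, c.initial_mass))

    # --- phase 2: perception, prey flight, movement ------------------------
    agents = state.allosaurs
    rng.shuffle(agents)
    carcasses = state.carcasses
    prey = state.prey
    pursuit: Dict[int, Tuple[float, float, float]] = {}  # prey id -> (hearing, px, py)

    # under exclusive displacement, a carcass guarded by a higher-dominance
    # resident is not a feeding opportunity: subordinates look elsewhere
    exclusive = cfg.feeding_mode == "exclusive"
    occupancy: Dict[int, float] = {}
    if exclusive:
        for a in agents:
            ax, ay = a.x, a.y
            for c in carcasses:
                if abs(ax - c.pos[0]) < 1e-9 and abs(ay - c.pos[1]) < 1e-9:
                    d = occupancy.get(c.id)
                    if d is None or a.dominance > d:
                        occupancy[c.id] = a.dominance
                    break

    for a in agents:
        ax, ay = a.x, a.y
        # nearest carcass within olfactory range (squared-distance scan)
        best_c = None
        best_d2 = a.detection_range * a.detection_range
        for c in carcasses:
            if c.current_mass <= c.residual_floor:  # spent carcass attracts nobody
                continue
            if exclusive and occupancy.get(c.id, -9.0) > a.dominance:
                continue
            dx = abs(c.pos[0] - ax)
            if dx > half:
                dx = size - dx
            dy = abs(c.pos[1] - ay)
            if dy > half:
                dy = size - dy
            d2 = dx * dx + dy * dy
            if d2 <= best_d2:
                best_d2 = d2
                best_c = c
        if best_c is not None:
            a.target_kind = "carcass"
            a.target = best_c
            continue
        best_p = None
        best_d2 = a.binocular_vision * a.binocular_vision
        for p in prey:
            dx = abs(p.x - ax)
            if dx > half:
                dx = size - dx
            dy = abs(p.y - ay)
            if dy > half:
                dy = size - dy
            d2 = dx * dx + dy * dy
            if d2 <= best_d2:
                best_d2 = d2
                best_p = p
        if best_p is not None:
            a.target_kind = "prey"
            a.target = best_p
            prev = pursuit.get(best_p.id)
            if prev is None or a.hearing > prev[0]:
                pursuit[best_p.id] = (a.hearing, ax, ay)
        else:
            a.target_kind = None
            a.target = None

    # prey move first: pursued prey flee the sharpest-eared pursuer at a
    # slowed speed, the rest wander with a persistent heading
    max_turn = math.radians(cfg.max_turn_deg)
    for p in prey:
        chase = pursuit.get(p.id)
        if chase is None:
            p.heading += max_turn * (2.0 * rng.random() - 1.0)
            theta = p.heading
            step = cfg.prey_speed
        else:
            hearing, px, py = chase
            dx = p.x - px
            dy = p.y - py
            if dx > half:
                dx -= size
            elif dx < -half:
                dx += size
            if dy > half:
                dy -= size
            elif dy < -half:
                dy += size
            dist = math.hypot(dx, dy)
            theta = math.atan2(dy, dx) if dist > 1e-12 else _TWO_PI * rng.random()
            p.heading = theta
            step = prey_flee_speed(hearing, cfg.prey_speed)
        p.x = (p.x + step * math.cos(theta)) % size
        p.y = (p.y + step * math.sin(theta)) % size

    # allosaurs move toward their target's current position (prey have
    # already fled), landing exactly on it when within a day's travel
    max_step = cfg.allosaur_speed
    for a in agents:
        if a.target_kind is None:
            a.heading += max_turn * (2.0 * rng.random() - 1.0)
            a.x = (a.x + max_step * math.cos(a.heading)) % size
            a.y = (a.y + max_step * math.sin(a.heading)) % size
            continue
        t = a.target
        tx, ty = (t.pos[0], t.pos[1]) if a.target_kind == "carcass" else (t.x, t.y)
        dx = tx - a.x
        dy = ty - a.y
        if dx > half:
            dx -= size
        elif dx < -half:
            dx += size
        if dy > half:
            dy -= size
        elif dy < -half:
            dy += size
        dist = math.hypot(dx, dy)
        if dist > 1e-12:
            a.heading = math.atan2(dy, dx)
        if dist <= max_step:
            a.x, a.y = tx % size, ty % size
        else:
            f = max_step / dist
            a.x = (a.x + f * dx) % size
            a.y = (a.y + f * dy) % size

    # --- phase 3: feeding contests -----------------------------------------
    tables: Dict[int, Tuple[CarcassObject, List[AllosaurAgent]]] = {}
    for a in agents:
        if a.target_kind == "carcass":
            c = a.target
            dx = abs(a.x - c.pos[0])
            dy = abs(a.y - c.pos[1])
            if dx < 1e-9 and dy < 1e-9:
                tables.setdefault(c.id, (c, []))[1].append(a)
    for c, attendees in tables.values():
        intakes = resolve_feeding(c, attendees, rng, mode=cfg.feeding_mode)
        for a in attendees:
            kg = intakes[a.id]
            a.consumed_today += kg
            state.total_intake += kg
            if log and kg > 0:
                log((day, "feed", a.id, c.id, kg))

    # --- phase 4: predation attempts ---------------------------------------
    killed_today = False
    for a in agents:
        if a.target_kind != "prey":
            continue
        p = a.target
        if not p.alive:
            continue
        dx = abs(a.x - p.x)
        if dx > half:
            dx = size - dx
        dy = abs(a.y - p.y)
        if dy > half:
            dy = size - dy
        if dx * dx + dy * dy > cfg.capture_radius * cfg.capture_radius:
            continue
        if rng.random() < a.bite_force:
            p.alive = False
            carcass = CarcassObject(
                id=state.next_carcass_id,
                pos=(p.x, p.y),
                initial_mass=cfg.prey_mass,
                origin="prey",
                spawn_day=day,
            )
            state.next_carcass_id += 1
            state.carcasses.append(carcass)
            state.total_kills += 1
            killed_today = True
            if log:
                log((day, "kill", a.id, p.id, cfg.prey_mass))
        elif log:
            log((day, "escape", a.id, p.id, 0.0))
    if killed_today:
        state.prey = [p for p in state.prey if p.alive]

    # --- phase 5: metabolic update and starvation --------------------------
    k_req = cfg.anchor_requirement / cfg.anchor_mass ** cfg.fmr_exponent
    exponent = cfg.fmr_exponent
    floor = cfg.starvation_fraction * cfg.anchor_mass
    pay_first = cfg.feed_order == "pay_first"
    survivors = []
    for a in agents:
        eaten = a.consumed_today
        a.consumed_today = 0.0
        a.days_alive += 1
        a.mass_sum += a.mass  # mass while alive today, before the ledger step
        if a.mass > a.mass_peak:
            a.mass_peak = a.mass
        if pay_first:
            a.mass -= k_req * a.mass ** exponent
            if a.mass < floor:
                _close_record(state, a, day, "starvation")
                if log:
                    log((day, "starve", a.id, -1, a.mass))
                continue
            a.mass += eaten
        else:
            a.mass += eaten - k_req * a.mass ** exponent
            if a.mass < floor:
                _close_record(state, a, day, "starvation")
                if log:
                    log((day, "starve", a.id, -1, a.mass))
                continue
        survivors.append(a)
    state.allosaurs = survivors

    # --- phase 6: births ----------------------------------------------------
    birth_rate = cfg.birth_rate
    cap = cfg.max_allosaurs
    for a in list(state.allosaurs):
        if len(state.allosaurs) >= cap:
            break
        if rng.random() < birth_rate:
            child = _spawn_allosaur(state, a)
            a.offspring_count += 1
            if cfg.reproduction_cost:
                a.mass -= cfg.reproduction_cost
            if log:
                log((day, "birth", a.id, child.id, 0.0))

    # --- phase 7: carcass decay, removal, depletion ------------------------
    kept = []
    for c in state.carcasses:
        out = carcass_daily_update(
            c, 0.0, rng,
            decay_fraction=cfg.decay_fraction,
            removal_prob=cfg.removal_prob,
            decay_model=cfg.decay_model,
        )
        if out is not None:
            kept.append(out)
        elif log:
            kind = "carcass_depleted" if c.current_mass < c.residual_floor else "carcass_removed"
            log((day, kind, -1, c.id, c.current_mass))
    state.carcasses = kept

    # --- phase 8: replenishment --------------------------------------------
    # an empty landscape is recolonized by a fresh founding cohort once
    # carrion is standing again (immigration tracks the resource pulse);
    # during a carcass famine the landscape simply stays empty
    if (
        not state.allosaurs
        and cfg.reseed_on_extinction
        and state.sauropod_carcass_count() >= cfg.reseed_carcass_threshold
    ):
        state.n_reseeds += 1
        for _ in range(cfg.init_allosaurs):
            _spawn_allosaur(state, None)
    while len(state.prey) < cfg.min_prey:
        state.prey.append(
            PreyAgent(state.next_prey_id, size * rng.random(), size * rng.random())
        )
        state.next_prey_id += 1

    # --- calendar / yearly snapshot ----------------------------------------
    if state.calendar.day_of_year == cfg.days_per_year - 1:
        _take_snapshot(state)
        state.annual_spawn_counts.append(state._spawns_this_year)
        state._spawns_this_year = 0
    state.calendar.advance(cfg.days_per_year)
    state.day += 1
    return state


def _take_snapshot(state: WorldState) -> None:
    """Composition of the living population on the last day of the year."""
    row = {"year": state.calendar.year, "n_alive": len(state.allosaurs)}
    for trait in TRAITS:
        counts = dict.fromkeys(CLASS_LABELS, 0)
        total_ability = 0.0
        for a in state.allosaurs:
            counts[a.genome.genes[trait].expression] += 1
            total_ability += getattr(a, trait)
        for cls in CLASS_LABELS:
            row[f"{trait}__{cls}"] = counts[cls]
        row[f"{trait}__mean_ability"] = (
            total_ability / len(state.allosaurs) if state.allosaurs else float("nan")
        )
    state.yearly.append(row)


@dataclass
class RunResult:
    records: List[dict]
    yearly: List[dict]
    events: List[tuple]
    meta: dict

    def records_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def yearly_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.yearly)

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=["day", "event", "agent_id", "target_id", "kg"])


def run(config: Optional[SimConfig] = None, seed: Optional[int] = None) -> RunResult:
    """Execute a full simulation and return all life-history records,
    yearly composition snapshots, the event log, and run metadata.

    Agents still alive at the end are recorded with an open death day
    (cause "end_of_run")."""
    if config is None:
        config = SimConfig()
    config.validate()
    state = _init_state(config, seed)
    n_days = config.years * config.days_per_year
    for _ in range(n_days):
        step_day(state)
    for a in list(state.allosaurs):
        _close_record(state, a, None, "end_of_run")
    state.records.sort(key=lambda r: r["id"])
    meta = {
        "config": config.to_dict(),
        "seed": seed if seed is not None else config.seed,
        "version": __version__,
        "days_simulated": n_days,
        "total_produced": state.total_produced,
        "total_kills": state.total_kills,
        "n_reseeds": state.n_reseeds,
        "n_founder_cohorts": 1 + state.n_reseeds,
        "total_intake_kg": state.total_intake,
        "annual_spawn_counts": list(state.annual_spawn_counts),
    }
    return RunResult(records=state.records, yearly=state.yearly, events=state.events, meta=meta)
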
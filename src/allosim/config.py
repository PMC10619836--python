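"""Run configuration: every model parameter in one flat, overridable record.

Defaults are the reference model's study conditions: 70 km torus, 279-year run,
12 founders capped at 30, 0.02/agent/day asexual birth rate, 20-prey
floor, seasonal sauropod-carcass windows with a 5-concurrent cap, and
the bird-FMR metabolic anchors.  A YAML file may use either flat keys or
module-named sections; CLI ``--set key=value`` overrides take precedence.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Dict, Optional, Sequence, Tuple

import yaml

__all__ = ["SimConfig", "load_config"]


@dataclass
class SimConfig:
    # --- world ---
    grid_km: float = 70.0
    years: int = 279
    days_per_year: int = 365

    # --- allosaur population ---
    init_allosaurs: int = 12
    max_allosaurs: int = 30
    # when the population dies out, a fresh founding cohort of
    # init_allosaurs random-phenotype colonizers immigrates once the
    # sauropod-carcass pool has recovered to reseed_carcass_threshold
    # (immigration tracks the carrion pulse; the landscape stays empty
    # through a famine); the reference run's life-history tables imply several
    # hundred such recolonizations in a full run
    reseed_on_extinction: bool = True
    reseed_carcass_threshold: int = 3
    birth_rate: float = 0.02          # per living agent per day, gated by the cap
    offspring_mass: float = 2000.0    # kg at birth
    reproduction_cost: float = 0.0    # kg deducted from the parent per birth
    allosaur_speed: float = 3.0       # km/day

    # --- metabolism ---
    anchor_mass: float = 2000.0
    anchor_requirement: float = 29.0  # kg meat/day at anchor mass
    fmr_exponent: float = 0.681
    starvation_fraction: float = 0.92
    feed_order: str = "feed_first"    # feed_first | pay_first

    # --- genetics ---
    factor_mode: str = "redraw"       # redraw | copy-when-same-class
    p_same: float = 0.8

    # --- prey ---
    min_prey: int = 20
    prey_mass: float = 2000.0
    prey_speed: float = 3.0           # km/day, unpursued

    # --- behaviour ---
    target_preference: str = "carrion_first"  # carrion_first | nearest_any
    # carcass-site displacement semantics: "shared" = attendees feed in
    # dominance order from the same pool; "exclusive" = the top-dominance
    # attendee holds the site and feeds alone, subordinates are pushed off
    # and must seek an unguarded carcass
    feeding_mode: str = "shared"
    capture_radius: float = 0.1       # km
    # undirected movement is a correlated wander: each day the heading
    # turns by uniform(-max_turn_deg, +max_turn_deg); 0 = ballistic,
    # 180 = memoryless diffusion
    max_turn_deg: float = 15.0

    # --- carcasses ---
    sauropod_mass_min: float = 10000.0
    sauropod_mass_max: float = 25000.0
    max_sauropod_carcasses: int = 5
    initial_carcasses: int = 5        # sauropod carcasses standing at setup
    spawn_prob: float = 0.14          # per day inside windows, under the cap
    spawn_windows: Tuple[Tuple[int, int], ...] = ((0, 91), (182, 274), (320, 365))
    decay_fraction: float = 0.002     # of initial (linear) or current (exponential) mass/day
    decay_model: str = "linear"
    removal_prob: float = 0.02        # random disappearance hazard per day
    residual_fraction: float = 0.2    # removal floor as a fraction of initial mass

    # --- bookkeeping ---
    seed: int = 0
    log_events: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        checks = [
            ("grid_km", self.grid_km > 0),
            ("years", self.years >= 1),
            ("days_per_year", self.days_per_year >= 1),
            ("init_allosaurs", self.init_allosaurs >= 0),
            ("max_allosaurs", self.max_allosaurs >= self.init_allosaurs),
            ("birth_rate", 0.0 <= self.birth_rate <= 1.0),
            ("offspring_mass", self.offspring_mass > 0),
            ("anchor_mass", self.anchor_mass > 0),
            ("anchor_requirement", self.anchor_requirement > 0),
            ("starvation_fraction", 0.0 < self.starvation_fraction < 1.0),
            ("feed_order", self.feed_order in ("feed_first", "pay_first")),
            ("factor_mode", self.factor_mode in ("redraw", "copy-when-same-class")),
            ("p_same", 0.0 < self.p_same <= 1.0),
            ("min_prey", self.min_prey >= 0),
            ("target_preference", self.target_preference in ("carrion_first", "nearest_any")),
            ("feeding_mode", self.feeding_mode in ("exclusive", "shared")),
            ("capture_radius", self.capture_radius > 0),
            ("max_turn_deg", 0.0 <= self.max_turn_deg <= 180.0),
            ("sauropod_mass", 0 < self.sauropod_mass_min <= self.sauropod_mass_max),
            ("max_sauropod_carcasses", self.max_sauropod_carcasses >= 0),
            ("initial_carcasses", 0 <= self.initial_carcasses <= self.max_sauropod_carcasses),
            ("reseed_carcass_threshold",
             1 <= self.reseed_carcass_threshold <= max(self.max_sauropod_carcasses, 1)),
            ("spawn_prob", 0.0 <= self.spawn_prob <= 1.0),
            ("decay_fraction", 0.0 <= self.decay_fraction < 1.0),
            ("decay_model", self.decay_model in ("linear", "exponential")),
            ("removal_prob", 0.0 <= self.removal_prob <= 1.0),
            ("residual_fraction", 0.0 <= self.residual_fraction < 1.0),
        ]
        bad = [name for name, ok in checks if not ok]
        if bad:
            raise ValueError(f"invalid configuration field(s): {', '.join(bad)}")

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> Dict[str, Any]:
        d = dataclasses.asdict(self)
        d["spawn_windows"] = [list(w) for w in self.spawn_windows]
        return d

    @classmethod
    def field_names(cls) -> Tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))

    @classmethod
    def from_dict(cls, data: Dict[str, Any]) -> "SimConfig":
        """Build from a mapping; nested sections are flattened, unknown
        keys are rejected by name."""
        flat: Dict[str, Any] = {}
        known = set(cls.field_names())
        for key, value in data.items():
            if isinstance(value, dict) and key not in known:
                flat.update(value)
            else:
                flat[key] = value
        unknown = sorted(set(flat) - known)
        if unknown:
            raise ValueError(f"unknown configuration field(s): {', '.join(unknown)}")
        if "spawn_windows" in flat:
            flat["spawn_windows"] = tuple(tuple(int(v) for v in w) for w in flat["spawn_windows"])
        return cls(**flat)

    def with_overrides(self, overrides: Sequence[str]) -> "SimConfig":
        """Apply ``key=value`` strings; values are YAML-parsed so numbers
        and booleans come through typed."""
        d = self.to_dict()
        for item in overrides:
            if "=" not in item:
                raise ValueError(f"override must look like key=value: {item!r}")
            key, _, raw = item.partition("=")
            key = key.strip()
            if key not in self.field_names():
                raise ValueError(f"unknown configuration field: {key!r}")
            d[key] = yaml.safe_load(raw)
        return SimConfig.from_dict(d)


def load_config(path: Optional[str] = None, overrides: Sequence[str] = ()) -> SimConfig:
    """Load a YAML config file (pure defaults when ``path`` is None) and
    apply overrides."""
    if path is None:
        cfg = SimConfig()
    else:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("configuration file must contain a mapping")
        cfg = SimConfig.from_dict(data)
    if overrides:
        cfg = cfg.with_overrides(overrides)
    return cfg
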
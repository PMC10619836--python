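"""Mass-dependent energy budget: daily meat requirement, body-mass ledger,
and the starvation rule.

Energy is tracked as body mass in kg of meat equivalent.  The daily
requirement follows the all-bird field-metabolic-rate allometry (mass
exponent 0.681), calibrated so that a 2,000 kg endotherm needs 29 kg of
meat per day.  An agent whose mass falls below 92% of its initialization
mass (1,840 kg by default) dies of starvation; the floor stays fixed even
after the animal grows.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "ANCHOR_MASS",
    "ANCHOR_REQUIREMENT",
    "FMR_EXPONENT",
    "STARVATION_FRACTION",
    "EnergyState",
    "daily_meat_requirement",
    "apply_daily_budget",
    "is_starved",
    "equilibrium_mass",
]

ANCHOR_MASS = 2000.0          # kg, initialization body mass
ANCHOR_REQUIREMENT = 29.0     # kg meat/day at the anchor mass
FMR_EXPONENT = 0.681          # all-bird FMR allometric exponent
STARVATION_FRACTION = 0.92


@dataclass(frozen=True)
class EnergyState:
    mass: float
    birth_mass: float = ANCHOR_MASS
    starvation_floor: float = STARVATION_FRACTION * ANCHOR_MASS

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError("mass must be positive")


def daily_meat_requirement(
    mass: float,
    anchor_mass: float = ANCHOR_MASS,
    anchor_requirement: float = ANCHOR_REQUIREMENT,
    exponent: float = FMR_EXPONENT,
) -> float:
    """kg of meat needed per day by an animal of the given body mass.

    N(M) = 29 * (M / 2000)**0.681; strictly increasing in M.  Accepts a
    scalar or an array of masses.
    """
    import numpy as np

    if np.any(np.asarray(mass) <= 0):
        raise ValueError("mass must be positive")
    return anchor_requirement * (mass / anchor_mass) ** exponent


def apply_daily_budget(state: EnergyState, consumed: float, **kwargs) -> EnergyState:
    """End-of-day ledger: feed first, then pay the requirement.

    mass' = mass + consumed - N(mass).  Mass may exceed the birth mass
    without bound (fat storage); the starvation floor is unchanged.
    """
    if consumed < 0:
        raise ValueError("consumed must be non-negative")
    need = daily_meat_requirement(state.mass, **kwargs)
    return replace(state, mass=state.mass + consumed - need)


def is_starved(state: EnergyState) -> bool:
    """True iff mass has dropped strictly below the starvation floor."""
    return state.mass < state.starvation_floor


def equilibrium_mass(
    daily_intake: float,
    anchor_mass: float = ANCHOR_MASS,
    anchor_requirement: float = ANCHOR_REQUIREMENT,
    exponent: float = FMR_EXPONENT,
) -> float:
    """Body mass at which the requirement equals a sustained daily intake:
    M* = 2000 * (t / 29)**(1/0.681)."""
    if daily_intake <= 0:
        raise ValueError("daily_intake must be positive")
    return anchor_mass * (daily_intake / anchor_requirement) ** (1.0 / exponent)
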
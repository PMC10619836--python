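"""Heritable trait machinery: expression classes, advantage factors, abilities.

Each simulated allosaur carries six independently inherited trait genes.
A gene is an ordered *expression class* (extra_small .. extra_big) plus a
continuous, dimensionless *advantage factor* drawn within that class's
band.  Abilities used by the behavioural rules (detection radii, daily
intake cap, feeding priority, kill probability, prey slow-down) are fixed
linear maps of the factor.

Inheritance is a nearest-neighbour Markov chain over the five classes:
offspring keep the parental class with probability 0.8 and otherwise move
to an adjacent class, so an extra_small lineage needs at least four
generations to produce an extra_big descendant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np

__all__ = [
    "CLASS_LABELS",
    "FACTOR_BOUNDS",
    "TRAITS",
    "SCAVENGER_TRAITS",
    "PREDATOR_TRAITS",
    "TraitGene",
    "Genome",
    "GeneticsParams",
    "DEFAULT_PARAMS",
    "classify_factor",
    "sample_initial_genome",
    "offspring_expression",
    "inherit_genome",
    "ability_value",
    "genome_abilities",
    "transition_matrix",
]

#: Ordered expression classes, rank 0..4.
CLASS_LABELS: Tuple[str, ...] = ("extra_small", "small", "medium", "big", "extra_big")

#: Advantage-factor band per class; half-open [lo, hi) except the top class,
#: which is closed, so every factor in [0.3, 1.7] maps to exactly one class.
FACTOR_BOUNDS: Tuple[Tuple[float, float], ...] = (
    (0.30, 0.65),
    (0.65, 0.90),
    (0.90, 1.10),
    (1.10, 1.35),
    (1.35, 1.70),
)

#: The six heritable traits.  The first three favour scavenging, the last
#: three favour predation.
SCAVENGER_TRAITS: Tuple[str, ...] = ("detection_range", "tailfat", "dominance")
PREDATOR_TRAITS: Tuple[str, ...] = ("bite_force", "hearing", "binocular_vision")
TRAITS: Tuple[str, ...] = SCAVENGER_TRAITS + PREDATOR_TRAITS

#: Probability that an offspring keeps the parental expression class.
P_SAME = 0.8

# Ability = scale * factor for multiplicative traits, factor - 1 for the
# rank-score traits (dominance, hearing).  Units: tailfat kg/day intake cap,
# detection_range km, binocular_vision km, bite_force kill probability.
_LINEAR_SCALES: Dict[str, float] = {
    "tailfat": 38.0,
    "detection_range": 5.0,
    "binocular_vision": 0.5,
    "bite_force": 0.1,
}
_OFFSET_TRAITS = ("dominance", "hearing")


@dataclass(frozen=True)
class GeneticsParams:
    """Versioned trait-parameter table.

    Shipped as data so alternative scalings can be tested without touching
    code.  ``factor_mode`` controls whether the offspring factor is always
    re-drawn within its class band (``"redraw"``) or copied from the parent
    when the class is unchanged (``"copy-when-same-class"``).
    """

    class_bounds: Tuple[Tuple[float, float], ...] = FACTOR_BOUNDS
    linear_scales: Mapping[str, float] = None  # type: ignore[assignment]
    offset_traits: Tuple[str, ...] = _OFFSET_TRAITS
    p_same: float = P_SAME
    factor_mode: str = "redraw"

    def __post_init__(self):
        if self.linear_scales is None:
            object.__setattr__(self, "linear_scales", dict(_LINEAR_SCALES))
        if self.factor_mode not in ("redraw", "copy-when-same-class"):
            raise ValueError(f"unknown factor_mode: {self.factor_mode!r}")


DEFAULT_PARAMS = GeneticsParams()


@dataclass(frozen=True)
class TraitGene:
    trait: str
    expression: str  # one of CLASS_LABELS
    factor: float

    @property
    def rank(self) -> int:
        return CLASS_LABELS.index(self.expression)


@dataclass(frozen=True)
class Genome:
    """Exactly one :class:`TraitGene` per trait."""

    genes: Mapping[str, TraitGene]

    def __post_init__(self):
        if tuple(sorted(self.genes)) != tuple(sorted(TRAITS)):
            raise ValueError("genome must contain exactly one gene per trait")

    def __getitem__(self, trait: str) -> TraitGene:
        return self.genes[trait]


def classify_factor(factor: float, params: GeneticsParams = DEFAULT_PARAMS) -> str:
    """Map an advantage factor to its expression class label."""
    bounds = params.class_bounds
    if not (bounds[0][0] <= factor <= bounds[-1][1]):
        raise ValueError(f"factor {factor} outside [{bounds[0][0]}, {bounds[-1][1]}]")
    for label, (lo, hi) in zip(CLASS_LABELS, bounds):
        if factor < hi:
            return label
    return CLASS_LABELS[-1]


def _draw_factor(rank: int, rng, params: GeneticsParams) -> float:
    lo, hi = params.class_bounds[rank]
    return lo + (hi - lo) * rng.random()


def sample_initial_genome(rng, params: GeneticsParams = DEFAULT_PARAMS) -> Genome:
    """Founder genome: class uniform over the five classes, factor uniform
    within the class band, all six traits independent."""
    genes = {}
    for trait in TRAITS:
        rank = int(rng.random() * 5)
        if rank == 5:  # rng.random() can return values arbitrarily close to 1
            rank = 4
        genes[trait] = TraitGene(trait, CLASS_LABELS[rank], _draw_factor(rank, rng, params))
    return Genome(genes)


def offspring_expression(parent: str, rng, params: GeneticsParams = DEFAULT_PARAMS) -> str:
    """One inheritance step of the expression-class Markov chain.

    Interior classes: keep with 0.8, each neighbour with 0.1.  Edge classes
    keep with 0.8 and move to the single neighbour with 0.2 (the mass that
    would fall outside the scale folds into the one available neighbour).
    Transitions never jump more than one class.
    """
    rank = CLASS_LABELS.index(parent)
    p_same = params.p_same
    u = rng.random()
    if u < p_same:
        return parent
    if rank == 0:
        return CLASS_LABELS[1]
    if rank == len(CLASS_LABELS) - 1:
        return CLASS_LABELS[rank - 1]
    half = (1.0 - p_same) / 2.0
    if u < p_same + half:
        return CLASS_LABELS[rank - 1]
    return CLASS_LABELS[rank + 1]


def inherit_genome(parent: Genome, rng, params: GeneticsParams = DEFAULT_PARAMS) -> Genome:
    """Offspring genome: each gene's class steps through
    :func:`offspring_expression` independently; the factor is re-drawn
    uniformly within the offspring class band (or copied when the class is
    unchanged, under ``factor_mode="copy-when-same-class"``)."""
    genes = {}
    for trait in TRAITS:
        pg = parent.genes[trait]
        expr = offspring_expression(pg.expression, rng, params)
        if params.factor_mode == "copy-when-same-class" and expr == pg.expression:
            factor = pg.factor
        else:
            factor = _draw_factor(CLASS_LABELS.index(expr), rng, params)
        genes[trait] = TraitGene(trait, expr, factor)
    return Genome(genes)


def ability_value(gene: TraitGene, params: GeneticsParams = DEFAULT_PARAMS) -> float:
    """Scale a gene's advantage factor to its behavioural ability.

    tailfat -> 38 kg * f (daily intake / storage cap);
    detection_range -> 5 km * f; binocular_vision -> 0.5 km * f;
    bite_force -> 0.1 * f (kill probability per attempt);
    dominance, hearing -> f - 1 (dimensionless scores).
    """
    if gene.trait in params.linear_scales:
        return params.linear_scales[gene.trait] * gene.factor
    if gene.trait in params.offset_traits:
        return gene.factor - 1.0
    raise ValueError(f"unknown trait: {gene.trait!r}")


def genome_abilities(genome: Genome, params: GeneticsParams = DEFAULT_PARAMS) -> Dict[str, float]:
    return {t: ability_value(genome.genes[t], params) for t in TRAITS}


def transition_matrix(params: GeneticsParams = DEFAULT_PARAMS) -> np.ndarray:
    """5x5 row-stochastic inheritance matrix over expression classes."""
    n = len(CLASS_LABELS)
    p_same = params.p_same
    half = (1.0 - p_same) / 2.0
    mat = np.zeros((n, n))
    for i in range(n):
        mat[i, i] = p_same
        if i == 0:
            mat[i, 1] = 1.0 - p_same
        elif i == n - 1:
            mat[i, i - 1] = 1.0 - p_same
        else:
            mat[i, i - 1] = half
            mat[i, i + 1] = half
    return mat
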
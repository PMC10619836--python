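import math
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from allosim.genetics import (
    CLASS_LABELS,
    FACTOR_BOUNDS,
    TRAITS,
    GeneticsParams,
    TraitGene,
    ability_value,
    classify_factor,
    inherit_genome,
    offspring_expression,
    sample_initial_genome,
    transition_matrix,
)

# Printed ability bands per expression class: the trait scalings must
# reproduce every cell (tailfat kg, carcass detection km, prey-vision km).
PRINTED_SCALED_BANDS = {
    "tailfat": [(11.4, 24.7), (24.7, 34.2), (34.2, 41.8), (41.8, 51.3), (51.3, 64.6)],
    "detection_range": [(1.5, 3.25), (3.25, 4.5), (4.5, 5.5), (5.5, 6.75), (6.75, 8.5)],
    "binocular_vision": [(0.15, 0.325), (0.325, 0.45), (0.45, 0.55), (0.55, 0.675), (0.675, 0.85)],
}


def test_scaled_ability_bands_match_printed_table():
    """38/5/0.5 x the factor bounds reproduce every printed class range."""
    for trait, bands in PRINTED_SCALED_BANDS.items():
        for (f_lo, f_hi), (lo, hi) in zip(FACTOR_BOUNDS, bands):
            assert ability_value(TraitGene(trait, "medium", f_lo)) == pytest.approx(lo, abs=1e-9)
            assert ability_value(TraitGene(trait, "medium", f_hi)) == pytest.approx(hi, abs=1e-9)


@pytest.mark.parametrize(
    "trait, factor, expected",
    [
        ("tailfat", 1.7, 64.6),
        ("detection_range", 0.3, 1.5),
        ("dominance", 0.77, -0.23),
        ("bite_force", 1.0, 0.10),
        ("hearing", 1.5, 0.5),
        ("binocular_vision", 1.0, 0.5),
    ],
)
def test_ability_value_examples(trait, factor, expected):
    assert ability_value(TraitGene(trait, "medium", factor)) == pytest.approx(expected)


def test_unknown_trait_rejected():
    with pytest.raises(ValueError):
        ability_value(TraitGene("wingspan", "medium", 1.0))


def test_initial_genome_structure(rng):
    g = sample_initial_genome(rng)
    assert set(g.genes) == set(TRAITS)
    for trait, gene in g.genes.items():
        assert gene.trait == trait
        assert 0.3 <= gene.factor <= 1.7
        lo, hi = FACTOR_BOUNDS[CLASS_LABELS.index(gene.expression)]
        assert lo <= gene.factor <= hi


def test_initial_class_frequencies_uniform(rng):
    """Founder expression classes are uniform over the five classes."""
    counts = {t: {c: 0 for c in CLASS_LABELS} for t in TRAITS}
    n = 10_000
    for _ in range(n):
        g = sample_initial_genome(rng)
        for t in TRAITS:
            counts[t][g.genes[t].expression] += 1
    for t in TRAITS:
        observed = [counts[t][c] for c in CLASS_LABELS]
        res = stats.chisquare(observed)
        assert res.pvalue > 0.01, f"{t}: {observed}"


def test_interior_class_inheritance_frequencies(rng):
    """A medium parent yields small/medium/big at 0.1/0.8/0.1."""
    n = 100_000
    counts = {c: 0 for c in CLASS_LABELS}
    for _ in range(n):
        counts[offspring_expression("medium", rng)] += 1
    assert counts["extra_small"] == 0 and counts["extra_big"] == 0
    observed = [counts["small"], counts["medium"], counts["big"]]
    res = stats.chisquare(observed, f_exp=[0.1 * n, 0.8 * n, 0.1 * n])
    assert res.pvalue > 0.01


@pytest.mark.parametrize("edge, neighbour", [("extra_small", "small"), ("extra_big", "big")])
def test_edge_class_inheritance(edge, neighbour, rng):
    outcomes = {offspring_expression(edge, rng) for _ in range(5000)}
    assert outcomes == {edge, neighbour}


def test_transition_matrix_is_nearest_neighbour_stochastic():
    mat = transition_matrix()
    assert np.allclose(mat.sum(axis=1), 1.0)
    for i in range(5):
        for j in range(5):
            if abs(i - j) > 1:
                assert mat[i, j] == 0.0
    # irreducible and aperiodic: some power has all entries positive
    assert (np.linalg.matrix_power(mat, 4) > 0).all()


def test_extreme_class_chain_takes_four_generations():
    """extra_small -> extra_big requires at least 4 inheritance steps."""
    mat = transition_matrix()
    for k in range(1, 4):
        assert np.linalg.matrix_power(mat, k)[0, 4] == 0.0
    assert np.linalg.matrix_power(mat, 4)[0, 4] > 0.0


def test_inheritance_is_class_adjacent_and_in_band(rng):
    parent = sample_initial_genome(rng)
    for _ in range(200):
        child = inherit_genome(parent, rng)
        for t in TRAITS:
            pr = parent.genes[t].rank
            cr = child.genes[t].rank
            assert abs(pr - cr) <= 1
            lo, hi = FACTOR_BOUNDS[cr]
            assert lo <= child.genes[t].factor <= hi


def test_all_medium_parent_offspring_classes(rng):
    genes = {t: TraitGene(t, "medium", 1.0) for t in TRAITS}
    from allosim.genetics import Genome

    parent = Genome(genes)
    for _ in range(200):
        child = inherit_genome(parent, rng)
        for t in TRAITS:
            assert child.genes[t].expression in {"small", "medium", "big"}


def test_inheritance_deterministic_under_seed():
    parent = sample_initial_genome(random.Random(7))
    a = inherit_genome(parent, random.Random(99))
    b = inherit_genome(parent, random.Random(99))
    assert a == b


def test_copy_when_same_class_mode(rng):
    params = GeneticsParams(factor_mode="copy-when-same-class")
    parent = sample_initial_genome(rng)
    for _ in range(100):
        child = inherit_genome(parent, rng, params)
        for t in TRAITS:
            if child.genes[t].expression == parent.genes[t].expression:
                assert child.genes[t].factor == parent.genes[t].factor


@settings(max_examples=200, deadline=None)
@given(st.floats(min_value=0.3, max_value=1.7, allow_nan=False))
def test_classify_factor_assigns_containing_class(factor):
    label = classify_factor(factor)
    lo, hi = FACTOR_BOUNDS[CLASS_LABELS.index(label)]
    assert lo <= factor <= hi
    # half-open bands: only the top class owns its upper bound
    if factor < 1.7 and factor == hi:
        assert label == "extra_big"
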
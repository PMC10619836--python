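import numpy as np
import pandas as pd
import pytest

from allosim.analysis import (
    bin_summary,
    composition_timeseries,
    fitness_ratio,
    fitness_table,
    offspring_probability,
    reproductive_success_density,
    successful_mass_mean,
    summary_statistics,
    zero_offspring_fraction,
)
from allosim.genetics import CLASS_LABELS, TRAITS
from allosim.metabolism import daily_meat_requirement


def make_records(rows):
    """Minimal records frame: each row is (offspring, mass, abilities dict)."""
    out = []
    for i, (offspring, mass, abilities) in enumerate(rows):
        rec = {"id": i, "offspring": offspring, "final_mass": mass, "mean_mass": mass}
        for t in TRAITS:
            rec[f"{t}_ability"] = abilities.get(t, 1.0)
        out.append(rec)
    return pd.DataFrame(out)


def test_zero_offspring_fraction_from_printed_bins(reference_offspring_bins):
    """The reference run's population bins give a 58.4% zero-offspring share."""
    df = make_records([(k, 2000.0, {}) for k in reference_offspring_bins])
    frac = zero_offspring_fraction(fitness_table(df))
    assert frac == pytest.approx(13440 / 23025, abs=1e-12)
    assert round(frac, 3) == 0.584


def test_zero_offspring_fraction_edge_cases():
    allz = fitness_table(make_records([(0, 2000.0, {})] * 5))
    assert zero_offspring_fraction(allz) == 1.0
    with pytest.raises(ValueError):
        fitness_table(pd.DataFrame())


def test_offspring_probability_and_ratio():
    # 100 high-tailfat agents, 28 with exactly one offspring;
    # 100 low-tailfat agents, 12 with exactly one offspring
    rows = []
    for i in range(100):
        rows.append((1 if i < 28 else 0, 2000.0, {"tailfat": 40.0}))
    for i in range(100):
        rows.append((1 if i < 12 else 0, 2000.0, {"tailfat": 30.0}))
    table = fitness_table(make_records(rows))
    p_hi, p_lo = offspring_probability(table, "tailfat", 35.0, k=1)
    assert (p_hi, p_lo) == (0.28, 0.12)
    assert fitness_ratio(table, "tailfat", 35.0, k=1) == pytest.approx(2.33, abs=0.005)


def test_empty_stratum_is_flagged():
    table = fitness_table(make_records([(1, 2000.0, {"tailfat": 40.0})] * 5))
    p_hi, p_lo = offspring_probability(table, "tailfat", 10.0, k=1)
    assert p_lo is None
    assert fitness_ratio(table, "tailfat", 10.0) is None
    with pytest.raises(ValueError):
        offspring_probability(table, "wingspan", 1.0)


def test_identical_strata_give_unit_ratio():
    rows = [((i // 2) % 2, 2000.0, {"tailfat": 30.0 + 10 * (i % 2)}) for i in range(400)]
    table = fitness_table(make_records(rows))
    # outcome alternates independently of the stratum assignment
    assert fitness_ratio(table, "tailfat", 35.0, k=1) == pytest.approx(1.0)


def test_permuted_abilities_null_ratio(small_table, rng):
    """Shuffling the ability column severs the trait-fitness link, so the
    stratified ratio calibrates to ~1."""
    ratios = []
    for _ in range(20):
        shuffled = small_table.copy()
        vals = shuffled["tailfat_ability"].to_numpy().copy()
        rng.shuffle(vals)
        shuffled["tailfat_ability"] = vals
        r = fitness_ratio(shuffled, "tailfat", 35.0, k=1)
        if r is not None:
            ratios.append(r)
    assert np.mean(ratios) == pytest.approx(1.0, abs=0.25)


def test_bin_summary_hand_computed():
    rows = [
        (0, 1900.0, {"tailfat": 30.0, "dominance": 0.1}),
        (0, 2100.0, {"tailfat": 50.0, "dominance": -0.1}),
        (2, 2400.0, {"tailfat": 44.0, "dominance": 0.2}),
    ]
    out = bin_summary(fitness_table(make_records(rows)))
    assert list(out["offspring"]) == [0, 2]
    assert list(out["n"]) == [2, 1]
    b0 = out[out["offspring"] == 0].iloc[0]
    assert b0["tailfat_ability"] == pytest.approx(40.0)
    assert b0["dominance_ability"] == pytest.approx(0.0)
    assert b0["mass"] == pytest.approx(2000.0)
    assert b0["energy_budget"] == pytest.approx(
        (daily_meat_requirement(1900.0) + daily_meat_requirement(2100.0)) / 2
    )


def test_bin_summary_single_bin_degenerate():
    out = bin_summary(fitness_table(make_records([(3, 2500.0, {})] * 4)))
    assert len(out) == 1 and out.iloc[0]["n"] == 4


def test_successful_mass_mean_toy():
    rows = [(0, 1800.0, {}), (1, 2000.0, {"tailfat": 40.0}), (2, 3000.0, {"tailfat": 44.0})]
    mass, tailfat = successful_mass_mean(fitness_table(make_records(rows)))
    assert mass == pytest.approx(2500.0)
    assert tailfat == pytest.approx(42.0)
    with pytest.raises(ValueError):
        successful_mass_mean(fitness_table(make_records([(0, 2000.0, {})])))


def test_density_integrates_to_one(small_table):
    grid, dens = reproductive_success_density(small_table)
    assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)


def test_density_point_mass_peaks_at_value():
    table = fitness_table(make_records([(2, 2000.0, {})] * 10))
    grid, dens = reproductive_success_density(table)
    assert grid[int(np.argmax(dens))] == pytest.approx(2.0, abs=0.05)
    dx = grid[1] - grid[0]
    assert dens.sum() * dx == pytest.approx(1.0)


def test_composition_timeseries_frequencies(small_run):
    comp = composition_timeseries(small_run.yearly_frame())
    assert set(comp["trait"].unique()) == set(TRAITS)
    assert set(comp["expression"].unique()) == set(CLASS_LABELS)
    sums = comp.dropna(subset=["frequency"]).groupby(["year", "trait"])["frequency"].sum()
    assert np.allclose(sums.to_numpy(), 1.0)


def test_summary_statistics_keys(small_table):
    s = summary_statistics(small_table)
    for key in (
        "total_agents", "zero_offspring_fraction", "tailfat_fitness_ratio",
        "bite_force_fitness_ratio", "successful_mean_mass", "successful_mean_tailfat",
    ):
        assert key in s
    assert 0.0 <= s["zero_offspring_fraction"] <= 1.0
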
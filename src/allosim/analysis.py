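"""Selection statistics over the life-history records.

The fitness measure is lifetime reproductive success (total offspring).
This module stratifies agents by trait ability, compares reproduction
probabilities across strata, tabulates per-offspring-bin trait means,
estimates the energetically favoured body mass of successful agents, and
summarizes yearly phenotype composition.
"""

from __future__ import annotations

from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .genetics import CLASS_LABELS, TRAITS
from .metabolism import daily_meat_requirement

__all__ = [
    "fitness_table",
    "zero_offspring_fraction",
    "offspring_probability",
    "fitness_ratio",
    "bin_summary",
    "successful_mass_mean",
    "reproductive_success_density",
    "composition_timeseries",
    "summary_statistics",
]

_ABILITY_COLS = [f"{t}_ability" for t in TRAITS]


def fitness_table(records: pd.DataFrame) -> pd.DataFrame:
    """Join the derived analysis columns onto raw agent records.

    Adds a ``mass`` column (lifetime mean body mass where recorded),
    ``energy_budget`` (the daily meat requirement at that mass) and an
    ``offspring_bin`` equal to the lifetime offspring count.  One row
    per agent ever created.
    """
    required = {"offspring", "final_mass"} | set(_ABILITY_COLS)
    missing = sorted(required - set(records.columns))
    if missing:
        raise ValueError(f"records missing required column(s): {', '.join(missing)}")
    if records.empty:
        raise ValueError("records table is empty")
    out = records.copy()
    # "mass" is the lifetime mean body mass when the engine recorded one
    # (the quantity the per-bin summaries describe); final-at-death mass
    # sits at the starvation floor for nearly every agent and is kept as
    # its own column
    out["mass"] = out["mean_mass"] if "mean_mass" in out.columns else out["final_mass"]
    out["energy_budget"] = daily_meat_requirement(out["mass"].to_numpy())
    out["offspring_bin"] = out["offspring"].astype(int)
    return out


def zero_offspring_fraction(table: pd.DataFrame) -> float:
    """Share of all agents that died without reproducing."""
    if table.empty:
        raise ValueError("table is empty")
    return float((table["offspring"] == 0).mean())


def offspring_probability(
    table: pd.DataFrame,
    trait: str,
    threshold: float,
    k: int = 1,
    mode: str = "exactly",
) -> Tuple[Optional[float], Optional[float]]:
    """Empirical reproduction probability by ability stratum.

    Returns (P(above), P(below)) where "above" means ability strictly
    greater than ``threshold``.  ``mode="exactly"`` counts agents with
    exactly ``k`` offspring (the headline 0.28-vs-0.12 comparison is of
    this form); ``mode="at_least"`` counts ``k`` or more.  An empty
    stratum yields None for its probability.
    """
    if trait not in TRAITS:
        raise ValueError(f"unknown trait: {trait!r}")
    if mode not in ("exactly", "at_least"):
        raise ValueError(f"unknown mode: {mode!r}")
    ability = table[f"{trait}_ability"]
    high = table.loc[ability > threshold, "offspring"]
    low = table.loc[ability <= threshold, "offspring"]

    def _prob(col):
        if len(col) == 0:
            return None
        hits = (col == k) if mode == "exactly" else (col >= k)
        return float(hits.mean())

    return _prob(high), _prob(low)


def fitness_ratio(
    table: pd.DataFrame,
    trait: str,
    threshold: float,
    k: int = 1,
    mode: str = "exactly",
) -> Optional[float]:
    """Ratio of the high-stratum to the low-stratum reproduction
    probability; None when either stratum is empty or the denominator is
    zero."""
    p_high, p_low = offspring_probability(table, trait, threshold, k, mode)
    if p_high is None or p_low is None or p_low == 0.0:
        return None
    return p_high / p_low


def bin_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean attribute expression grouped by lifetime reproductive success.

    One row per observed offspring count, with the bin size and the mean
    of each trait ability, final mass, and daily energy budget."""
    if table.empty:
        raise ValueError("table is empty")
    cols = _ABILITY_COLS + ["mass", "energy_budget"]
    grouped = table.groupby("offspring_bin")
    out = grouped[cols].mean()
    out.insert(0, "n", grouped.size())
    out.index.name = "offspring"
    return out.reset_index()


def successful_mass_mean(table: pd.DataFrame) -> Tuple[float, float]:
    """(mean body mass, mean tailfat ability) over agents that produced
    at least one offspring.  Body mass is the lifetime mean when
    available (see :func:`fitness_table`)."""
    winners = table.loc[table["offspring"] >= 1]
    if winners.empty:
        raise ValueError("no reproductively successful agents in table")
    col = "mass" if "mass" in table.columns else "final_mass"
    return float(winners[col].mean()), float(winners["tailfat_ability"].mean())


def reproductive_success_density(
    table: pd.DataFrame,
    mask: Optional[pd.Series] = None,
    grid: Optional[np.ndarray] = None,
    bandwidth=None,
):
    """Gaussian kernel density of the offspring-count distribution.

    ``mask`` selects a stratum (default: all agents).  Bandwidth follows
    Silverman's rule unless overridden.  Returns ``(grid, density)``;
    the density integrates to 1 over the real line.  A degenerate
    stratum (zero variance) returns a unit point mass on the grid cell
    nearest the common value.
    """
    counts = table["offspring"] if mask is None else table.loc[mask, "offspring"]
    counts = counts.to_numpy(dtype=float)
    if counts.size == 0:
        raise ValueError("stratum is empty")
    if grid is None:
        hi = counts.max() + 3.0
        grid = np.linspace(-3.0, hi, 512)
    if np.ptp(counts) == 0.0:
        density = np.zeros_like(grid)
        idx = int(np.argmin(np.abs(grid - counts[0])))
        dx = grid[1] - grid[0]
        density[idx] = 1.0 / dx
        return grid, density
    kde = stats.gaussian_kde(counts, bw_method=bandwidth)
    return grid, kde(grid)


def composition_timeseries(yearly: pd.DataFrame) -> pd.DataFrame:
    """Tidy per-year, per-trait expression-class frequencies.

    Input is the engine's yearly snapshot table (class counts among
    agents alive on the year's final day).  Output columns: year, trait,
    expression class, count, frequency; frequencies sum to 1 within each
    trait-year that had any survivors."""
    if yearly.empty:
        raise ValueError("no yearly snapshots")
    rows = []
    for _, snap in yearly.iterrows():
        n = snap["n_alive"]
        for trait in TRAITS:
            for cls in CLASS_LABELS:
                count = snap[f"{trait}__{cls}"]
                rows.append(
                    {
                        "year": int(snap["year"]),
                        "trait": trait,
                        "expression": cls,
                        "count": int(count),
                        "frequency": count / n if n else float("nan"),
                    }
                )
    return pd.DataFrame(rows)


def summary_statistics(
    table: pd.DataFrame,
    tailfat_threshold: float = 35.0,
    bite_force_threshold: float = 0.11,
    k: int = 1,
) -> Dict[str, float]:
    """Headline selection statistics for one run, as a flat mapping.

    The tail-fat stratification follows the >35 kg intake-cap split; the
    "high bite force" stratum is ability > 0.11 (factor above the
    big-class threshold)."""
    p_tf_hi, p_tf_lo = offspring_probability(table, "tailfat", tailfat_threshold, k)
    p_bf_hi, p_bf_lo = offspring_probability(table, "bite_force", bite_force_threshold, k)
    out = {
        "total_agents": int(len(table)),
        "zero_offspring_fraction": zero_offspring_fraction(table),
        "max_offspring": int(table["offspring"].max()),
        "tailfat_p_high": p_tf_hi,
        "tailfat_p_low": p_tf_lo,
        "tailfat_fitness_ratio": fitness_ratio(table, "tailfat", tailfat_threshold, k),
        "bite_force_p_high": p_bf_hi,
        "bite_force_p_low": p_bf_lo,
        "bite_force_fitness_ratio": fitness_ratio(table, "bite_force", bite_force_threshold, k),
    }
    try:
        mass, tailfat = successful_mass_mean(table)
        out["successful_mean_mass"] = mass
        out["successful_mean_tailfat"] = tailfat
    except ValueError:
        out["successful_mean_mass"] = None
        out["successful_mean_tailfat"] = None
    return out
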
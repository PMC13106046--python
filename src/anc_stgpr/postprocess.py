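"""Draw-level adjustments: raking, ANC1 rescaling, aggregation, correlation.

Every operation here works cell-by-cell on aligned draw cubes so that the
logical constraints hold in every draw (not merely in the mean) and the
final intervals reflect the full dependence structure.  Aggregation is
always performed before summarisation: the livebirth-weighted mean of
country draws is itself a draw, whereas a weighted mean of country
intervals would not be an interval of anything.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cubes import DrawCube
from .hierarchy import GLOBAL_ID, LocationHierarchy


def rake_content_proportion(content: DrawCube,
                            items: list[DrawCube]) -> DrawCube:
    """Cap the content proportion at the minimum of its five components.

    Applied per (location, year, draw) before any aggregation, so the
    composite can never exceed any single item anywhere in draw space.
    Idempotent: raking an already-raked cube changes nothing.
    """
    for item in items:
        content.require_aligned(item)
    floor = np.minimum.reduce([item.values for item in items])
    return content.copy_with(np.minimum(content.values, floor))


def scale_by_anc1(cube: DrawCube, anc1: DrawCube) -> DrawCube:
    """Rescale an attendee-conditional cube to the all-women scale.

    Elementwise product with the ANC1 coverage draws; refuses cubes that
    are already among all women with a livebirth.
    """
    if cube.denominator != "anc_attendees":
        raise ValueError(
            f"cube {cube.indicator!r} is already on the all-women scale")
    cube.require_aligned(anc1)
    return cube.copy_with(cube.values * anc1.values,
                          denominator="all_livebirths")


def aggregate_regions(cube: DrawCube,
                      hierarchy: LocationHierarchy) -> DrawCube:
    """Append livebirth-weighted region and global aggregates to a cube.

    Each aggregate draw is the weighted mean of its member countries'
    draws for that year, with weights the annual livebirth counts; a
    missing weight raises an error naming the country-year.
    """
    countries = [c for c in cube.locations if c in set(hierarchy.countries)]
    if not countries:
        raise ValueError("cube contains no countries from the hierarchy")
    w = hierarchy.weight_matrix(countries, cube.years)   # (C, Y)
    idx = {c: cube.locations.index(c) for c in countries}
    vals = np.stack([cube.values[idx[c]] for c in countries])  # (C, Y, D)

    def weighted(members: list[str]) -> np.ndarray:
        rows = [countries.index(m) for m in members]
        ww = w[rows][:, :, None]
        return (ww * vals[rows]).sum(axis=0) / ww.sum(axis=0)

    agg_locs, agg_vals = [], []
    for region in hierarchy.regions:
        members = [m for m in hierarchy.members(region) if m in idx]
        if members:
            agg_locs.append(region)
            agg_vals.append(weighted(members))
    agg_locs.append(GLOBAL_ID)
    agg_vals.append(weighted(countries))
    values = np.concatenate([cube.values, np.stack(agg_vals)], axis=0)
    return DrawCube(cube.indicator, list(cube.locations) + agg_locs,
                    cube.years, values, cube.denominator)


def summarize(cube: DrawCube) -> pd.DataFrame:
    """Mean and 2.5/97.5 percentile summary table (one row per cell)."""
    if cube.n_draws < 2:
        raise ValueError("need at least 2 draws to summarise")
    return cube.summarize()


def correlate_with_outcomes(cubes: dict[str, DrawCube], outcomes: pd.DataFrame,
                            year: int, method: str = "spearman",
                            level: str = "draw") -> pd.DataFrame:
    """Cross-country correlation of each indicator with each outcome.

    For ``level="draw"`` the correlation is computed within every draw and
    summarised by its mean and 2.5/97.5 percentiles, so the interval
    reflects estimation uncertainty; ``level="point"`` correlates the
    posterior means instead (degenerate interval).  Spearman by default.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    sub = outcomes.loc[outcomes["year"] == int(year)]
    outcome_cols = [c for c in outcomes.columns if c not in ("location", "year")]
    rows = []
    for name, cube in sorted(cubes.items()):
        countries = [c for c in cube.locations if c in set(sub["location"])]
        if len(countries) < 3:
            raise ValueError(
                f"correlation undefined with {len(countries)} countries")
        j = int(np.searchsorted(cube.years, int(year)))
        if j >= len(cube.years) or cube.years[j] != int(year):
            raise ValueError(f"year {year} not in cube {name!r}")
        draws = np.stack([cube.loc(c)[j] for c in countries])   # (C, D)
        if level == "point":
            draws = draws.mean(axis=1, keepdims=True)
        elif level != "draw":
            raise ValueError("level must be 'draw' or 'point'")
        x = rankdata(draws, axis=0) if method == "spearman" else draws
        out_by_loc = sub.set_index("location")
        for outcome in outcome_cols:
            o = out_by_loc.loc[countries, outcome].to_numpy(dtype=float)
            yv = rankdata(o) if method == "spearman" else o
            xc = x - x.mean(axis=0)
            yc = yv - yv.mean()
            denom = np.sqrt((xc ** 2).sum(axis=0) * (yc ** 2).sum())
            r = (xc * yc[:, None]).sum(axis=0) / denom
            rows.append((name, outcome, float(r.mean()),
                         float(np.quantile(r, 0.025)),
                         float(np.quantile(r, 0.975))))
    return pd.DataFrame(rows, columns=["indicator", "outcome", "mean",
                                       "lower", "upper"])
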
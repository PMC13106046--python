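"""DrawCube: the (location, year, draw) array that carries uncertainty.

Every adjustment after the Gaussian-process stage — raking the composite
against its components, rescaling attendee-conditional estimates by ANC1
coverage, aggregating countries into regions — operates on this object at
the draw level, so correlations between quantities propagate into the final
intervals instead of being discarded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class DrawCube:
    indicator: str
    locations: list[str]
    years: np.ndarray
    values: np.ndarray          # shape (n_locations, n_years, n_draws)
    denominator: str = "all_livebirths"
    _loc_index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.locations = list(self.locations)
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[:2] != (len(self.locations), len(self.years)):
            raise ValueError("values shape does not match locations x years")
        if self.values.ndim != 3:
            raise ValueError("values must be 3-d (location, year, draw)")
        self._loc_index = {c: i for i, c in enumerate(self.locations)}

    @property
    def n_draws(self) -> int:
        return self.values.shape[2]

    def loc(self, location: str) -> np.ndarray:
        """(n_years, n_draws) slice for one location."""
        return self.values[self._loc_index[location]]

    def aligned_with(self, other: "DrawCube") -> bool:
        return (self.locations == other.locations
                and np.array_equal(self.years, other.years)
                and self.n_draws == other.n_draws)

    def require_aligned(self, other: "DrawCube") -> None:
        if not self.aligned_with(other):
            raise ValueError(
                f"cubes {self.indicator!r} and {other.indicator!r} are not aligned "
                "(locations, years and draw count must match)")

    def copy_with(self, values: np.ndarray, indicator: str | None = None,
                  denominator: str | None = None) -> "DrawCube":
        return DrawCube(indicator or self.indicator, self.locations, self.years,
                        values, denominator or self.denominator)

    # --- summaries ------------------------------------------------------
    def summarize(self) -> pd.DataFrame:
        """Mean and 2.5/97.5 percentile interval per (location, year).

        Percentiles use the linear-interpolation quantile definition
        (numpy's default), so with 1000 draws the bounds interpolate
        between order statistics 25/26 and 975/976.
        """
        mean = self.values.mean(axis=2)
        lower = np.quantile(self.values, 0.025, axis=2)
        upper = np.quantile(self.values, 0.975, axis=2)
        rows = []
        for i, c in enumerate(self.locations):
            for j, y in enumerate(self.years):
                rows.append((c, int(y), self.indicator,
                             mean[i, j], lower[i, j], upper[i, j]))
        return pd.DataFrame(rows, columns=["location", "year", "indicator",
                                           "mean", "lower", "upper"])

    # --- persistence (CSV per location + JSON manifest) -----------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "indicator": self.indicator,
            "denominator": self.denominator,
            "locations": self.locations,
            "years": [int(y) for y in self.years],
            "n_draws": int(self.n_draws),
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
        for i, c in enumerate(self.locations):
            df = pd.DataFrame(self.values[i],
                              columns=[f"draw_{d}" for d in range(self.n_draws)])
            df.insert(0, "year", self.years)
            df.to_csv(directory / f"{c}.csv", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "DrawCube":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        values = np.empty((len(manifest["locations"]), len(manifest["years"]),
                           manifest["n_draws"]))
        for i, c in enumerate(manifest["locations"]):
            df = pd.read_csv(directory / f"{c}.csv")
            values[i] = df.drop(columns="year").to_numpy()
        return cls(manifest["indicator"], manifest["locations"],
                   np.array(manifest["years"]), values, manifest["denominator"])
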
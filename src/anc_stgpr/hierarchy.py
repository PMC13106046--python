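"""Location hierarchy (country -> region -> global) with livebirth weights."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GLOBAL_ID = "global"


@dataclass
class LocationHierarchy:
    """A three-level location tree plus annual livebirth counts per country.

    Parameters
    ----------
    nodes : DataFrame with columns (location_id, parent_id, level), where
        level is one of "global", "region", "country".  Exactly one global
        root; every country must have a region parent.
    livebirths : DataFrame with columns (location_id, year, livebirths);
        counts must be nonnegative.
    """

    nodes: pd.DataFrame
    livebirths: pd.DataFrame
    _weights: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        required = {"location_id", "parent_id", "level"}
        if not required.issubset(self.nodes.columns):
            raise ValueError(f"nodes needs columns {sorted(required)}")
        roots = self.nodes[self.nodes["level"] == "global"]
        if len(roots) != 1:
            raise ValueError("hierarchy must have exactly one global root")
        region_ids = set(self.nodes.loc[self.nodes["level"] == "region", "location_id"])
        for _, row in self.nodes[self.nodes["level"] == "country"].iterrows():
            if row["parent_id"] not in region_ids:
                raise ValueError(f"country {row['location_id']} lacks a region parent")
        if (self.livebirths["livebirths"] < 0).any():
            raise ValueError("livebirth counts must be nonnegative")
        lb = self.livebirths.set_index(["location_id", "year"])["livebirths"]
        self._weights = lb.to_dict()

    @property
    def countries(self) -> list[str]:
        return sorted(self.nodes.loc[self.nodes["level"] == "country", "location_id"])

    @property
    def regions(self) -> list[str]:
        return sorted(self.nodes.loc[self.nodes["level"] == "region", "location_id"])

    def members(self, parent: str) -> list[str]:
        """Direct children of a region (countries) or the root (regions)."""
        return sorted(self.nodes.loc[self.nodes["parent_id"] == parent, "location_id"])

    def region_of(self, country: str) -> str:
        row = self.nodes.loc[self.nodes["location_id"] == country]
        if row.empty:
            raise KeyError(country)
        return row["parent_id"].iloc[0]

    def weight(self, country: str, year: int) -> float:
        try:
            return float(self._weights[(country, int(year))])
        except KeyError:
            raise KeyError(f"no livebirth weight for {country} in {year}") from None

    def weight_matrix(self, countries: list[str], years: np.ndarray) -> np.ndarray:
        return np.array([[self.weight(c, y) for y in years] for c in countries])

    # --- I/O ------------------------------------------------------------
    def to_csv(self, nodes_path: str | Path, livebirths_path: str | Path) -> None:
        self.nodes.to_csv(nodes_path, index=False)
        self.livebirths.to_csv(livebirths_path, index=False)

    @classmethod
    def from_csv(cls, nodes_path: str | Path, livebirths_path: str | Path
                 ) -> "LocationHierarchy":
        return cls(pd.read_csv(nodes_path), pd.read_csv(livebirths_path))

    @classmethod
    def from_config(cls, sim_config, rng: np.random.Generator | None = None
                    ) -> "LocationHierarchy":
        """Build the simulated study's hierarchy with lognormal livebirth counts."""
        rows = [{"location_id": GLOBAL_ID, "parent_id": "", "level": "global"}]
        for r in sim_config.regions:
            rows.append({"location_id": r, "parent_id": GLOBAL_ID, "level": "region"})
        for c in sim_config.countries:
            rows.append({"location_id": c, "parent_id": sim_config.region_of(c),
                         "level": "country"})
        years = sim_config.years
        rng = rng or np.random.default_rng(sim_config.seed)
        lb_rows = []
        for c in sim_config.countries:
            base = float(np.exp(rng.normal(12.0, 1.0)))   # ~160k births/year
            growth = rng.normal(0.005, 0.01)
            for i, y in enumerate(years):
                lb_rows.append({"location_id": c, "year": int(y),
                                "livebirths": base * float(np.exp(growth * i))})
        return cls(pd.DataFrame(rows), pd.DataFrame(lb_rows))
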
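"""Configuration objects: simulation settings and pipeline settings.

Both are plain dataclasses with explicit validation and YAML round-trip
support; unknown keys are rejected so that a typo in a config file fails
loudly instead of silently falling back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .indicators import INDICATORS


class ConfigError(ValueError):
    """A configuration document failed validation."""


@dataclass
class SimConfig:
    """Settings for the synthetic study generator.

    The defaults describe a DHS/MICS-like multi-country panel: a handful of
    surveys per country over the period, a few thousand sampled births per
    survey, design effects between 1.2 and 3, and occasional surveys that
    omit the weight or iron question entirely.
    """

    n_regions: int = 2
    countries_per_region: int = 3
    year_range: tuple[int, int] = (1995, 2023)
    indicators: tuple[str, ...] = tuple(INDICATORS)
    seed: int = 0
    survey_rate: float = 5.0            # expected surveys per country (Poisson)
    mean_sample_size: float = 3000.0    # expected births per survey (Poisson)
    design_effect_range: tuple[float, float] = (1.2, 3.0)
    # probability a survey omits the weight item, the iron item, or one other
    # clinic item (73/643, 61/643 and 7/643 of real sources respectively)
    missingness_probs: tuple[float, float, float] = (0.11, 0.09, 0.01)
    covariate_effects: tuple[float, float, float] = (0.8, 0.3, -0.2)
    # residual country heterogeneity AFTER conditioning on the three
    # covariates, which absorb most systematic cross-country variation
    country_sd: float = 0.25            # logit-scale country intercept sd
    residual_sd: float = 0.1            # logit-scale survey-level bias sd
    gp_amplitude: float = 0.25          # logit-scale smooth temporal deviation
    gp_timescale: float = 10.0          # years
    compliance_sd: float = 0.7          # per-woman shared item factor sd (logit)
    item_intercepts: dict = field(default_factory=lambda: {
        "iron_supplementation": 0.4,
        "weight_measured": 1.1,
        "bp_measured": 1.4,
        "blood_sample": 0.6,
        "urine_sample": 0.6,
    })
    anc1_intercept: float = 1.4
    early_intercept: float = 0.0
    visits_log_mean: float = 1.1        # log(mu - 1) intercept for attendee visits
    visits_dispersion: float = 4.0      # negative-binomial size parameter
    iron_nonattendee_gap: float = 2.0   # logit penalty for iron without ANC
    anc1_draw_sd: float = 0.1           # logit-scale sd of the ANC1 input draws
    outcome_noise_sd: float = 0.3       # log-scale outcome noise
    recall_window_months: int = 60      # births asked about per survey

    def __post_init__(self) -> None:
        self.year_range = tuple(int(y) for y in self.year_range)
        self.indicators = tuple(self.indicators)
        self.design_effect_range = tuple(float(x) for x in self.design_effect_range)
        self.missingness_probs = tuple(float(p) for p in self.missingness_probs)
        self.covariate_effects = tuple(float(b) for b in self.covariate_effects)
        self.validate()

    def validate(self) -> None:
        if self.n_regions < 1 or self.countries_per_region < 1:
            raise ConfigError("need at least one region and one country per region")
        lo, hi = self.year_range
        if not lo < hi:
            raise ConfigError("year_range start must precede end")
        for name in self.indicators:
            if name not in INDICATORS:
                raise ConfigError(f"unknown indicator {name!r}")
        for p in self.missingness_probs:
            if not 0.0 <= p <= 1.0:
                raise ConfigError("missingness probabilities must lie in [0, 1]")
        dlo, dhi = self.design_effect_range
        if not (dlo >= 1.0 and dhi >= dlo):
            raise ConfigError("design_effect_range must satisfy 1 <= lo <= hi")
        for attr in ("country_sd", "residual_sd", "gp_amplitude", "compliance_sd",
                     "anc1_draw_sd", "outcome_noise_sd"):
            if getattr(self, attr) < 0:
                raise ConfigError(f"{attr} must be nonnegative")
        for attr in ("gp_timescale", "survey_rate", "mean_sample_size",
                     "visits_dispersion"):
            if getattr(self, attr) <= 0:
                raise ConfigError(f"{attr} must be positive")

    @property
    def years(self):
        import numpy as np
        return np.arange(self.year_range[0], self.year_range[1] + 1)

    @property
    def countries(self) -> list[str]:
        return [f"C{r + 1:02d}{c + 1:02d}"
                for r in range(self.n_regions)
                for c in range(self.countries_per_region)]

    @property
    def regions(self) -> list[str]:
        return [f"R{r + 1}" for r in range(self.n_regions)]

    def region_of(self, country: str) -> str:
        return f"R{int(country[1:3])}"

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["year_range"] = list(self.year_range)
        d["indicators"] = list(self.indicators)
        d["design_effect_range"] = list(self.design_effect_range)
        d["missingness_probs"] = list(self.missingness_probs)
        d["covariate_effects"] = list(self.covariate_effects)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        return from_mapping(cls, yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class StgprConfig:
    """Hyperparameters of the three-stage estimator, all on the model scale."""

    lambda_time: float = 10.0     # tricube temporal bandwidth (years)
    zeta_space: float = 0.3       # same-region borrowing weight
    gpr_timescale: float = 10.0   # Matern-3/2 length scale rho (years)
    default_amplitude: float = 0.3  # eta fallback when too few residuals
    amplitude_floor: float = 0.01
    stage2_degree: int = 0        # weighted-mean residual smoothing

    def validate(self) -> None:
        if self.lambda_time <= 0:
            raise ConfigError("lambda_time must be positive")
        if not 0.0 <= self.zeta_space <= 1.0:
            raise ConfigError("zeta_space must lie in [0, 1]")
        if self.gpr_timescale <= 0 or self.default_amplitude <= 0:
            raise ConfigError("GPR hyperparameters must be positive")
        if self.stage2_degree != 0:
            raise ConfigError("only degree-0 residual smoothing is implemented")


@dataclass
class PipelineConfig:
    """Validated settings for an end-to-end run."""

    output_dir: str = "anc_stgpr_output"
    seed: int = 0
    n_draws: int = 1000
    indicators: tuple[str, ...] = tuple(INDICATORS)
    sim: SimConfig = field(default_factory=SimConfig)
    stgpr: StgprConfig = field(default_factory=StgprConfig)
    crosswalk_trim_fraction: float = 0.1
    correlation_year: int | None = None   # defaults to last panel year
    write_microdata: bool = False

    def __post_init__(self) -> None:
        self.indicators = tuple(self.indicators)
        self.validate()

    def validate(self) -> None:
        if self.n_draws < 2:
            raise ConfigError("n_draws must be at least 2")
        for name in self.indicators:
            if name not in INDICATORS:
                raise ConfigError(f"unknown indicator {name!r}")
        if not 0.0 <= self.crosswalk_trim_fraction < 0.5:
            raise ConfigError("crosswalk_trim_fraction must lie in [0, 0.5)")
        self.stgpr.validate()

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["indicators"] = list(self.indicators)
        d["sim"]["year_range"] = list(self.sim.year_range)
        d["sim"]["indicators"] = list(self.sim.indicators)
        d["sim"]["design_effect_range"] = list(self.sim.design_effect_range)
        d["sim"]["missingness_probs"] = list(self.sim.missingness_probs)
        d["sim"]["covariate_effects"] = list(self.sim.covariate_effects)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def from_mapping(cls, raw: dict):
    """Build a config dataclass from a mapping, rejecting unknown keys."""
    if not isinstance(raw, dict):
        raise ConfigError(f"expected a mapping for {cls.__name__}")
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = sorted(set(raw) - set(known))
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {', '.join(unknown)}")
    kwargs = {}
    for key, value in raw.items():
        ftype = known[key].type
        if key == "sim":
            value = from_mapping(SimConfig, value)
        elif key == "stgpr":
            value = from_mapping(StgprConfig, value)
            value.validate()
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    try:
        obj = cls(**kwargs)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(str(exc)) from exc
    if cls is StgprConfig:
        obj.validate()
    return obj


def validate_config(raw: dict | str | Path) -> PipelineConfig:
    """Parse and validate a pipeline configuration.

    Accepts a mapping or a path to a YAML document; returns a fully
    defaulted :class:`PipelineConfig`.  Schema violations raise
    :class:`ConfigError` naming the offending key.
    """
    if isinstance(raw, (str, Path)):
        raw = yaml.safe_load(Path(raw).read_text()) or {}
    return from_mapping(PipelineConfig, raw)
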
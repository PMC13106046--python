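"""Synthetic study generator: latent truth, covariates, surveys, outcomes.

The generator emulates the statistical structure the estimation pipeline
assumes about real multi-country survey collections:

* smooth latent country-year values per indicator, driven by three
  standardised covariates (an ANC4-like coverage series, health-worker
  density, and a health-access/quality index), a country random intercept,
  and a smooth temporal Gaussian-process deviation — all on the logit scale
  for proportions and on the log scale for the two means;
* retrospective household surveys placed at Poisson-sampled country-years,
  interviewing women about their most recent livebirth within a five-year
  recall window, with design effects expressed through unequal survey
  weights;
* item-level dependence within a woman through a single shared logit-scale
  "compliance" factor, so the all-five-items composite is a genuine joint
  probability rather than a product of marginals (content shortfalls
  cluster within health systems);
* abbreviated sources that omit the weight or iron question entirely, as a
  sizeable minority of real surveys do.

Item marginals are parameterised directly: the per-item logit offsets are
solved numerically so that, after integrating over the compliance factor,
each item's marginal equals the inverse-logit of its linear predictor.
Dependence therefore never attenuates the covariate effects that the
first-stage regression is asked to recover.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import betainc, expit, logit
from scipy.optimize import brentq

from .config import SimConfig
from .indicators import CONTENT_ITEMS, INDICATORS
from .util import substream

logger = logging.getLogger("anc_stgpr.synthetic")

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(60)

#: channels that require the item-level model
_ITEM_DRIVEN = set(CONTENT_ITEMS) | {"content_proportion", "content_mean"}


def _compliance_marginal(eta: np.ndarray, sd: float) -> np.ndarray:
    """E[invlogit(eta + Z)] for Z ~ N(0, sd^2), by Gauss-Hermite quadrature."""
    if sd == 0.0:
        return expit(eta)
    z = np.sqrt(2.0) * sd * _GH_NODES
    w = _GH_WEIGHTS / np.sqrt(np.pi)
    return expit(eta[..., None] + z) @ w


class _MarginalInverter:
    """Invert p -> eta with eta such that E[invlogit(eta+Z)] = p."""

    def __init__(self, sd: float, grid_half_width: float = 16.0, n: int = 6001):
        self.sd = sd
        if sd == 0.0:
            self._grid = None
            return
        self._eta = np.linspace(-grid_half_width, grid_half_width, n)
        self._p = _compliance_marginal(self._eta, sd)

    def __call__(self, p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        if self.sd == 0.0:
            return logit(p)
        return np.interp(p, self._p, self._eta)


def _joint_all(etas: np.ndarray, sd: float) -> np.ndarray:
    """P(all items received): E[prod_k invlogit(eta_k + Z)].

    ``etas`` has shape (..., K); the compliance factor Z is shared across
    items within a woman.
    """
    if sd == 0.0:
        return expit(etas).prod(axis=-1)
    z = np.sqrt(2.0) * sd * _GH_NODES
    w = _GH_WEIGHTS / np.sqrt(np.pi)
    probs = expit(etas[..., None] + z)          # (..., K, Q)
    return probs.prod(axis=-2) @ w


def first_visit_month_probs(p_early: float) -> np.ndarray:
    """Distribution of first-visit month 1..9 as a discretised Beta(a, 2).

    The shape parameter ``a`` is solved so that P(month <= 3) equals
    ``p_early``; gestational months partition the Beta's unit support into
    ninths.
    """
    p = float(np.clip(p_early, 1e-6, 1 - 1e-6))
    a = brentq(lambda s: betainc(np.exp(s), 2.0, 1.0 / 3.0) - p, -14.0, 10.0)
    a = np.exp(a)
    edges = betainc(a, 2.0, np.arange(10) / 9.0)
    probs = np.diff(edges)
    return probs / probs.sum()


@dataclass
class TruthSurface:
    """Latent country-year truth for every simulated quantity.

    ``series`` maps a series name to a (n_countries, n_years) array.  Item
    series (e.g. ``att:bp_measured``) are on the ANC-attendee scale;
    ``iron_supplementation`` is among all women with a livebirth, as is
    ``mean_visits``; ``anc1`` is the attendance proportion itself.
    """

    countries: list[str]
    years: np.ndarray
    series: dict[str, np.ndarray]
    item_eta: dict[str, np.ndarray] = field(default_factory=dict)
    compliance_sd: float = 0.0
    iron_eta_nonattendee: np.ndarray | None = None
    _idx: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self._idx = {c: i for i, c in enumerate(self.countries)}

    def cell(self, location: str, year: int) -> tuple[int, int]:
        j = int(np.searchsorted(self.years, int(year)))
        if j >= len(self.years) or self.years[j] != int(year):
            raise KeyError(f"year {year} outside truth panel")
        return self._idx[location], j

    def value(self, series: str, location: str, year: int) -> float:
        i, j = self.cell(location, year)
        return float(self.series[series][i, j])

    def modelled(self, indicator: str) -> np.ndarray:
        """Truth for the quantity the pipeline models for this indicator.

        Clinic items, composites and early initiation are modelled on the
        attendee-conditional scale (that is what the surveys measure); iron
        and mean visits are modelled among all women with a livebirth.
        """
        if indicator in ("iron_supplementation", "content_proportion",
                         "content_mean", "mean_visits", "anc1"):
            return self.series[indicator]
        if indicator in CONTENT_ITEMS:
            return self.series[f"att:{indicator}"]
        if indicator == "early_initiation":
            return self.series["early_initiation"]
        raise KeyError(indicator)

    def all_women(self, indicator: str) -> np.ndarray:
        """Truth among all women with a livebirth (post ANC1-rescaling scale)."""
        ind = INDICATORS[indicator]
        m = self.modelled(indicator)
        return m * self.series["anc1"] if ind.scale_by_anc1 else m

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, arr in sorted(self.series.items()):
            for i, c in enumerate(self.countries):
                for j, y in enumerate(self.years):
                    rows.append((name, c, int(y), arr[i, j]))
        return pd.DataFrame(rows, columns=["series", "location", "year", "value"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _smooth_gp_deviations(rng: np.random.Generator, n_countries: int,
                          years: np.ndarray, amplitude: float,
                          timescale: float) -> np.ndarray:
    """One smooth zero-mean temporal GP path per country (squared-exp kernel)."""
    if amplitude == 0.0:
        return np.zeros((n_countries, len(years)))
    d = (years[:, None] - years[None, :]) / timescale
    cov = amplitude ** 2 * np.exp(-0.5 * d ** 2) + 1e-10 * np.eye(len(years))
    chol = np.linalg.cholesky(cov)
    return rng.standard_normal((n_countries, len(years))) @ chol.T


def simulate_covariates(config: SimConfig) -> pd.DataFrame:
    """Three smooth covariate series per country-year, panel-standardised.

    Columns x1 (ANC4-like coverage, trending upward), x2 (health-worker
    density) and x3 (access/quality index) are each standardised to mean 0,
    sd 1 across the whole panel.  Deterministic given the config seed.
    """
    rng = substream(config.seed, "covariates")
    years = config.years
    t = (years - years.mean()) / (0.5 * (years[-1] - years[0]))
    countries = config.countries
    data = {}
    trends = (1.0, 0.5, 0.6)
    for k, trend in enumerate(trends, start=1):
        cols = []
        for _ in countries:
            a = rng.normal(0.0, 1.0)
            b = rng.normal(trend, 0.3)
            c = rng.normal(0.0, 0.25)
            phase = rng.uniform(0, 2 * np.pi)
            cols.append(a + b * t + c * np.sin(np.pi * t + phase))
        arr = np.concatenate(cols)
        data[f"x{k}"] = (arr - arr.mean()) / arr.std()
    frame = pd.DataFrame({
        "location": np.repeat(countries, len(years)),
        "year": np.tile(years, len(countries)),
        **data,
    })
    return frame


def _linear_predictor(config: SimConfig, covariates: pd.DataFrame, channel: str,
                      intercept: float, beta_scale: float = 1.0) -> np.ndarray:
    """intercept + beta.x + country effect + smooth GP, shape (C, Y)."""
    countries, years = config.countries, config.years
    x = (covariates.sort_values(["location", "year"])
         [["x1", "x2", "x3"]].to_numpy()
         .reshape(len(countries), len(years), 3))
    beta = beta_scale * np.asarray(config.covariate_effects)
    lp = intercept + x @ beta
    rng_c = substream(config.seed, "truth", channel, "country")
    lp += config.country_sd * rng_c.standard_normal(len(countries))[:, None]
    rng_g = substream(config.seed, "truth", channel, "gp")
    lp += _smooth_gp_deviations(rng_g, len(countries), years,
                                config.gp_amplitude, config.gp_timescale)
    return lp


def simulate_truth(config: SimConfig,
                   covariates: pd.DataFrame | None = None) -> TruthSurface:
    """Generate the latent truth surface for the configured indicators.

    Composite truths are derived from the item-level compliance model, never
    drawn independently: the content proportion is the joint probability
    that all five items are received by one woman, and the content mean is
    the sum of the five item marginals.
    """
    config.validate()
    if covariates is None:
        covariates = simulate_covariates(config)
    countries, years = config.countries, config.years
    sd = config.compliance_sd
    series: dict[str, np.ndarray] = {}
    item_eta: dict[str, np.ndarray] = {}
    iron_eta_non = None

    # ANC1 attendance is always needed (survey generation + rescaling).
    series["anc1"] = expit(_linear_predictor(
        config, covariates, "anc1", config.anc1_intercept))

    wanted = set(config.indicators)
    if wanted & _ITEM_DRIVEN:
        invert = _MarginalInverter(sd)
        for item in CONTENT_ITEMS:
            target = expit(_linear_predictor(
                config, covariates, item, config.item_intercepts[item]))
            eta = invert(target)
            item_eta[item] = eta
            series[f"att:{item}"] = _compliance_marginal(eta, sd)
        etas = np.stack([item_eta[i] for i in CONTENT_ITEMS], axis=-1)
        series["content_proportion"] = _joint_all(etas, sd)
        series["content_mean"] = sum(series[f"att:{i}"] for i in CONTENT_ITEMS)
        # Iron outside antenatal care: same compliance model with a logit
        # penalty, mixed over attendance for the all-women marginal.
        target_non = expit(logit(series["att:iron_supplementation"])
                           - config.iron_nonattendee_gap)
        iron_eta_non = invert(target_non)
        p_non = _compliance_marginal(iron_eta_non, sd)
        series["iron_nonattendee"] = p_non
        series["iron_supplementation"] = (
            series["anc1"] * series["att:iron_supplementation"]
            + (1.0 - series["anc1"]) * p_non)

    if "early_initiation" in wanted:
        series["early_initiation"] = expit(_linear_predictor(
            config, covariates, "early_initiation", config.early_intercept))

    if "mean_visits" in wanted:
        lp = _linear_predictor(config, covariates, "mean_visits",
                               config.visits_log_mean, beta_scale=0.25)
        series["visits_attendee_mean"] = 1.0 + np.exp(lp)
        series["mean_visits"] = series["anc1"] * series["visits_attendee_mean"]

    return TruthSurface(countries, years, series, item_eta, sd, iron_eta_non)


# ---------------------------------------------------------------------------
# Survey microdata
# ---------------------------------------------------------------------------

_MICRODATA_COLUMNS = [
    "woman_id", "survey_id", "location", "interview_year", "interview_month",
    "birth_year", "birth_month", "survey_weight", "attended_anc", "n_visits",
    "first_visit_month", "iron", "weight_measured", "bp_measured",
    "blood_sample", "urine_sample",
]


def _clamp_year(year: int, years: np.ndarray) -> int:
    return int(np.clip(year, years[0], years[-1]))


def simulate_surveys(truth: TruthSurface, config: SimConfig) -> list[pd.DataFrame]:
    """Draw retrospective surveys from the truth surface.

    Surveys land at Poisson-sampled country-years.  Each interviewed woman
    reports her most recent livebirth within the configured recall window
    (five years by default), so the tabulator's two-year restriction is a
    genuine filter.  With the configured probabilities a survey omits the
    weight column, the iron column, or one other clinic item column
    entirely, producing abbreviated sources.
    """
    rng = substream(config.seed, "surveys")
    years = truth.years
    sd = truth.compliance_sd
    surveys: list[pd.DataFrame] = []
    woman_counter = 0
    p_weight, p_iron, p_other = config.missingness_probs

    for country in truth.countries:
        n_surveys = rng.poisson(config.survey_rate)
        for s in range(n_surveys):
            interview_year = int(rng.choice(years))
            interview_month = int(rng.integers(1, 13))
            n_women = int(rng.poisson(config.mean_sample_size))
            if n_women == 0:
                logger.info("dropping empty survey for %s in %d",
                            country, interview_year)
                continue
            survey_id = f"{country}_{interview_year}_{s}"
            bias = rng.normal(0.0, config.residual_sd)
            deff = rng.uniform(*config.design_effect_range)
            sigma_w = np.sqrt(np.log(deff)) if deff > 1.0 else 0.0
            weights = rng.lognormal(-0.5 * sigma_w ** 2, sigma_w, n_women)

            months_back = rng.integers(1, config.recall_window_months + 1, n_women)
            interview_index = interview_year * 12 + (interview_month - 1)
            birth_index = interview_index - months_back
            birth_year = birth_index // 12
            birth_month = birth_index % 12 + 1
            cell_year = np.array([_clamp_year(y, years) for y in birth_year])

            df = pd.DataFrame({
                "woman_id": np.arange(woman_counter, woman_counter + n_women),
                "survey_id": survey_id,
                "location": country,
                "interview_year": interview_year,
                "interview_month": interview_month,
                "birth_year": birth_year,
                "birth_month": birth_month,
                "survey_weight": weights,
            })
            woman_counter += n_women

            anc1 = np.array([truth.value("anc1", country, y) for y in cell_year])
            attended = rng.random(n_women) < expit(logit(anc1) + bias)
            df["attended_anc"] = attended.astype(int)

            z = rng.normal(0.0, sd, n_women)
            for item in CONTENT_ITEMS:
                col = np.full(n_women, np.nan)
                if truth.item_eta:
                    eta = np.array([truth.item_eta[item][truth.cell(country, y)]
                                    for y in cell_year])
                    col[attended] = (rng.random(attended.sum())
                                     < expit(eta[attended] + z[attended] + bias)
                                     ).astype(float)
                    if item == "iron_supplementation":
                        eta_non = np.array(
                            [truth.iron_eta_nonattendee[truth.cell(country, y)]
                             for y in cell_year])
                        non = ~attended
                        col[non] = (rng.random(non.sum())
                                    < expit(eta_non[non] + z[non] + bias)
                                    ).astype(float)
                df[{"iron_supplementation": "iron"}.get(item, item)] = col

            # first visit month and visit counts, attendees only
            month = np.full(n_women, np.nan)
            visits = np.zeros(n_women, dtype=int)
            if "early_initiation" in truth.series:
                for y in np.unique(cell_year[attended]):
                    mask = attended & (cell_year == y)
                    p = expit(logit(truth.value("early_initiation", country, y))
                              + bias)
                    probs = first_visit_month_probs(p)
                    month[mask] = rng.choice(np.arange(1, 10), mask.sum(), p=probs)
            if "visits_attendee_mean" in truth.series:
                mu = np.array([truth.value("visits_attendee_mean", country, y)
                               for y in cell_year])
                m = np.maximum((mu - 1.0) * np.exp(bias), 1e-9)
                r = config.visits_dispersion
                extra = rng.negative_binomial(r, r / (r + m[attended]))
                visits[attended] = 1 + extra
            else:
                visits[attended] = 1
            df["first_visit_month"] = month
            df["n_visits"] = visits

            # abbreviated sources: drop whole item columns
            if truth.item_eta:
                if rng.random() < p_weight:
                    df = df.drop(columns="weight_measured")
                if rng.random() < p_iron:
                    df = df.drop(columns="iron")
                if rng.random() < p_other:
                    other = rng.choice(["bp_measured", "blood_sample",
                                        "urine_sample"])
                    df = df.drop(columns=other)
            surveys.append(df[[c for c in _MICRODATA_COLUMNS if c in df.columns]])
    return surveys


def simulate_outcomes(truth: TruthSurface, config: SimConfig) -> pd.DataFrame:
    """Country-level MMR / NMR / SBR series, decreasing in care content.

    Outcomes are generated on the log scale as noisy decreasing functions of
    the all-women content mean (falling back to ANC1 coverage when the item
    model was not simulated), so they are strictly positive and their rank
    correlation with the indicator is controlled by ``outcome_noise_sd``.
    """
    if "content_mean" in truth.series:
        driver = truth.series["content_mean"] * truth.series["anc1"]
    else:
        driver = 5.0 * truth.series["anc1"]
    rng = substream(config.seed, "outcomes")
    specs = {"mmr": (np.log(400.0), 0.5, 1.0),
             "nmr": (np.log(25.0), 0.4, 0.5),
             "sbr": (np.log(15.0), 0.35, 0.8)}
    rows = {"location": np.repeat(truth.countries, len(truth.years)),
            "year": np.tile(truth.years, len(truth.countries))}
    for name, (a, b, noise_factor) in specs.items():
        eps = rng.normal(0.0, 1.0, driver.shape)
        vals = np.exp(a - b * driver + noise_factor * config.outcome_noise_sd * eps)
        rows[name] = vals.ravel()
    return pd.DataFrame(rows)


def simulate_anc1_draws(truth: TruthSurface, config: SimConfig, n_draws: int,
                        seed: int | None = None):
    """ANC1 coverage as a draw cube: logit-normal noise around the truth.

    Attendance is estimated by a separate model in the real pipeline and
    enters this one as an input; here its posterior is emulated directly.
    """
    from .cubes import DrawCube

    rng = substream(config.seed if seed is None else seed, "anc1_draws")
    base = logit(truth.series["anc1"])[:, :, None]
    draws = expit(base + rng.normal(0.0, config.anc1_draw_sd,
                                    base.shape[:2] + (n_draws,)))
    return DrawCube("anc1", truth.countries, truth.years, draws,
                    denominator="all_livebirths")


def write_surveys(surveys: list[pd.DataFrame], directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for df in surveys:
        path = directory / f"{df['survey_id'].iloc[0]}.csv"
        df.to_csv(path, index=False)
        paths.append(path)
    return paths
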
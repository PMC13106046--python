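"""Three-stage spatiotemporal Gaussian-process regression.

Stage 1 fits a linear mixed-effects regression of the transformed data on
the three covariates with a country random intercept, observations weighted
by the inverse of their sampling variance, and predicts a prior mean for
every country-year (unseen countries receive the fixed-effects prediction
alone).  Stage 2 smooths the residuals between data and stage-1 predictions
over time and the location hierarchy with a tricube temporal kernel and
discrete spatial weights (1 within country, zeta within region, zeta^2
across regions), borrowing strength where data are sparse.  Stage 3
conditions a Gaussian process (Matern-3/2 kernel) on each country's own
data around the stage-2 mean, with the per-datum sampling variance as
observation noise; the kernel amplitude is set from the robust scale of the
stage-2 residuals.  Posterior sample paths, back-transformed to the natural
scale, form the draw cube that every later adjustment consumes.

The model-object surface follows statsmodels conventions: ``STGPR`` is
constructed from a :class:`ModelFrame`, ``fit()`` returns
:class:`STGPRResults` holding the stage artifacts, and draws and summary
tables hang off the results object.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from .config import StgprConfig
from .cubes import DrawCube
from .hierarchy import LocationHierarchy
from .indicators import INDICATORS
from .tabulation import SourceEstimate
from .util import delta_variance, inverse_transform, transform_value

logger = logging.getLogger("anc_stgpr.stgpr")

_COVARIATES = ["x1", "x2", "x3"]


class NumericalError(RuntimeError):
    """A covariance matrix could not be stabilised within the jitter budget."""


# ---------------------------------------------------------------------------
# Model frame
# ---------------------------------------------------------------------------

class ModelFrame:
    """Transformed observations plus the covariate panel and hierarchy.

    ``data`` has one row per source estimate with columns (location, year,
    y, v, source_id) where y is the logit (proportions) or log (means) of
    the tabulated value and v its transform-scale sampling variance.
    """

    def __init__(self, indicator: str, data: pd.DataFrame,
                 covariates: pd.DataFrame, hierarchy: LocationHierarchy):
        self.indicator = indicator
        self.transform = INDICATORS[indicator].transform
        self.data = data.reset_index(drop=True)
        self.covariates = covariates
        self.hierarchy = hierarchy
        self.years = np.sort(covariates["year"].unique())
        self.countries = hierarchy.countries
        self._validate()
        cov = covariates.set_index(["location", "year"])
        self._x_panel = {
            (c, int(y)): cov.loc[(c, int(y)), _COVARIATES].to_numpy(dtype=float)
            for c in self.countries for y in self.years}

    def _validate(self) -> None:
        if (self.data["v"] <= 0).any():
            raise ValueError("transform-scale variances must be positive")
        known = set(self.countries)
        bad = set(self.data["location"]) - known
        if bad:
            raise ValueError(f"data locations missing from hierarchy: {sorted(bad)}")
        years = set(int(y) for y in self.years)
        bad_years = set(int(y) for y in self.data["year"]) - years
        if bad_years:
            raise ValueError(f"data years outside panel: {sorted(bad_years)}")

    @classmethod
    def from_estimates(cls, estimates: list[SourceEstimate], indicator: str,
                       covariates: pd.DataFrame,
                       hierarchy: LocationHierarchy) -> "ModelFrame":
        """Build the frame, preferring full over crosswalked definitions.

        For the composites, each source contributes at most one row: its
        full estimate if reported, otherwise its crosswalked one.
        Non-composite indicators only ever carry the full definition.
        """
        transform = INDICATORS[indicator].transform
        by_source: dict[str, SourceEstimate] = {}
        for est in estimates:
            if est.indicator != indicator:
                continue
            if est.definition == "full":
                by_source[est.source_id] = est
            elif (est.definition == "full (crosswalked)"
                  and est.source_id not in by_source):
                by_source[est.source_id] = est
        rows = []
        cov = covariates.set_index(["location", "year"])
        years = covariates["year"].unique()
        for sid in sorted(by_source):
            est = by_source[sid]
            year = int(np.clip(est.year, years.min(), years.max()))
            x = cov.loc[(est.location, year), _COVARIATES]
            rows.append({
                "location": est.location, "year": year, "source_id": sid,
                "y": float(transform_value(est.value, transform)),
                "v": delta_variance(est.value, est.standard_error, transform),
                **{k: float(x[k]) for k in _COVARIATES},
            })
        return cls(indicator, pd.DataFrame(rows), covariates, hierarchy)

    def x_at(self, location: str, year: int) -> np.ndarray:
        return self._x_panel[(location, int(year))]


# ---------------------------------------------------------------------------
# Stage 1: weighted random-intercept regression (REML)
# ---------------------------------------------------------------------------

@dataclass
class Stage1Fit:
    """Mixed-effects prior: fixed effects, country BLUPs, panel predictions."""

    fixed_effects: np.ndarray          # (intercept, b1, b2, b3)
    fixed_effects_se: np.ndarray
    country_sd: float                  # random-intercept sd (tau)
    scale: float                       # residual multiplier sigma^2 on v
    blups: dict[str, float]
    predictions: pd.DataFrame          # location, year, m1
    fixed_only: bool = False
    _pred: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._pred = {(r.location, int(r.year)): r.m1
                      for r in self.predictions.itertuples()}

    def m1(self, location: str, year: int) -> float:
        return self._pred[(location, int(year))]


def _reml_negloglik(params: np.ndarray, groups: list[tuple[np.ndarray, np.ndarray,
                                                           np.ndarray]]) -> float:
    """-2 x REML log-likelihood of the weighted random-intercept model.

    Observation variances are sigma2 * v_i plus tau2 shared within country;
    Woodbury keeps everything O(n) per country.
    """
    log_sigma2, log_tau2 = params
    sigma2, tau2 = math.exp(log_sigma2), math.exp(log_tau2)
    p = groups[0][1].shape[1]
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    logdet = 0.0
    cache = []
    for y, X, v in groups:
        d = sigma2 * v
        dinv = 1.0 / d
        s = dinv.sum()
        f = tau2 / (1.0 + tau2 * s)
        # V^{-1} a = D^{-1}a - f (D^{-1}1)(1'D^{-1}a)
        Xd = X * dinv[:, None]
        yd = y * dinv
        xtvx += X.T @ Xd - f * np.outer(Xd.sum(0), Xd.sum(0))
        xtvy += X.T @ yd - f * Xd.sum(0) * yd.sum()
        logdet += np.log(d).sum() + math.log1p(tau2 * s)
        cache.append((y, X, dinv, f))
    try:
        beta = np.linalg.solve(xtvx, xtvy)
        sign, logdet_xtvx = np.linalg.slogdet(xtvx)
        if sign <= 0:
            return 1e10
    except np.linalg.LinAlgError:
        return 1e10
    quad = 0.0
    for y, X, dinv, f in cache:
        r = y - X @ beta
        rd = r * dinv
        quad += r @ rd - f * rd.sum() ** 2
    return logdet + logdet_xtvx + quad


def fit_stage1(frame: ModelFrame) -> Stage1Fit:
    """Fit the stage-1 prior by restricted maximum likelihood.

    Falls back to a fixed-effects-only weighted regression (with a warning)
    when the mixed model cannot be fitted — fewer than two countries with
    data, or a singular/failed optimisation.
    """
    data = frame.data
    n, p = len(data), 1 + len(_COVARIATES)
    if n == 0:
        raise ValueError("cannot fit stage 1 without data")
    y_all = data["y"].to_numpy(dtype=float)
    v_all = data["v"].to_numpy(dtype=float)
    if n < p + 1:
        # too few rows for covariate effects: intercept-only weighted mean
        logger.warning("stage 1 has only %d rows; fitting intercept only", n)
        w = 1.0 / v_all
        mean = float(np.sum(w * y_all) / w.sum())
        beta = np.array([mean, 0.0, 0.0, 0.0])
        beta_se = np.array([float(1.0 / np.sqrt(w.sum())), np.inf, np.inf,
                            np.inf])
        rows = [(c, int(yr), mean) for c in frame.countries
                for yr in frame.years]
        return Stage1Fit(beta, beta_se, 0.0, 1.0, {},
                         pd.DataFrame(rows,
                                      columns=["location", "year", "m1"]),
                         fixed_only=True)
    X_all = np.column_stack([np.ones(n), data[_COVARIATES].to_numpy(dtype=float)])

    groups = []
    order = data.groupby("location").indices
    for loc in sorted(order):
        idx = order[loc]
        groups.append((y_all[idx], X_all[idx], v_all[idx]))

    fixed_only = len(groups) < 2
    beta = beta_se = None
    tau2 = sigma2 = 0.0
    if not fixed_only:
        x0 = np.array([0.0, math.log(0.1)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                _reml_negloglik, x0, args=(groups,), method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
        if not res.success and not np.isfinite(res.fun):
            fixed_only = True
        else:
            sigma2, tau2 = float(np.exp(res.x[0])), float(np.exp(res.x[1]))
            xtvx = np.zeros((p, p))
            xtvy = np.zeros(p)
            for y, X, v in groups:
                dinv = 1.0 / (sigma2 * v)
                s = dinv.sum()
                f = tau2 / (1.0 + tau2 * s)
                Xd = X * dinv[:, None]
                xtvx += X.T @ Xd - f * np.outer(Xd.sum(0), Xd.sum(0))
                xtvy += X.T @ (y * dinv) - f * Xd.sum(0) * (y * dinv).sum()
            try:
                cov_beta = np.linalg.inv(xtvx)
                beta = cov_beta @ xtvy
                beta_se = np.sqrt(np.diag(cov_beta))
            except np.linalg.LinAlgError:
                fixed_only = True

    if fixed_only:
        logger.warning("stage 1 falling back to fixed-effects-only regression")
        w = 1.0 / v_all
        xtwx = X_all.T @ (X_all * w[:, None])
        cov_beta = np.linalg.pinv(xtwx)
        beta = cov_beta @ (X_all.T @ (y_all * w))
        beta_se = np.sqrt(np.diag(cov_beta))
        tau2, sigma2 = 0.0, 1.0

    blups: dict[str, float] = {}
    if not fixed_only and tau2 > 0:
        for loc, (y, X, v) in zip(sorted(order), groups):
            dinv = 1.0 / (sigma2 * v)
            r = y - X @ beta
            blups[loc] = float(tau2 * (r * dinv).sum()
                               / (1.0 + tau2 * dinv.sum()))

    rows = []
    for c in frame.countries:
        u = blups.get(c, 0.0)
        for yr in frame.years:
            x = frame.x_at(c, yr)
            rows.append((c, int(yr),
                         float(beta[0] + x @ beta[1:] + u)))
    predictions = pd.DataFrame(rows, columns=["location", "year", "m1"])
    return Stage1Fit(np.asarray(beta), np.asarray(beta_se),
                     math.sqrt(tau2), sigma2, blups, predictions, fixed_only)


# ---------------------------------------------------------------------------
# Stage 2: space-time residual smoothing
# ---------------------------------------------------------------------------

@dataclass
class Stage2Prior:
    """Space-time smoothed mean function m2 on the transform scale."""

    mean: pd.DataFrame                 # location, year, m2
    lambda_time: float
    zeta_space: float
    _m2: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._m2 = {(r.location, int(r.year)): r.m2
                    for r in self.mean.itertuples()}

    def m2(self, location: str, year: int) -> float:
        return self._m2[(location, int(year))]


def tricube(u: np.ndarray) -> np.ndarray:
    a = np.clip(np.abs(u), 0.0, None)
    w = (1.0 - a ** 3) ** 3
    return np.where(a < 1.0, w, 0.0)


def smooth_residuals(frame: ModelFrame, stage1: Stage1Fit, lambda_time: float,
                     zeta_space: float) -> Stage2Prior:
    """Add a locally weighted average of stage-1 residuals to the prior mean.

    Weight of datum i at cell (c, t): tricube(|t - t_i| / lambda_time) times
    1 if the datum is from c itself, zeta_space if from another country in
    c's region, zeta_space^2 otherwise.  Cells with zero total weight keep
    the stage-1 prediction.
    """
    if lambda_time <= 0:
        raise ValueError("lambda_time must be positive")
    if not 0.0 <= zeta_space <= 1.0:
        raise ValueError("zeta_space must lie in [0, 1]")
    data = frame.data
    r = data["y"].to_numpy(dtype=float) - np.array(
        [stage1.m1(loc, yr) for loc, yr in zip(data["location"], data["year"])])
    data_years = data["year"].to_numpy(dtype=float)
    data_locs = data["location"].to_numpy()
    data_regions = np.array([frame.hierarchy.region_of(c) for c in data_locs])

    rows = []
    for c in frame.countries:
        region = frame.hierarchy.region_of(c)
        w_space = np.where(data_locs == c, 1.0,
                           np.where(data_regions == region,
                                    zeta_space, zeta_space ** 2))
        for t in frame.years:
            w = w_space * tricube((t - data_years) / lambda_time)
            total = w.sum()
            adj = float((w @ r) / total) if total > 0 else 0.0
            rows.append((c, int(t), stage1.m1(c, t) + adj))
    return Stage2Prior(pd.DataFrame(rows, columns=["location", "year", "m2"]),
                       lambda_time, zeta_space)


# ---------------------------------------------------------------------------
# Stage 3: Gaussian-process regression
# ---------------------------------------------------------------------------

def matern32(t1: np.ndarray, t2: np.ndarray, amplitude: float,
             timescale: float) -> np.ndarray:
    d = np.abs(t1[:, None] - t2[None, :]) * (math.sqrt(3.0) / timescale)
    return amplitude ** 2 * (1.0 + d) * np.exp(-d)


def _stable_cho_factor(mat: np.ndarray):
    # observation noise usually makes the matrix PD as-is; only escalate
    # jitter (1e-8 .. 1e-4, x10 steps) when factorisation actually fails
    for jitter in (0.0, 1e-8, 1e-7, 1e-6, 1e-5, 1e-4):
        try:
            return cho_factor(mat + jitter * np.eye(len(mat)), lower=True)
        except np.linalg.LinAlgError:
            continue
    raise NumericalError("covariance not positive definite after jitter 1e-4")


@dataclass
class GPRPosterior:
    """Per-location posterior mean vectors and covariance matrices over years."""

    locations: list[str]
    years: np.ndarray
    means: np.ndarray                  # (L, Y)
    covariances: np.ndarray            # (L, Y, Y)
    amplitude: float
    timescale: float

    def sd(self) -> np.ndarray:
        return np.sqrt(np.maximum(np.diagonal(self.covariances,
                                              axis1=1, axis2=2), 0.0))


def estimate_amplitude(frame: ModelFrame, stage2: Stage2Prior,
                       config: StgprConfig | None = None) -> float:
    """Kernel amplitude from the robust scale of stage-2 residuals.

    eta = 1.4826 x MAD(y - m2), floored; when fewer than five residuals are
    available the configured default is used instead.
    """
    config = config or StgprConfig()
    data = frame.data
    if len(data) < 5:
        return config.default_amplitude
    resid = data["y"].to_numpy(dtype=float) - np.array(
        [stage2.m2(loc, yr) for loc, yr in zip(data["location"], data["year"])])
    mad = float(np.median(np.abs(resid - np.median(resid))))
    return max(1.4826 * mad, config.amplitude_floor)


def fit_gpr(prior: Stage2Prior, frame: ModelFrame, amplitude: float,
            timescale: float) -> GPRPosterior:
    """Condition a Matern-3/2 GP on each location's own data.

    The prior mean is the stage-2 surface; observation noise is each
    datum's transform-scale sampling variance.  Locations without data
    return the prior mean with the full prior covariance.
    """
    if amplitude <= 0 or timescale <= 0:
        raise ValueError("kernel hyperparameters must be positive")
    years = frame.years.astype(float)
    n_years = len(years)
    k_prior = matern32(years, years, amplitude, timescale)
    locations = frame.countries
    means = np.empty((len(locations), n_years))
    covs = np.empty((len(locations), n_years, n_years))
    grouped = frame.data.groupby("location").indices
    for i, c in enumerate(locations):
        m_prior = np.array([prior.m2(c, int(y)) for y in frame.years])
        idx = grouped.get(c)
        if idx is None or len(idx) == 0:
            means[i] = m_prior
            covs[i] = k_prior
            continue
        sub = frame.data.iloc[idx]
        t_obs = sub["year"].to_numpy(dtype=float)
        y_obs = sub["y"].to_numpy(dtype=float)
        v_obs = sub["v"].to_numpy(dtype=float)
        m_obs = np.array([prior.m2(c, int(t)) for t in sub["year"]])
        k_oo = matern32(t_obs, t_obs, amplitude, timescale) + np.diag(v_obs)
        k_po = matern32(years, t_obs, amplitude, timescale)
        chol = _stable_cho_factor(k_oo)
        alpha = cho_solve(chol, y_obs - m_obs)
        means[i] = m_prior + k_po @ alpha
        covs[i] = k_prior - k_po @ cho_solve(chol, k_po.T)
    covs = 0.5 * (covs + covs.transpose(0, 2, 1))
    return GPRPosterior(list(locations), frame.years, means, covs,
                        amplitude, timescale)


def sample_draws(posterior: GPRPosterior, n_draws: int, seed: int,
                 transform: str = "logit", indicator: str = "",
                 upper: float | None = None,
                 denominator: str = "all_livebirths") -> DrawCube:
    """Sample posterior paths and back-transform to the natural scale.

    Covariance square roots come from a symmetric eigendecomposition with
    negative eigenvalues clipped to zero, so an exactly singular posterior
    (e.g. zero covariance) yields degenerate draws rather than a failure.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    n_loc, n_years = posterior.means.shape
    out = np.empty((n_loc, n_years, n_draws))
    for i in range(n_loc):
        evals, evecs = np.linalg.eigh(posterior.covariances[i])
        root = evecs * np.sqrt(np.clip(evals, 0.0, None))
        z = rng.standard_normal((n_years, n_draws))
        out[i] = posterior.means[i][:, None] + root @ z
    values = inverse_transform(out, transform)
    if upper is not None:
        values = np.clip(values, 0.0, upper)
    return DrawCube(indicator or "indicator", posterior.locations,
                    posterior.years, values, denominator=denominator)


# ---------------------------------------------------------------------------
# Model object
# ---------------------------------------------------------------------------

class STGPR:
    """The three-stage estimator for one indicator.

    Examples
    --------
    >>> frame = ModelFrame.from_estimates(estimates, "bp_measured",
    ...                                   covariates, hierarchy)   # doctest: +SKIP
    >>> results = STGPR(frame).fit()                               # doctest: +SKIP
    >>> cube = results.sample(n_draws=1000, seed=7)                # doctest: +SKIP
    """

    def __init__(self, frame: ModelFrame, config: StgprConfig | None = None):
        self.frame = frame
        self.config = config or StgprConfig()
        self.config.validate()

    def fit(self) -> "STGPRResults":
        stage1 = fit_stage1(self.frame)
        stage2 = smooth_residuals(self.frame, stage1,
                                  self.config.lambda_time,
                                  self.config.zeta_space)
        amplitude = estimate_amplitude(self.frame, stage2, self.config)
        posterior = fit_gpr(stage2, self.frame, amplitude,
                            self.config.gpr_timescale)
        return STGPRResults(self, stage1, stage2, posterior)


class STGPRResults:
    """Fitted stages, posterior, and draw/summary accessors."""

    def __init__(self, model: STGPR, stage1: Stage1Fit, stage2: Stage2Prior,
                 posterior: GPRPosterior):
        self.model = model
        self.stage1 = stage1
        self.stage2 = stage2
        self.posterior = posterior
        self.indicator = model.frame.indicator

    @property
    def amplitude(self) -> float:
        return self.posterior.amplitude

    def sample(self, n_draws: int = 1000, seed: int = 0) -> DrawCube:
        ind = INDICATORS[self.indicator]
        return sample_draws(self.posterior, n_draws, seed,
                            transform=ind.transform, indicator=self.indicator,
                            upper=ind.upper, denominator=ind.denominator)

    def predictions(self) -> pd.DataFrame:
        """Posterior mean and sd per country-year on the natural scale."""
        ind = INDICATORS[self.indicator]
        sd = self.posterior.sd()
        rows = []
        for i, c in enumerate(self.posterior.locations):
            for j, y in enumerate(self.posterior.years):
                rows.append((c, int(y), float(inverse_transform(
                    self.posterior.means[i, j], ind.transform)),
                    self.posterior.means[i, j], sd[i, j]))
        return pd.DataFrame(rows, columns=["location", "year", "mean",
                                           "mean_transformed", "sd_transformed"])

    def summary(self) -> str:
        s1 = self.stage1
        lines = [
            f"ST-GPR results: {self.indicator}",
            "=" * 40,
            f"observations: {len(self.model.frame.data)}   "
            f"countries with data: {self.model.frame.data['location'].nunique()}",
            "",
            "Stage 1 (mixed-effects prior, transform scale)",
            f"  {'term':<12}{'coef':>10}{'se':>10}",
        ]
        for name, b, se in zip(["intercept", "x1_anc4", "x2_hrh", "x3_haq"],
                               s1.fixed_effects, s1.fixed_effects_se):
            lines.append(f"  {name:<12}{b:>10.4f}{se:>10.4f}")
        lines += [
            f"  country random-intercept sd: {s1.country_sd:.4f}"
            + ("  [fixed-effects fallback]" if s1.fixed_only else ""),
            "",
            "Stage 2 (space-time smoothing)",
            f"  lambda_time={self.stage2.lambda_time:g}  "
            f"zeta_space={self.stage2.zeta_space:g}",
            "",
            "Stage 3 (Gaussian process)",
            f"  Matern-3/2 amplitude eta={self.posterior.amplitude:.4f}  "
            f"timescale rho={self.posterior.timescale:g}",
        ]
        return "\n".join(lines)
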
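"""Simulation studies evaluating the estimator against known truth.

These are the package's own validation experiments: replicate synthetic
panels are generated, the full tabulate-and-model path is run, and the
stage-1 coefficient estimates, stage-wise RMSE against the latent truth,
and the empirical coverage of the 95% draw intervals are recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logit

from .config import SimConfig, StgprConfig
from .hierarchy import LocationHierarchy
from .stgpr import STGPR, ModelFrame
from .synthetic import simulate_covariates, simulate_surveys, simulate_truth
from .tabulation import tabulate_survey
from .util import substream


@dataclass
class RecoveryStudy:
    """Results of a replicate-panel parameter-recovery experiment."""

    covariate_effects: np.ndarray        # true coefficients
    beta_estimates: np.ndarray           # (n_seeds, 3)
    beta_ses: np.ndarray                 # (n_seeds, 3)
    rmse_stage1: np.ndarray              # (n_seeds,) logit scale
    rmse_stage3: np.ndarray
    n_covered: int                       # truth inside 95% draw interval
    n_cells: int                         # pooled country-years

    @property
    def coverage(self) -> float:
        return self.n_covered / self.n_cells

    @property
    def mean_beta(self) -> np.ndarray:
        return self.beta_estimates.mean(axis=0)

    @property
    def mean_beta_se(self) -> np.ndarray:
        return self.beta_ses.mean(axis=0)


def run_recovery_study(n_seeds: int = 20, base_seed: int = 0,
                       n_countries: int = 40, n_regions: int = 5,
                       year_range: tuple[int, int] = (1995, 2023),
                       surveys_per_country: float = 2.0,
                       women_per_survey: float = 1000.0,
                       n_draws: int = 1000,
                       indicator: str = "early_initiation") -> RecoveryStudy:
    """Recover known covariate effects and measure interval calibration.

    Each replicate builds a ``n_countries``-country panel whose
    early-initiation truth is exactly logit-linear in the covariates (plus
    country intercept and smooth temporal deviation), samples retrospective
    surveys, tabulates them, runs the three-stage estimator, and compares
    stage-1 predictions and final posterior draws against the truth.
    """
    if n_countries % n_regions:
        raise ValueError("n_countries must divide evenly into regions")
    betas, ses, rmse1, rmse3 = [], [], [], []
    n_covered = 0
    n_cells = 0
    for k in range(n_seeds):
        seed = int(substream(base_seed, "recovery", k).integers(0, 2 ** 31 - 1))
        cfg = SimConfig(n_regions=n_regions,
                        countries_per_region=n_countries // n_regions,
                        year_range=year_range, seed=seed,
                        survey_rate=surveys_per_country,
                        mean_sample_size=women_per_survey,
                        indicators=(indicator,))
        covariates = simulate_covariates(cfg)
        truth = simulate_truth(cfg, covariates)
        surveys = simulate_surveys(truth, cfg)
        estimates = []
        for survey in surveys:
            estimates.extend(tabulate_survey(survey, [indicator]))
        hierarchy = LocationHierarchy.from_config(cfg)
        frame = ModelFrame.from_estimates(estimates, indicator, covariates,
                                          hierarchy)
        results = STGPR(frame, StgprConfig()).fit()
        cube = results.sample(n_draws=n_draws, seed=seed + 1)

        truth_nat = truth.modelled(indicator)
        truth_logit = logit(truth_nat)
        m1 = (results.stage1.predictions
              .pivot(index="location", columns="year", values="m1")
              .loc[truth.countries].to_numpy())
        rmse1.append(float(np.sqrt(((m1 - truth_logit) ** 2).mean())))
        rmse3.append(float(np.sqrt(
            ((results.posterior.means - truth_logit) ** 2).mean())))
        betas.append(results.stage1.fixed_effects[1:])
        ses.append(results.stage1.fixed_effects_se[1:])
        lower = np.quantile(cube.values, 0.025, axis=2)
        upper = np.quantile(cube.values, 0.975, axis=2)
        n_covered += int(((truth_nat >= lower) & (truth_nat <= upper)).sum())
        n_cells += truth_nat.size
    return RecoveryStudy(np.asarray(SimConfig().covariate_effects),
                         np.asarray(betas), np.asarray(ses),
                         np.asarray(rmse1), np.asarray(rmse3),
                         n_covered, n_cells)
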
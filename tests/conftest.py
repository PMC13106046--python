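import numpy as np
import pandas as pd
import pytest

from anc_stgpr.config import PipelineConfig, SimConfig
from anc_stgpr.hierarchy import LocationHierarchy
from anc_stgpr.synthetic import simulate_covariates, simulate_surveys, simulate_truth
from anc_stgpr.tabulation import tabulate_survey


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_regions=2, countries_per_region=3,
                     year_range=(2000, 2009), seed=42, survey_rate=3.0,
                     mean_sample_size=500.0)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_truth(small_config)


@pytest.fixture(scope="session")
def small_surveys(small_config, small_truth):
    return simulate_surveys(small_truth, small_config)


@pytest.fixture(scope="session")
def small_estimates(small_config, small_surveys):
    estimates = []
    for survey in small_surveys:
        estimates.extend(tabulate_survey(survey))
    return estimates


@pytest.fixture(scope="session")
def small_hierarchy(small_config):
    return LocationHierarchy.from_config(small_config)


@pytest.fixture(scope="session")
def small_covariates(small_config):
    return simulate_covariates(small_config)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline run shared by the pipeline/postprocess tests."""
    from anc_stgpr.pipeline import run_pipeline

    out = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(
        output_dir=str(out), seed=7, n_draws=250,
        sim=SimConfig(n_regions=2, countries_per_region=3,
                      year_range=(2000, 2009), survey_rate=3.0,
                      mean_sample_size=400.0))
    manifest = run_pipeline(cfg)
    return cfg, manifest, out


def naive_gp_oracle(t_grid, t_obs, y_obs, v_obs, m_grid, m_obs, amplitude,
                    timescale):
    """Textbook dense GP regression, written independently of the package.

    Matern-3/2 kernel, explicit matrix inversion; returns (mean, cov) over
    the grid.  Used as the closed-form oracle for the stage-3 solver.
    """
    def kern(a, b):
        d = np.abs(np.subtract.outer(a, b)) * np.sqrt(3.0) / timescale
        return amplitude ** 2 * (1.0 + d) * np.exp(-d)

    if len(t_obs) == 0:
        return m_grid, kern(t_grid, t_grid)
    k_oo = kern(t_obs, t_obs) + np.diag(v_obs)
    k_go = kern(t_grid, t_obs)
    k_gg = kern(t_grid, t_grid)
    k_inv = np.linalg.inv(k_oo)
    mean = m_grid + k_go @ k_inv @ (y_obs - m_obs)
    cov = k_gg - k_go @ k_inv @ k_go.T
    return mean, cov
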
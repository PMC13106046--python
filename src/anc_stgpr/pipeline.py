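"""End-to-end orchestration: simulate -> tabulate -> crosswalk -> model ->
rake -> rescale -> aggregate -> summarise, with a JSON run manifest.

Seeds for every stochastic stage are derived from the master seed keyed by
(stage, indicator), so adding or removing an indicator leaves all other
indicators' draws untouched, and rerunning the same configuration is
byte-identical for every value output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .crosswalk import CrosswalkMetaRegression, apply_crosswalk, build_pairs
from .cubes import DrawCube
from .hierarchy import LocationHierarchy
from .indicators import ALTERNATE_DEFINITIONS, COMPOSITES, CONTENT_ITEMS, INDICATORS
from .postprocess import (aggregate_regions, correlate_with_outcomes,
                          rake_content_proportion, scale_by_anc1, summarize)
from .stgpr import STGPR, ModelFrame
from .synthetic import (simulate_anc1_draws, simulate_covariates,
                        simulate_outcomes, simulate_surveys, simulate_truth,
                        write_surveys)
from .tabulation import tabulate_survey, write_estimates
from .util import substream

logger = logging.getLogger("anc_stgpr.pipeline")


def _stage_seed(master: int, *names: str) -> int:
    """A derived 31-bit seed for one (stage, indicator) substream."""
    return int(substream(master, *names).integers(0, 2 ** 31 - 1))


def setup_logging(output_dir: Path) -> None:
    handler = logging.FileHandler(output_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s: %(message)s"))
    root = logging.getLogger("anc_stgpr")
    root.setLevel(logging.INFO)
    root.addHandler(handler)


def fit_crosswalks(estimates, trim_fraction: float):
    """Fit one crosswalk per (composite, alternate) with enough pairs and
    adjust every abbreviated-only source onto the full definition.

    Returns (augmented estimate list, fitted models dict, diagnostics).
    """
    models = {}
    diagnostics = []
    adjusted = list(estimates)
    for indicator in COMPOSITES:
        full_sources = {e.source_id for e in estimates
                        if e.indicator == indicator and e.definition == "full"}
        for alternate in ALTERNATE_DEFINITIONS:
            pairs = build_pairs(estimates, indicator, alternate)
            orphans = [e for e in estimates
                       if e.indicator == indicator
                       and e.definition == alternate
                       and e.source_id not in full_sources]
            if not orphans:
                continue
            if len(pairs) < 2:
                logger.warning("crosswalk %s/%s: only %d pairs, "
                               "abbreviated sources dropped",
                               indicator, alternate, len(pairs))
                continue
            model = CrosswalkMetaRegression(pairs, trim_fraction, indicator,
                                            alternate).fit()
            models[(indicator, alternate)] = model
            adjusted.extend(apply_crosswalk(e, model) for e in orphans)
            diagnostics.append({
                "indicator": indicator, "alternate": alternate,
                "beta": model.beta, "beta_se": model.beta_se,
                "gamma": model.gamma, "n_pairs": len(pairs),
                "n_pairs_used": model.n_pairs_used,
                "n_adjusted": len(orphans)})
    return adjusted, models, diagnostics


def model_indicator(indicator: str, estimates, covariates: pd.DataFrame,
                    hierarchy: LocationHierarchy, config: PipelineConfig
                    ) -> tuple[DrawCube, "object"]:
    """Fit ST-GPR for one indicator and sample its draw cube."""
    frame = ModelFrame.from_estimates(estimates, indicator, covariates,
                                      hierarchy)
    results = STGPR(frame, config.stgpr).fit()
    seed = _stage_seed(config.seed, "draws", indicator)
    cube = results.sample(n_draws=config.n_draws, seed=seed)
    return cube, results


def postprocess_cubes(cubes: dict[str, DrawCube], anc1: DrawCube,
                      hierarchy: LocationHierarchy) -> dict[str, DrawCube]:
    """Rescale by ANC1, rake the composite, aggregate to regions and global.

    Rescaling happens first so that all six content cubes (including iron,
    which is tabulated among all livebirths) share the all-women scale on
    which the min-consistency constraint is enforced.
    """
    scaled: dict[str, DrawCube] = {}
    for name, cube in cubes.items():
        if INDICATORS[name].scale_by_anc1:
            scaled[name] = scale_by_anc1(cube, anc1)
        else:
            scaled[name] = cube
    if "content_proportion" in scaled and all(
            i in scaled for i in CONTENT_ITEMS):
        scaled["content_proportion"] = rake_content_proportion(
            scaled["content_proportion"],
            [scaled[i] for i in CONTENT_ITEMS])
    return {name: aggregate_regions(cube, hierarchy)
            for name, cube in sorted(scaled.items())}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run manifest."""
    t_start = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    setup_logging(out)
    config.to_yaml(out / "config.yaml")
    manifest: dict = {"seed": config.seed, "n_draws": config.n_draws,
                      "stages": {}, "status": "running"}

    def _record(stage: str, t0: float, **info) -> None:
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3),
                                     **info}

    try:
        # --- simulate ---------------------------------------------------
        t0 = time.time()
        sim = dataclasses.replace(config.sim, seed=config.seed)
        covariates = simulate_covariates(sim)
        truth = simulate_truth(sim, covariates)
        hierarchy = LocationHierarchy.from_config(
            sim, substream(config.seed, "hierarchy"))
        surveys = simulate_surveys(truth, sim)
        outcomes = simulate_outcomes(truth, sim)
        anc1 = simulate_anc1_draws(truth, sim, config.n_draws,
                                   seed=_stage_seed(config.seed, "anc1"))
        covariates.to_csv(out / "covariates.csv", index=False)
        truth.to_csv(out / "truth.csv")
        outcomes.to_csv(out / "outcomes.csv", index=False)
        hierarchy.to_csv(out / "hierarchy_nodes.csv",
                         out / "hierarchy_livebirths.csv")
        if config.write_microdata:
            write_surveys(surveys, out / "surveys")
        _record("simulate", t0, n_surveys=len(surveys),
                n_women=int(sum(len(s) for s in surveys)))

        # --- tabulate ---------------------------------------------------
        t0 = time.time()
        estimates = []
        for survey in surveys:
            estimates.extend(tabulate_survey(survey, list(config.indicators)))
        write_estimates(estimates, out / "source_estimates.csv")
        _record("tabulate", t0, n_estimates=len(estimates))

        # --- crosswalk --------------------------------------------------
        t0 = time.time()
        estimates, xwalk_models, xwalk_diag = fit_crosswalks(
            estimates, config.crosswalk_trim_fraction)
        for (indicator, alternate), model in xwalk_models.items():
            model.to_yaml(out / f"crosswalk_{indicator}_{alternate}.yaml")
        if xwalk_diag:
            pd.DataFrame(xwalk_diag).to_csv(out / "crosswalk_diagnostics.csv",
                                            index=False)
        write_estimates(estimates, out / "source_estimates_crosswalked.csv")
        _record("crosswalk", t0, n_models=len(xwalk_models))

        # --- model ------------------------------------------------------
        t0 = time.time()
        cubes: dict[str, DrawCube] = {}
        amplitudes = {}
        for indicator in config.indicators:
            cube, results = model_indicator(indicator, estimates, covariates,
                                            hierarchy, config)
            cubes[indicator] = cube
            amplitudes[indicator] = results.amplitude
            (out / "fits").mkdir(exist_ok=True)
            (out / "fits" / f"{indicator}.txt").write_text(
                results.summary() + "\n")
        _record("model", t0, amplitudes=amplitudes)

        # --- postprocess ------------------------------------------------
        t0 = time.time()
        final = postprocess_cubes(cubes, anc1, hierarchy)
        final["anc1"] = aggregate_regions(anc1, hierarchy)
        summaries = pd.concat([summarize(c) for _, c in sorted(final.items())],
                              ignore_index=True)
        summaries = summaries.sort_values(
            ["indicator", "location", "year"]).reset_index(drop=True)
        summaries.to_csv(out / "summary.csv", index=False)
        for name, cube in final.items():
            cube.save(out / "cubes" / name)
        year = config.correlation_year or int(sim.year_range[1])
        correlations = correlate_with_outcomes(
            {k: v for k, v in final.items()}, outcomes, year)
        correlations.to_csv(out / "correlations.csv", index=False)
        _record("postprocess", t0, summary_rows=len(summaries),
                correlation_year=year)

        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise
    manifest["total_seconds"] = round(time.time() - t_start, 3)
    manifest["hyperparameters"] = dataclasses.asdict(config.stgpr)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
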
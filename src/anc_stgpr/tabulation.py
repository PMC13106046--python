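"""Survey tabulation: microdata -> per-source indicator estimates.

Implements the extraction rules used for DHS/MICS-style data: only the most
recent livebirth within two years of the interview is retained; iron
supplementation is tabulated among all respondents with a livebirth while
the clinic items, the composites and first-trimester initiation are
tabulated among women who attended at least one antenatal-care visit (only
they are asked about those services).  Mean visits is tabulated over all
women, non-attendees contributing zero visits.

Design effects enter through unequal survey weights: the effective sample
size is Kish's (sum w)^2 / sum w^2 over the indicator's denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .indicators import (ALTERNATE_DEFINITIONS, CONTENT_ITEMS, COMPOSITES,
                         INDICATORS, ITEM_COLUMNS)

logger = logging.getLogger("anc_stgpr.tabulation")

RECALL_LIMIT_MONTHS = 24   # interview - birth gap, boundary inclusive
FIRST_TRIMESTER_MAX_MONTH = 3


class DefinitionUnavailableError(KeyError):
    """The microdata lacks a column required by the requested definition."""


@dataclass
class SourceEstimate:
    """One tabulated survey datapoint."""

    source_id: str
    location: str
    year: int                  # weighted mean birth year, rounded
    indicator: str
    definition: str            # "full" | alternate name | "full (crosswalked)"
    value: float
    standard_error: float
    n_eff: float
    denominator: str


def restrict_births(microdata: pd.DataFrame) -> pd.DataFrame:
    """Keep the most recent livebirth within two years of the interview.

    Rows with a missing interview or birth date are dropped (and counted in
    the log); the 24-month boundary itself is retained.
    """
    date_cols = ["interview_year", "interview_month", "birth_year", "birth_month"]
    dated = microdata.dropna(subset=date_cols)
    n_undated = len(microdata) - len(dated)
    if n_undated:
        logger.info("dropped %d rows with missing dates", n_undated)
    gap = ((dated["interview_year"] * 12 + dated["interview_month"])
           - (dated["birth_year"] * 12 + dated["birth_month"]))
    kept = dated.loc[gap <= RECALL_LIMIT_MONTHS]
    if kept["woman_id"].duplicated().any():
        kept = kept.sort_values(["woman_id", "birth_year", "birth_month"])
        kept = kept.drop_duplicates("woman_id", keep="last")
    return kept


def kish_n_eff(weights: np.ndarray) -> float:
    w = np.asarray(weights, dtype=float)
    return float(w.sum() ** 2 / (w ** 2).sum())


def _weighted_mean(values: np.ndarray, weights: np.ndarray) -> float:
    return float(np.average(values, weights=weights))


def _required_columns(indicator: str, definition: str) -> list[str]:
    if indicator in CONTENT_ITEMS:
        return [ITEM_COLUMNS[indicator]]
    if indicator in COMPOSITES:
        if definition == "full":
            items = CONTENT_ITEMS
        else:
            try:
                items = ALTERNATE_DEFINITIONS[definition]
            except KeyError:
                raise ValueError(f"unknown composite definition {definition!r}")
        return [ITEM_COLUMNS[i] for i in items]
    if indicator == "early_initiation":
        return ["first_visit_month"]
    if indicator == "mean_visits":
        return ["n_visits"]
    raise ValueError(f"unknown indicator {indicator!r}")


def tabulate_indicator(microdata: pd.DataFrame, indicator: str,
                       definition: str = "full",
                       source_id: str | None = None) -> SourceEstimate | None:
    """Tabulate one indicator (under one definition) from restricted microdata.

    Returns None (with a log entry) when the denominator is empty; raises
    :class:`DefinitionUnavailableError` when a required column is absent so
    the caller can fall back to an alternate definition.
    """
    ind = INDICATORS[indicator]
    required = _required_columns(indicator, definition)
    missing = [c for c in required if c not in microdata.columns]
    if missing:
        raise DefinitionUnavailableError(
            f"{indicator}/{definition} needs absent column(s) {missing}")
    if indicator not in COMPOSITES and definition != "full":
        raise ValueError("alternate definitions exist only for composites")

    if ind.denominator == "anc_attendees":
        sub = microdata.loc[microdata["attended_anc"] == 1]
    else:
        sub = microdata
    if len(sub) == 0:
        logger.info("zero denominator for %s/%s", indicator, definition)
        return None
    w = sub["survey_weight"].to_numpy(dtype=float)
    n_eff = kish_n_eff(w)

    if indicator in CONTENT_ITEMS:
        y = sub[required[0]].to_numpy(dtype=float)
    elif indicator == "content_proportion":
        y = (sub[required].to_numpy(dtype=float) == 1).all(axis=1).astype(float)
    elif indicator == "content_mean":
        y = sub[required].to_numpy(dtype=float).sum(axis=1)
    elif indicator == "early_initiation":
        y = (sub["first_visit_month"].to_numpy(dtype=float)
             <= FIRST_TRIMESTER_MAX_MONTH).astype(float)
    else:  # mean_visits
        y = sub["n_visits"].to_numpy(dtype=float)

    value = _weighted_mean(y, w)
    if ind.kind == "proportion":
        se = float(np.sqrt(max(value * (1.0 - value), 0.0) / n_eff))
    else:
        var = _weighted_mean((y - value) ** 2, w)
        se = float(np.sqrt(var / n_eff))

    if source_id is None:
        source_id = str(microdata["survey_id"].iloc[0])
    year = int(round(_weighted_mean(
        microdata["birth_year"].to_numpy(dtype=float),
        microdata["survey_weight"].to_numpy(dtype=float))))
    est = SourceEstimate(source_id, str(microdata["location"].iloc[0]), year,
                         indicator, definition, value, se, n_eff,
                         ind.denominator)
    return apply_variance_offset(est)


def apply_variance_offset(estimate: SourceEstimate) -> SourceEstimate:
    """Clamp boundary values so logit/log-scale modelling is well defined.

    Proportions are clamped to [0.5/n_eff, 1 - 0.5/n_eff] and their standard
    error floored at the binomial SE of the clamped value.  Means are
    floored at 0.5/n_eff with a 1% relative SE floor (a survey where every
    woman reports the identical count still carries sampling uncertainty).
    """
    ind = INDICATORS[estimate.indicator]
    offset = 0.5 / estimate.n_eff
    if ind.kind == "proportion":
        p = float(np.clip(estimate.value, offset, 1.0 - offset))
        se_floor = float(np.sqrt(p * (1.0 - p) / estimate.n_eff))
        return replace(estimate, value=p,
                       standard_error=max(estimate.standard_error, se_floor))
    value = max(estimate.value, offset)
    se_floor = 0.01 * value
    return replace(estimate, value=value,
                   standard_error=max(estimate.standard_error, se_floor))


def tabulate_survey(microdata: pd.DataFrame,
                    indicators: list[str] | None = None) -> list[SourceEstimate]:
    """Tabulate every requested indicator (and feasible composite definition).

    Composites are tabulated under the full five-item definition when all
    item columns are present, and additionally under every four-item
    alternate whose columns exist — complete sources therefore provide the
    (full, alternate) pairs on which crosswalks are trained, while
    abbreviated sources provide only an alternate to be adjusted later.
    """
    indicators = list(indicators or INDICATORS)
    restricted = restrict_births(microdata)
    if len(restricted) == 0:
        logger.info("survey %s has no births within the recall limit",
                    microdata["survey_id"].iloc[0] if len(microdata) else "?")
        return []
    estimates: list[SourceEstimate] = []
    for name in indicators:
        definitions = ["full"]
        if name in COMPOSITES:
            definitions += list(ALTERNATE_DEFINITIONS)
        for definition in definitions:
            try:
                est = tabulate_indicator(restricted, name, definition)
            except DefinitionUnavailableError:
                continue
            if est is not None:
                estimates.append(est)
    return estimates


# --- CSV round-trip --------------------------------------------------------

_COLUMNS = ["source_id", "location", "year", "indicator", "definition",
            "value", "standard_error", "n_eff", "denominator"]


def estimates_to_frame(estimates: list[SourceEstimate]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in estimates], columns=_COLUMNS)


def estimates_from_frame(frame: pd.DataFrame) -> list[SourceEstimate]:
    return [SourceEstimate(**{c: row[c] for c in _COLUMNS})
            for _, row in frame.iterrows()]


def write_estimates(estimates: list[SourceEstimate], path: str | Path) -> None:
    estimates_to_frame(estimates).to_csv(path, index=False)


def read_estimates(path: str | Path) -> list[SourceEstimate]:
    return estimates_from_frame(pd.read_csv(path))
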
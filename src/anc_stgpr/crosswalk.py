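"""Crosswalking abbreviated composite estimates onto the full definition.

A minority of sources omit one item (most often weight measurement or iron
supplementation) and can only provide a four-item composite.  To use them,
the systematic offset between the full five-item composite and each
four-item alternate is estimated on the sources that report both, by an
inverse-variance-weighted meta-regression with iterative residual-based
trimming and a method-of-moments (DerSimonian-Laird) between-source
heterogeneity component.  Abbreviated estimates are then shifted by the
fitted offset on the model's transform scale, with their variance inflated
by the offset's uncertainty and the heterogeneity, so a crosswalked source
can never be more precise than an untouched one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .indicators import INDICATORS
from .tabulation import SourceEstimate
from .util import delta_variance, inverse_transform, transform_value


@dataclass
class CrosswalkResults:
    """Fitted offset for one (indicator, alternate definition) pair."""

    indicator: str
    alternate_definition: str
    beta: float                # transform-scale offset: full - alternate
    beta_se: float
    gamma: float               # between-source heterogeneity sd
    trim_fraction: float
    n_pairs_used: int
    transform: str
    converged: bool = True

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CrosswalkResults":
        return cls(**yaml.safe_load(Path(path).read_text()))


def build_pairs(estimates: list[SourceEstimate], indicator: str,
                alternate: str) -> pd.DataFrame:
    """Pair each source's full and alternate composite on the transform scale.

    Returns one row per source reporting both definitions, with the
    transformed difference ``d = g(full) - g(alternate)`` and its standard
    error ``sqrt(se_full^2 + se_alt^2)`` (transform scale).  Sources with
    only one definition are excluded here but remain available for
    adjustment later.
    """
    transform = INDICATORS[indicator].transform
    by_source: dict[str, dict[str, SourceEstimate]] = {}
    for est in estimates:
        if est.indicator == indicator:
            by_source.setdefault(est.source_id, {})[est.definition] = est
    rows = []
    for source_id in sorted(by_source):
        defs = by_source[source_id]
        if "full" in defs and alternate in defs:
            full, alt = defs["full"], defs[alternate]
            y_full = float(transform_value(full.value, transform))
            y_alt = float(transform_value(alt.value, transform))
            var = (delta_variance(full.value, full.standard_error, transform)
                   + delta_variance(alt.value, alt.standard_error, transform))
            rows.append((source_id, y_full, y_alt, y_full - y_alt,
                         math.sqrt(var)))
    return pd.DataFrame(rows, columns=["source_id", "y_full", "y_alternate",
                                       "difference", "se"])


def _dersimonian_laird(d: np.ndarray, se: np.ndarray) -> float:
    """Method-of-moments between-source variance, floored at zero."""
    w = 1.0 / se ** 2
    mu = np.sum(w * d) / np.sum(w)
    q = np.sum(w * (d - mu) ** 2)
    denom = np.sum(w) - np.sum(w ** 2) / np.sum(w)
    if denom <= 0:
        return 0.0
    return max(0.0, (q - (len(d) - 1)) / denom)


class CrosswalkMetaRegression:
    """Trimmed inverse-variance meta-regression of definition differences.

    Parameters
    ----------
    pairs : DataFrame from :func:`build_pairs`.
    trim_fraction : proportion of pairs (by largest standardised residual)
        excluded from the fit; the membership is re-derived after each refit
        until it stabilises.  Exact residual ties are broken by dropping the
        lowest source_id first, so trimming is permutation invariant.
    """

    MAX_ITER = 100

    def __init__(self, pairs: pd.DataFrame, trim_fraction: float = 0.1,
                 indicator: str = "content_proportion",
                 alternate: str = "four_item_no_weight"):
        if not 0.0 <= trim_fraction < 0.5:
            raise ValueError("trim_fraction must lie in [0, 0.5)")
        if len(pairs) < 2:
            raise ValueError("need at least 2 (full, alternate) pairs")
        self.pairs = pairs.reset_index(drop=True)
        self.trim_fraction = trim_fraction
        self.indicator = indicator
        self.alternate = alternate

    def fit(self) -> CrosswalkResults:
        d = self.pairs["difference"].to_numpy(dtype=float)
        se = self.pairs["se"].to_numpy(dtype=float)
        source_ids = self.pairs["source_id"].astype(str).to_numpy()
        n = len(d)
        # never trim below two pairs — the offset needs that many to exist
        n_trim = min(math.ceil(self.trim_fraction * n), n - 2)

        active = np.ones(n, dtype=bool)
        converged = False
        for _ in range(self.MAX_ITER):
            gamma2 = _dersimonian_laird(d[active], se[active])
            w = 1.0 / (se ** 2 + gamma2)
            beta = np.sum(w[active] * d[active]) / np.sum(w[active])
            if n_trim == 0:
                converged = True
                break
            resid = np.abs(d - beta) / np.sqrt(se ** 2 + gamma2)
            # drop the n_trim largest |residuals|; ties -> lowest source_id first
            order = np.lexsort((source_ids, -resid))
            new_active = np.ones(n, dtype=bool)
            new_active[order[:n_trim]] = False
            if np.array_equal(new_active, active):
                converged = True
                break
            active = new_active
        gamma2 = _dersimonian_laird(d[active], se[active])
        w = 1.0 / (se[active] ** 2 + gamma2)
        beta = float(np.sum(w * d[active]) / np.sum(w))
        beta_se = float(1.0 / math.sqrt(np.sum(w)))
        return CrosswalkResults(self.indicator, self.alternate, beta, beta_se,
                                math.sqrt(gamma2), self.trim_fraction,
                                int(active.sum()),
                                INDICATORS[self.indicator].transform,
                                converged=converged)


def fit_crosswalk(pairs: pd.DataFrame, trim_fraction: float = 0.1,
                  indicator: str = "content_proportion",
                  alternate: str = "four_item_no_weight") -> CrosswalkResults:
    """Convenience wrapper: build the model and fit it."""
    return CrosswalkMetaRegression(pairs, trim_fraction, indicator,
                                   alternate).fit()


def apply_crosswalk(estimate: SourceEstimate,
                    model: CrosswalkResults) -> SourceEstimate:
    """Adjust an abbreviated estimate onto the full definition.

    The value is shifted by the fitted offset on the transform scale; the
    transform-scale variance is inflated by the offset's sampling variance
    and the between-source heterogeneity, then mapped back to the natural
    scale by the delta method.
    """
    if estimate.definition == "full" or estimate.definition.startswith("full ("):
        raise ValueError("estimate already uses the full definition")
    if estimate.definition != model.alternate_definition:
        raise ValueError(
            f"estimate definition {estimate.definition!r} does not match "
            f"crosswalk for {model.alternate_definition!r}")
    transform = model.transform
    y = float(transform_value(estimate.value, transform)) + model.beta
    var = (delta_variance(estimate.value, estimate.standard_error, transform)
           + model.beta_se ** 2 + model.gamma ** 2)
    value = float(inverse_transform(y, transform))
    upper = INDICATORS[estimate.indicator].upper
    if upper is not None:
        value = min(value, upper * (1.0 - 1e-9))
    deriv = value * (1.0 - value) if transform == "logit" else value
    se = float(math.sqrt(var) * deriv)
    return replace(estimate, value=value, standard_error=se,
                   definition="full (crosswalked)")
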
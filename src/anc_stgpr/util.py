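"""Small numeric helpers shared across the pipeline."""

from __future__ import annotations

import zlib

import numpy as np
from scipy.special import expit, logit  # noqa: F401  (re-exported)


def substream(master_seed: int, *names: str | int) -> np.random.Generator:
    """Derive an independent, reproducible RNG stream from a master seed.

    Streams are keyed by (stage, indicator, ...) name tuples so that adding
    or removing one indicator never perturbs another's draws.
    """
    key = tuple(zlib.crc32(str(n).encode()) for n in names)
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=key))


def transform_value(x, transform: str):
    x = np.asarray(x, dtype=float)
    if transform == "logit":
        return logit(x)
    if transform == "log":
        return np.log(x)
    raise ValueError(f"unknown transform {transform!r}")


def inverse_transform(y, transform: str):
    y = np.asarray(y, dtype=float)
    if transform == "logit":
        return expit(y)
    if transform == "log":
        return np.exp(y)
    raise ValueError(f"unknown transform {transform!r}")


def delta_variance(value: float, se: float, transform: str) -> float:
    """Sampling variance on the transformed scale by the delta method."""
    if transform == "logit":
        d = value * (1.0 - value)
    elif transform == "log":
        d = value
    else:
        raise ValueError(f"unknown transform {transform!r}")
    if d <= 0:
        raise ValueError("value must be interior to the transform's domain")
    return (se / d) ** 2
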
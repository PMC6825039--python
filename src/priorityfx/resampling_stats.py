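"""Percentile-bootstrap confidence intervals for index group means.

The group mean of per-replicate index values is resampled with
replacement; the CI endpoints are empirical quantiles of the resampled
means (linear interpolation between order statistics).  A group mean is
declared significantly different from zero exactly when its interval does
not contain zero, the closed-interval reading: an endpoint equal to zero
counts as containing it.

Determinism: for a fixed seed the resample index stream is drawn once,
independent of the coverage level, so the 99% interval of a given stream
always contains its 95% interval.  When intervals are produced for many
groups, each group's seed is derived from a single root seed and the group
label, making results invariant to group ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import hashlib

import numpy as np

from priorityfx.errors import (
    ConfigurationError,
    InsufficientDataError,
    InvalidInputError,
)


@dataclass(frozen=True)
class BootstrapConfig:
    n_iterations: int = 1000
    level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")
        if not 0.0 < self.level < 1.0:
            raise ConfigurationError("level must lie in (0, 1)")


def substream_seed(root_seed: int, *labels: object) -> np.random.SeedSequence:
    """Deterministic per-group seed derived from a root seed and labels.

    Hashing the labels (rather than enumerating groups) makes the stream
    independent of the order in which groups are processed.
    """
    digest = hashlib.sha256("/".join(map(str, labels)).encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.SeedSequence([int(root_seed), key])


def bootstrap_percentile_ci(
    values, config: BootstrapConfig = BootstrapConfig()
) -> tuple[float, float]:
    """Percentile bootstrap CI for the mean of ``values``.

    Resamples with replacement ``config.n_iterations`` times, takes the
    mean of each resample, and returns the (1-level)/2 and 1-(1+level)/2
    empirical quantiles.  Bit-reproducible for a given config.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise InvalidInputError("values must be one-dimensional")
    if len(x) < 2:
        raise InsufficientDataError(
            f"bootstrap needs >= 2 values, got {len(x)}"
        )
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("bootstrap values must all be finite")
    rng = np.random.default_rng(config.seed)
    n = len(x)
    idx = rng.integers(0, n, size=(config.n_iterations, n))
    means = x[idx].mean(axis=1)
    alpha = 1.0 - config.level
    low, high = np.quantile(means, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(low), float(high)


def exhaustive_percentile_ci(values, level: float = 0.95) -> tuple[float, float]:
    """Exact percentile interval over *all* n^n resamples.

    Feasible only for very small n; used to pin the Monte-Carlo routine's
    quantile convention against full enumeration.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise InsufficientDataError("need >= 2 values")
    if n ** n > 500_000:
        raise ConfigurationError(f"n = {n} too large to enumerate {n}**{n} resamples")
    if not 0.0 < level < 1.0:
        raise ConfigurationError("level must lie in (0, 1)")
    means = np.array(
        [np.mean(x[list(combo)]) for combo in product(range(n), repeat=n)]
    )
    alpha = 1.0 - level
    low, high = np.quantile(means, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(low), float(high)


def differs_from_zero(ci: tuple[float, float]) -> bool:
    """True iff the closed interval [low, high] excludes zero."""
    low, high = ci
    if low > high:
        raise InvalidInputError(f"invalid interval: low {low} > high {high}")
    return bool(low > 0.0 or high < 0.0)
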
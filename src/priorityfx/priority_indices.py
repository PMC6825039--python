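"""Bounded indices for the benefit of arriving early and the cost of arriving late.

Both indices are built on the relative interaction kernel

    RI(a, b) = (a - b) / (a + b),

which is symmetric around zero, scale invariant, and bounded in [-1, +1] —
properties that log response ratios lack and that make experiments directly
comparable.  Each index contrasts a group's performance under a timed
arrival with its performance under the age-matched synchronous control:

====  ======  ==========================  =====================
kind  origin  treatment                    synchronous control
====  ======  ==========================  =====================
B     E       exotic sown Early            Sync1
B     N       natives with exotic Late     Sync1
P     E       exotic sown Late             Sync2
P     N       natives with exotic Early    Sync2
====  ======  ==========================  =====================

The mapping looks crossed because arrival codes always refer to the exotic
species: when the exotic arrives Late, the *natives* are the early
arrivers, so their benefit B_N contrasts the Late treatment against Sync1.
Negative values denote inhibitory priority effects, positive values
facilitative ones; the magnitude gives the strength.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
import pandas as pd

from priorityfx.core_model import COMPOSITIONS, PerformanceMatrix
from priorityfx.errors import (
    ConfigurationError,
    DomainError,
    InsufficientDataError,
    InvalidInputError,
)

#: (kind, origin) -> (treatment arrival level, synchronous control level)
INDEX_TREATMENTS: dict[tuple[str, str], tuple[str, str]] = {
    ("B", "E"): ("Early", "Sync1"),
    ("B", "N"): ("Late", "Sync1"),
    ("P", "E"): ("Late", "Sync2"),
    ("P", "N"): ("Early", "Sync2"),
}

PAIRING_POLICIES = ("replicate", "random")


def relative_index(y_a, y_b):
    """Relative interaction kernel ``(y_a - y_b) / (y_a + y_b)``.

    Accepts scalars or arrays of non-negative performances.  A pair
    summing to zero carries no information, so it yields NaN (missing),
    never 0 — a zero index must mean "no effect", not "no data".
    """
    a = np.asarray(y_a, dtype=float)
    b = np.asarray(y_b, dtype=float)
    if np.any(a[~np.isnan(a)] < 0) or np.any(b[~np.isnan(b)] < 0):
        raise InvalidInputError("relative_index requires non-negative performances")
    denom = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (a - b) / np.where(denom > 0, denom, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class IndexEstimate:
    """Per-replicate values and summary of one index in one composition."""

    kind: str  # "B" or "P"
    origin: str  # "E" or "N"
    composition: str
    per_replicate: pd.Series  # indexed by replicate; NaN where undefined
    mean: float
    n: int
    ci: tuple[float, float] | None = None

    @property
    def values(self) -> np.ndarray:
        """Non-missing per-replicate index values."""
        return self.per_replicate.dropna().to_numpy()


def compute_priority_indices(
    matrix: PerformanceMatrix,
    kind: str,
    origin: str,
    pairing_policy: str = "replicate",
    seed: int | None = None,
) -> dict[str, IndexEstimate]:
    """Compute one index for every composition in a performance matrix.

    The default pairing policy matches replicate r of the treatment with
    replicate r of its synchronous control — deterministic and independent
    of row order.  ``random`` permutes the control replicates first
    (seeded), for sensitivity analysis of the pairing convention.
    Replicates whose pair is undefined (missing data or a zero-zero pair)
    are dropped from the mean.
    """
    if (kind, origin) not in INDEX_TREATMENTS:
        raise ConfigurationError(f"unknown index ({kind!r}, {origin!r})")
    if pairing_policy not in PAIRING_POLICIES:
        raise ConfigurationError(f"unknown pairing policy {pairing_policy!r}")
    treatment, control = INDEX_TREATMENTS[(kind, origin)]

    out: dict[str, IndexEstimate] = {}
    compositions = [
        c for c in COMPOSITIONS if c in matrix.data["composition"].unique()
    ]
    for comp in compositions:
        y_t = matrix.get(comp, treatment, origin)
        y_c = matrix.get(comp, control, origin)
        if y_t.empty or y_c.empty:
            raise ConfigurationError(
                f"matrix lacks arrival level {treatment!r} or {control!r} "
                f"for origin {origin!r} in composition {comp!r}"
            )
        if pairing_policy == "random":
            rng = np.random.default_rng(seed)
            y_c = pd.Series(
                y_c.to_numpy()[rng.permutation(len(y_c))], index=y_c.index
            )
        paired = pd.concat(
            {"treatment": y_t, "control": y_c}, axis=1, join="outer"
        )
        values = relative_index(
            paired["treatment"].to_numpy(), paired["control"].to_numpy()
        )
        per_rep = pd.Series(values, index=paired.index, name="index")
        n = int(per_rep.notna().sum())
        if n == 0:
            raise InsufficientDataError(
                f"all replicate pairs undefined for {kind}_{origin} in {comp}"
            )
        out[comp] = IndexEstimate(
            kind=kind,
            origin=origin,
            composition=comp,
            per_replicate=per_rep,
            mean=float(per_rep.mean()),
            n=n,
        )
    return out


def compute_all_indices(
    matrix: PerformanceMatrix, pairing_policy: str = "replicate", seed: int | None = None
) -> pd.DataFrame:
    """All four indices for all compositions, as a tidy per-replicate table."""
    rows = []
    for (kind, origin), _ in INDEX_TREATMENTS.items():
        estimates = compute_priority_indices(
            matrix, kind, origin, pairing_policy=pairing_policy, seed=seed
        )
        for comp, est in estimates.items():
            for rep, value in est.per_replicate.items():
                rows.append(
                    {
                        "kind": kind,
                        "origin": origin,
                        "composition": comp,
                        "replicate": rep,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows)


def index_percent_equivalence(b: float) -> float:
    """Percent change g such that ``relative_index(1 + g/100, 1) == b``.

    Links index values to the familiar +x% / -x% language:
    ``g = 100 * 2b / (1 - b)``.  Undefined at b = 1 (infinite change).
    """
    if math.isnan(b):
        return math.nan
    if not -1.0 <= b < 1.0:
        if b == 1.0:
            raise DomainError("index 1 corresponds to an infinite percent change")
        raise DomainError(f"index must lie in [-1, 1), got {b}")
    return 100.0 * 2.0 * b / (1.0 - b)
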
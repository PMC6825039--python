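"""delta-15N natural-abundance computation and nitrogen-facilitation checks.

The natural-abundance method exploits the fact that atmospheric N2 is the
international isotope standard: tissue built from freshly fixed N2 carries
a 15N/14N ratio close to the standard (delta-15N near 0 permil), whereas
tissue built from soil N inherits the usually heavier soil signature.
Three diagnostics follow for a grasses-vs-grasses+legumes experiment:

* **fixation check** — legume shoot delta-15N well below the non-legume
  mean (toward zero) indicates active N2 fixation;
* **N-transfer check** — if fixed N moves belowground to neighbours,
  non-legume shoots should show *lower* delta-15N with legumes present
  (composition GL) than without (G);
* **N-sparing check** — legumes relying on the atmosphere leave soil N to
  neighbours, raising non-legume shoot %N in GL without changing its
  isotope signature.

Each check reports direction, magnitude and a test outcome under the
stated decision rule; no biological verdict is drawn beyond those rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from priorityfx.core_model import PotRecord, records_to_frame
from priorityfx.errors import DomainError
from priorityfx.inferential_stats import anova_fixed_effects

#: Conventional 15N/14N ratio of atmospheric N2 (the delta-15N standard).
R_STANDARD_AIR = 0.0036765

NON_LEGUME_GROUPS = ("exotic", "grass")


def delta15n(r_sample: float, r_standard: float = R_STANDARD_AIR) -> float:
    """Per-mil deviation of a sample 15N/14N ratio from the standard.

    ``delta = (r_sample / r_standard - 1) * 1000``; zero when the sample
    matches atmospheric N2 exactly.
    """
    r_sample = np.asarray(r_sample, dtype=float)
    if np.any(r_sample <= 0) or r_standard <= 0:
        raise DomainError("isotope ratios must be strictly positive")
    out = (r_sample / r_standard - 1.0) * 1000.0
    return float(out) if out.ndim == 0 else out


def invert_delta15n(delta: float, r_standard: float = R_STANDARD_AIR) -> float:
    """Sample ratio recovering a given per-mil value; exact inverse of
    :func:`delta15n`."""
    delta = np.asarray(delta, dtype=float)
    if np.any(delta <= -1000.0):
        raise DomainError("delta-15N must exceed -1000 permil")
    if r_standard <= 0:
        raise DomainError("r_standard must be positive")
    out = r_standard * (1.0 + delta / 1000.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class GroupCheck:
    """Outcome of one directional diagnostic."""

    name: str
    assessable: bool
    direction: str = ""  # e.g. "GL < G"
    magnitude: float = float("nan")  # difference on the measured scale
    percent_lower: float = float("nan")
    statistic: float = float("nan")
    p: float = float("nan")
    consistent: bool | None = None  # with the mechanism, under the rule
    detail: str = ""


@dataclass
class FacilitationReport:
    fixation: GroupCheck
    n_transfer: dict[str, GroupCheck] = field(default_factory=dict)
    n_sparing: dict[str, GroupCheck] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        checks = [self.fixation]
        checks += list(self.n_transfer.values()) + list(self.n_sparing.values())
        return pd.DataFrame(
            [
                {
                    "check": c.name,
                    "assessable": c.assessable,
                    "direction": c.direction,
                    "magnitude": c.magnitude,
                    "percent_lower": c.percent_lower,
                    "statistic": c.statistic,
                    "p": c.p,
                    "consistent": c.consistent,
                    "detail": c.detail,
                }
                for c in checks
            ]
        )


def _composition_contrast(
    frame: pd.DataFrame, group: str, column: str, name: str, lower_is_consistent: bool,
    alpha: float,
) -> GroupCheck:
    sub = frame.loc[(frame["group"] == group) & frame[column].notna()]
    comps = sub["composition"].unique()
    if len(comps) < 2 or sub.groupby("composition")[column].count().min() < 2:
        return GroupCheck(
            name=name,
            assessable=False,
            detail=f"need {column} for group {group!r} in both compositions",
        )
    means = sub.groupby("composition")[column].mean()
    diff = float(means["GL"] - means["G"])
    table, _ = anova_fixed_effects(
        sub.reset_index(drop=True), column, "composition"
    )
    row = table["composition"]
    lower = diff < 0
    consistent = (lower == lower_is_consistent) and row.p < alpha
    return GroupCheck(
        name=name,
        assessable=True,
        direction="GL < G" if lower else ("GL > G" if diff > 0 else "GL = G"),
        magnitude=diff,
        percent_lower=float(-diff / means["G"] * 100.0) if means["G"] != 0 else np.nan,
        statistic=row.F,
        p=row.p,
        consistent=bool(consistent),
        detail=(
            f"F_{row.df_num},{row.df_den} = {row.F:.3g}, p = {row.p:.3g}; "
            f"mean GL = {means['GL']:.3g}, mean G = {means['G']:.3g}"
        ),
    )


def nitrogen_facilitation_contrasts(
    records: Iterable[PotRecord] | pd.DataFrame, alpha: float = 0.05
) -> FacilitationReport:
    """Run the fixation, N-transfer and N-sparing diagnostics.

    Group means pool all arrival treatments within a species group.  A
    missing measurement set renders a check not-assessable rather than
    raising.
    """
    frame = records_to_frame(records)

    leg = frame.loc[(frame["group"] == "legume") & frame["delta15n"].notna()]
    nonleg = frame.loc[
        frame["group"].isin(NON_LEGUME_GROUPS) & frame["delta15n"].notna()
    ]
    if leg.empty or nonleg.empty:
        fixation = GroupCheck(
            name="fixation",
            assessable=False,
            detail="need legume and non-legume delta15n measurements",
        )
    else:
        m_leg = float(leg["delta15n"].mean())
        m_non = float(nonleg["delta15n"].mean())
        fixation = GroupCheck(
            name="fixation",
            assessable=True,
            direction="legume < non-legume" if m_leg < m_non else "legume >= non-legume",
            magnitude=m_leg - m_non,
            percent_lower=(
                float((1.0 - m_leg / m_non) * 100.0) if m_non != 0 else np.nan
            ),
            statistic=np.nan,
            p=np.nan,
            consistent=bool(m_leg < m_non),
            detail=(
                f"legume mean delta15n = {m_leg:.3g} permil "
                f"(distance from 0: {abs(m_leg):.3g}), "
                f"non-legume mean = {m_non:.3g} permil"
            ),
        )

    transfer = {
        g: _composition_contrast(
            frame, g, "delta15n", f"n_transfer[{g}]",
            lower_is_consistent=True, alpha=alpha,
        )
        for g in NON_LEGUME_GROUPS
    }
    sparing = {
        g: _composition_contrast(
            frame, g, "n_percent", f"n_sparing[{g}]",
            lower_is_consistent=False, alpha=alpha,
        )
        for g in NON_LEGUME_GROUPS
    }
    return FacilitationReport(
        fixation=fixation, n_transfer=transfer, n_sparing=sparing
    )
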
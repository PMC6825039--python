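"""Domain types for the factorial timed-arrival design.

The experimental template is a full factorial greenhouse design: an exotic
focal species is sown into a native community that is either grasses only
(``G``) or grasses plus legumes (``GL``), at one of four arrival
treatments, with five replicate pots per cell.  Arrival codes always refer
to the timing of the *exotic* species:

``Early``
    exotic sown at the first sowing event, natives at the second;
``Late``
    natives sown first, exotic at the second event;
``Sync1`` / ``Sync2``
    everything sown together at the first / second event.  The two
    synchronous controls exist so that early- and late-sown plants can be
    compared with plants of exactly the same age at harvest.

Raw measurements arrive as one row per (pot, species group); this module
validates the design and aggregates the rows into analysis-ready
performance matrices, including the native-origin totals obtained by
summing grass and legume values within a pot.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Mapping, Sequence

import math

import numpy as np
import pandas as pd

from priorityfx.errors import (
    InvalidInputError,
    ParseError,
    UndefinedReferenceError,
)

ARRIVAL_LEVELS: tuple[str, ...] = ("Early", "Late", "Sync1", "Sync2")
COMPOSITIONS: tuple[str, ...] = ("G", "GL")
SPECIES_GROUPS: tuple[str, ...] = ("exotic", "grass", "legume")
#: Origin codes: E = exotic focal species, N = native community (grass+legume).
ORIGINS: tuple[str, ...] = ("E", "N")

NATIVE_GROUPS: tuple[str, ...] = ("grass", "legume")

#: Replicates per treatment cell in the reference design.
DEFAULT_N_REPLICATES = 5

RESPONSE_NAMES: tuple[str, ...] = ("shoot_dry_weight", "shoot_n_content")


@dataclass(frozen=True)
class PotRecord:
    """One measured species group in one pot.

    ``shoot_dry_weight`` is in grams; ``n_percent`` / ``c_percent`` are
    percentages of dry mass; ``delta15n`` is per mil relative to
    atmospheric N2.  Optional measurements default to ``None`` (missing).
    """

    pot_id: str
    composition: str
    arrival: str
    replicate: int
    group: str
    shoot_dry_weight: float
    n_percent: float | None = None
    c_percent: float | None = None
    delta15n: float | None = None
    n_individuals: int | None = None

    def __post_init__(self) -> None:
        if self.composition not in COMPOSITIONS:
            raise ParseError(
                f"pot {self.pot_id!r}: unknown composition code "
                f"{self.composition!r}; expected one of {COMPOSITIONS}"
            )
        if self.arrival not in ARRIVAL_LEVELS:
            raise ParseError(
                f"pot {self.pot_id!r}: unknown arrival code "
                f"{self.arrival!r}; expected one of {ARRIVAL_LEVELS}"
            )
        if self.group not in SPECIES_GROUPS:
            raise ParseError(
                f"pot {self.pot_id!r}: unknown species group "
                f"{self.group!r}; expected one of {SPECIES_GROUPS}"
            )
        if not (self.shoot_dry_weight >= 0 or _is_missing(self.shoot_dry_weight)):
            raise InvalidInputError(
                f"pot {self.pot_id!r}: shoot_dry_weight must be >= 0, "
                f"got {self.shoot_dry_weight}"
            )
        for name in ("n_percent", "c_percent"):
            value = getattr(self, name)
            if value is not None and not _is_missing(value):
                if not 0.0 <= value <= 100.0:
                    raise InvalidInputError(
                        f"pot {self.pot_id!r}: {name} must lie in [0, 100], "
                        f"got {value}"
                    )
        if (
            self.n_percent is not None
            and self.c_percent is not None
            and not _is_missing(self.n_percent)
            and not _is_missing(self.c_percent)
            and self.n_percent + self.c_percent > 100.0 + 1e-9
        ):
            raise InvalidInputError(
                f"pot {self.pot_id!r}: n_percent + c_percent exceeds 100%"
            )
        if self.n_individuals is not None and self.n_individuals < 0:
            raise InvalidInputError(
                f"pot {self.pot_id!r}: n_individuals must be >= 0"
            )


def _is_missing(value: object) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


RECORD_COLUMNS = [f.name for f in dc_fields(PotRecord)]


def records_to_frame(records: Iterable[PotRecord] | pd.DataFrame) -> pd.DataFrame:
    """Return a tidy DataFrame with one row per (pot, species group)."""
    if isinstance(records, pd.DataFrame):
        missing = [c for c in RECORD_COLUMNS[:6] if c not in records.columns]
        if missing:
            raise InvalidInputError(f"record table lacks columns {missing}")
        out = records.copy()
        for col in RECORD_COLUMNS:
            if col not in out.columns:
                out[col] = np.nan
        return out[RECORD_COLUMNS]
    rows = [{f: getattr(r, f) for f in RECORD_COLUMNS} for r in records]
    if not rows:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[PotRecord]:
    """Materialize typed :class:`PotRecord` objects from a tidy frame."""
    records = []
    for _, row in frame.iterrows():
        kwargs = {}
        for f in RECORD_COLUMNS:
            value = row.get(f)
            if f in ("n_percent", "c_percent", "delta15n") and _is_missing(value):
                value = None
            if f == "n_individuals":
                value = None if _is_missing(value) else int(value)
            if f == "replicate":
                value = int(value)
            kwargs[f] = value
        records.append(PotRecord(**kwargs))
    return records


@dataclass
class DesignReport:
    """Outcome of :func:`validate_design`.

    ``cell_counts`` maps (composition, arrival) to the number of replicate
    pots observed; ``flags`` holds human-readable descriptions of every
    deviation from the reference design.
    """

    n_pots: int
    cell_counts: dict[tuple[str, str], int]
    flags: list[str] = field(default_factory=list)
    expected_replicates: int = DEFAULT_N_REPLICATES

    @property
    def ok(self) -> bool:
        return not self.flags

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [f"{self.n_pots} pots across {len(self.cell_counts)} cells"]
        for (comp, arr), n in sorted(self.cell_counts.items()):
            lines.append(f"  {comp:>2} x {arr:<5}: n = {n}")
        lines.extend(f"  FLAG: {f}" for f in self.flags)
        return "\n".join(lines)


def validate_design(
    records: Iterable[PotRecord] | pd.DataFrame,
    expected_replicates: int = DEFAULT_N_REPLICATES,
) -> DesignReport:
    """Check a record collection against the full-factorial template.

    Reports replicate counts per (composition, arrival) cell and flags:
    cells whose pot count differs from ``expected_replicates``, legume
    rows inside grasses-only (``G``) communities, and duplicated
    (pot_id, species group) rows.  The input is never mutated.
    """
    frame = records_to_frame(records)
    if frame.empty:
        raise InvalidInputError("validate_design: empty record collection")
    for col, levels in (
        ("composition", COMPOSITIONS),
        ("arrival", ARRIVAL_LEVELS),
        ("group", SPECIES_GROUPS),
    ):
        bad = frame.loc[~frame[col].isin(levels)]
        if not bad.empty:
            row = bad.index[0]
            raise ParseError(
                f"row {row}: illegal {col} code {bad[col].iloc[0]!r}; "
                f"expected one of {levels}"
            )

    flags: list[str] = []

    dup = frame.duplicated(subset=["pot_id", "group"], keep=False)
    if dup.any():
        for pot_id, group in (
            frame.loc[dup, ["pot_id", "group"]].drop_duplicates().itertuples(index=False)
        ):
            flags.append(f"duplicate record for pot {pot_id!r}, group {group!r}")

    legume_in_g = frame.loc[
        (frame["composition"] == "G") & (frame["group"] == "legume")
    ]
    for pot_id in legume_in_g["pot_id"].unique():
        flags.append(
            f"pot {pot_id!r}: legume record inside grasses-only composition G"
        )

    pots = frame.drop_duplicates(subset=["pot_id"])[
        ["pot_id", "composition", "arrival"]
    ]
    counts = (
        pots.groupby(["composition", "arrival"], sort=True)["pot_id"]
        .nunique()
        .to_dict()
    )
    cell_counts = {
        (comp, arr): counts.get((comp, arr), 0)
        for comp in COMPOSITIONS
        for arr in ARRIVAL_LEVELS
    }
    for (comp, arr), n in cell_counts.items():
        if n != expected_replicates:
            flags.append(
                f"cell ({comp}, {arr}): {n} replicates, "
                f"expected {expected_replicates}"
            )

    return DesignReport(
        n_pots=int(pots["pot_id"].nunique()),
        cell_counts=cell_counts,
        flags=flags,
        expected_replicates=expected_replicates,
    )


@dataclass
class PerformanceMatrix:
    """A response Y indexed by (composition, arrival, replicate, unit).

    ``unit`` is either a species group (``exotic``/``grass``/``legume``)
    or an origin (``E``/``N``); native-origin values are the within-pot sum
    of grass and legume values.  Missing measurements propagate as NaN.
    """

    response_name: str
    data: pd.DataFrame  # columns: composition, arrival, replicate, unit, value

    def get(self, composition: str, arrival: str, unit: str) -> pd.Series:
        """Values for one treatment cell, indexed by replicate."""
        sub = self.data.loc[
            (self.data["composition"] == composition)
            & (self.data["arrival"] == arrival)
            & (self.data["unit"] == unit)
        ]
        return sub.set_index("replicate")["value"].sort_index()

    def units(self) -> list[str]:
        return sorted(self.data["unit"].unique())


def aggregate_performance(
    records: Iterable[PotRecord] | pd.DataFrame,
    response_name: str = "shoot_dry_weight",
) -> PerformanceMatrix:
    """Assemble the response matrix Y from raw pot records.

    ``shoot_dry_weight`` uses the measured biomass directly;
    ``shoot_n_content`` is the per-pot nitrogen mass
    ``shoot_dry_weight * n_percent / 100`` (grams).  Origin totals are
    added: ``E`` equals the exotic group, ``N`` is grass + legume where
    legumes exist and grass alone otherwise.  Missing inputs yield missing
    Y values.
    """
    if response_name not in RESPONSE_NAMES:
        raise InvalidInputError(
            f"unknown response {response_name!r}; expected one of {RESPONSE_NAMES}"
        )
    frame = records_to_frame(records)
    if frame.empty:
        raise InvalidInputError("aggregate_performance: empty record collection")

    if response_name == "shoot_dry_weight":
        value = frame["shoot_dry_weight"].astype(float)
    else:
        value = frame["shoot_dry_weight"].astype(float) * (
            frame["n_percent"].astype(float) / 100.0
        )

    tidy = frame[["composition", "arrival", "replicate", "group"]].copy()
    tidy["unit"] = tidy.pop("group")
    tidy["value"] = value.to_numpy()

    rows = [tidy]

    exotic = tidy.loc[tidy["unit"] == "exotic"].copy()
    exotic["unit"] = "E"
    rows.append(exotic)

    native = tidy.loc[tidy["unit"].isin(NATIVE_GROUPS)].copy()
    if not native.empty:
        # a missing grass or legume measurement poisons the native total
        native_tot = (
            native.groupby(["composition", "arrival", "replicate"], sort=False)[
                "value"
            ]
            .agg(lambda s: s.sum() if not s.isna().any() else np.nan)
            .reset_index()
        )
        native_tot["unit"] = "N"
        rows.append(native_tot[["composition", "arrival", "replicate", "unit", "value"]])

    data = pd.concat(rows, ignore_index=True)
    neg = data["value"] < 0
    if neg.any():
        raise InvalidInputError("negative response value encountered")
    return PerformanceMatrix(response_name=response_name, data=data)


def percent_change(treatment_mean: float, reference_mean: float) -> float:
    """Signed percent difference of a treatment mean from its reference.

    The reference is always the age-matched synchronous treatment mean
    (Sync1 for early-arrival comparisons, Sync2 for late-arrival ones).
    """
    if not reference_mean > 0:
        raise UndefinedReferenceError(
            f"percent_change needs a positive reference mean, got {reference_mean}"
        )
    return (treatment_mean - reference_mean) / reference_mean * 100.0
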
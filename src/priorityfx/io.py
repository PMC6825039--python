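"""CSV readers/writers, run configuration and the end-to-end pipeline.

The canonical on-disk format is a tidy UTF-8 CSV with one row per
(pot, species group): required columns ``pot_id, composition, arrival,
replicate, species_group, shoot_dry_weight``; optional ``n_percent,
c_percent, delta15n, r_sample, n_individuals``.  ``r_sample`` (a raw
15N/14N ratio) is converted to ``delta15n`` on read when the latter is
absent.

:func:`run_full_analysis` orchestrates the whole pipeline — design
validation, priority indices with bootstrap CIs, percent-change
summaries, index ANOVA with post-hoc contrasts, Gamma GLMs on biomass,
and the nitrogen diagnostics — and writes a JSON manifest (package and
library versions, seeds, config hash, product list) sufficient to rerun
the analysis bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import priorityfx
from priorityfx.core_model import (
    ARRIVAL_LEVELS,
    COMPOSITIONS,
    SPECIES_GROUPS,
    records_to_frame,
    validate_design,
    aggregate_performance,
    percent_change,
)
from priorityfx.errors import ConfigurationError, ParseError, SchemaError
from priorityfx.inferential_stats import (
    anova_fixed_effects,
    covariate_model_comparison,
    gamma_glm_analysis,
    pearson_correlation,
    tukey_single_step,
)
from priorityfx.isotopes import R_STANDARD_AIR, delta15n, nitrogen_facilitation_contrasts
from priorityfx.priority_indices import (
    INDEX_TREATMENTS,
    compute_all_indices,
    index_percent_equivalence,
)
from priorityfx.resampling_stats import (
    BootstrapConfig,
    bootstrap_percentile_ci,
    differs_from_zero,
    substream_seed,
)

REQUIRED_COLUMNS = [
    "pot_id",
    "composition",
    "arrival",
    "replicate",
    "species_group",
    "shoot_dry_weight",
]
OPTIONAL_COLUMNS = ["n_percent", "c_percent", "delta15n", "r_sample", "n_individuals"]


def read_experiment_csv(
    path: str | Path, r_standard: float = R_STANDARD_AIR
) -> pd.DataFrame:
    """Read a tidy experiment CSV into the internal record frame.

    Errors name the offending column or data row (1-based, excluding the
    header).  When ``delta15n`` is absent but ``r_sample`` is present the
    per-mil value is derived from the ratio.
    """
    frame = pd.read_csv(path, dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    out = pd.DataFrame()
    out["pot_id"] = frame["pot_id"].astype(str)
    for col, levels in (
        ("composition", COMPOSITIONS),
        ("arrival", ARRIVAL_LEVELS),
        ("species_group", SPECIES_GROUPS),
    ):
        values = frame[col].astype(str)
        bad = ~values.isin(levels)
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 1
            raise ParseError(
                f"{path}: row {row}: illegal {col} value {values[bad.idxmax()]!r}; "
                f"expected one of {levels}"
            )
        out[col] = values
    out = out.rename(columns={"species_group": "group"})

    def numeric(col: str, required: bool = False) -> pd.Series:
        if col not in frame.columns:
            return pd.Series(np.nan, index=frame.index)
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna() & (frame[col].str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 1
            raise ParseError(
                f"{path}: row {row}: cannot parse {col} value "
                f"{frame[col][bad.idxmax()]!r} as a number"
            )
        if required and converted.isna().any():
            row = int(np.flatnonzero(converted.isna())[0]) + 1
            raise ParseError(f"{path}: row {row}: missing required {col}")
        return converted

    out["replicate"] = numeric("replicate", required=True).astype(int)
    out["shoot_dry_weight"] = numeric("shoot_dry_weight", required=True)
    for col in ("n_percent", "c_percent", "delta15n", "n_individuals"):
        out[col] = numeric(col)
    if out["delta15n"].isna().all() and "r_sample" in frame.columns:
        ratios = numeric("r_sample")
        with_ratio = ratios.notna()
        if with_ratio.any():
            out.loc[with_ratio, "delta15n"] = delta15n(
                ratios[with_ratio].to_numpy(), r_standard
            )
    return records_to_frame(out)


def write_experiment_csv(records, path: str | Path) -> None:
    """Write records in the canonical tidy dialect (lossless round trip)."""
    frame = records_to_frame(records).rename(columns={"group": "species_group"})
    frame.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Everything needed to rerun an analysis bit-identically."""

    input_path: str | Path | None = None  # None -> synthetic preset
    out_dir: str | Path = "priorityfx_out"
    response: str = "shoot_dry_weight"
    alpha: float = 0.05
    seed: int = 0
    bootstrap_iterations: int = 1000
    bootstrap_level: float = 0.95
    glm_tol: float = 1e-8
    glm_max_iter: int = 100
    posthoc_draws: int = 100_000
    isotope_r_standard: float = R_STANDARD_AIR
    pairing_policy: str = "replicate"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0.0 < self.bootstrap_level < 1.0:
            raise ConfigurationError("bootstrap_level must lie in (0, 1)")
        if self.bootstrap_iterations < 1 or self.posthoc_draws < 1:
            raise ConfigurationError("iteration counts must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["input_path"] = str(d["input_path"]) if d["input_path"] else None
        d["out_dir"] = str(d["out_dir"])
        return d


def summarize_indices(
    tidy: pd.DataFrame, config: RunConfig
) -> pd.DataFrame:
    """Group means of per-replicate index values with bootstrap CIs.

    One row per (kind, origin, composition): mean, percentile-bootstrap
    interval, the include-zero significance verdict, and the
    percent-change equivalent of the mean index.
    """
    rows = []
    for (kind, origin, comp), sub in tidy.groupby(["kind", "origin", "composition"]):
        values = sub["value"].dropna().to_numpy()
        mean = float(values.mean())
        ss = substream_seed(config.seed, "bootstrap", kind, origin, comp)
        lo, hi = bootstrap_percentile_ci(
            values,
            BootstrapConfig(
                n_iterations=config.bootstrap_iterations,
                level=config.bootstrap_level,
                seed=int(ss.generate_state(1)[0] % (2**31)),
            ),
        )
        rows.append(
            {
                "kind": kind,
                "origin": origin,
                "composition": comp,
                "mean": mean,
                "ci_low": lo,
                "ci_high": hi,
                "n": len(values),
                "differs_from_zero": differs_from_zero((lo, hi)),
                "percent_equivalent": (
                    index_percent_equivalence(mean) if mean < 1 else np.inf
                ),
            }
        )
    return pd.DataFrame(rows)


def _percent_change_table(matrix) -> pd.DataFrame:
    """Group-mean percent changes against the age-matched synchronous control."""
    rows = []
    for (kind, origin), (treatment, control) in INDEX_TREATMENTS.items():
        units = (
            ["E"] if origin == "E" else ["N", "grass", "legume"]
        )
        for comp in COMPOSITIONS:
            for unit in units:
                y_t = matrix.get(comp, treatment, unit)
                y_c = matrix.get(comp, control, unit)
                if y_t.dropna().empty or y_c.dropna().empty:
                    continue
                ref = float(y_c.mean())
                if not ref > 0:
                    continue
                rows.append(
                    {
                        "kind": kind,
                        "unit": unit,
                        "composition": comp,
                        "treatment": treatment,
                        "control": control,
                        "treatment_mean": float(y_t.mean()),
                        "control_mean": ref,
                        "percent_change": percent_change(float(y_t.mean()), ref),
                    }
                )
    return pd.DataFrame(rows)


def _index_anova(tidy: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Two-way origin x composition ANOVA per index kind, with post-hoc
    composition-within-origin contrasts (single-step adjusted)."""
    rows = []
    for kind, sub in tidy.groupby("kind"):
        data = sub.dropna(subset=["value"]).reset_index(drop=True)
        table, fit = anova_fixed_effects(
            data, "value", "origin", "composition", interaction=True
        )
        for r in table.rows:
            rows.append(
                {
                    "kind": kind,
                    "term": r.term,
                    "df_num": r.df_num,
                    "df_den": r.df_den,
                    "statistic": r.F,
                    "statistic_kind": "F",
                    "p": r.p,
                    "p_adjusted": np.nan,
                }
            )
        design = fit.design
        contrasts = []
        labels = []
        for origin in sorted(data["origin"].unique()):
            row_gl = design.row({"origin": origin, "composition": "GL"})
            row_g = design.row({"origin": origin, "composition": "G"})
            contrasts.append(row_gl - row_g)
            labels.append(f"{kind}: GL - G | origin {origin}")
        ss = substream_seed(config.seed, "posthoc", kind)
        results = tukey_single_step(
            fit,
            np.array(contrasts),
            labels=labels,
            n_draws=config.posthoc_draws,
            seed=int(ss.generate_state(1)[0] % (2**31)),
        )
        for res in results:
            rows.append(
                {
                    "kind": kind,
                    "term": res.label,
                    "df_num": 1,
                    "df_den": fit.df_resid,
                    "statistic": res.statistic,
                    "statistic_kind": res.statistic_kind,
                    "p": res.p_raw,
                    "p_adjusted": res.p_adjusted,
                }
            )
    return pd.DataFrame(rows)


def _biomass_glms(frame: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Gamma GLM analyses of deviance on biomass, per species group."""
    rows = []
    for group, factors in (
        ("exotic", ("arrival", "composition")),
        ("grass", ("arrival", "composition")),
        ("legume", ("arrival", None)),
    ):
        data = frame.loc[
            (frame["group"] == group) & (frame["shoot_dry_weight"] > 0)
        ].reset_index(drop=True)
        if data.empty or data["arrival"].nunique() < 2:
            continue
        table, _ = gamma_glm_analysis(
            data, "shoot_dry_weight", factors[0], factors[1], alpha=config.alpha
        )
        for r in table.rows:
            rows.append(
                {
                    "group": group,
                    "term": r.term,
                    "df_num": r.df_num,
                    "df_den": r.df_den,
                    "F": r.F,
                    "p": r.p,
                    "notes": "; ".join(table.notes),
                }
            )
    return pd.DataFrame(rows)


def _covariate_report(frame: pd.DataFrame, config: RunConfig) -> dict:
    """Does the number of established exotic individuals improve the model?"""
    data = frame.loc[
        (frame["group"] == "exotic")
        & (frame["shoot_dry_weight"] > 0)
        & frame["n_individuals"].notna()
    ].reset_index(drop=True)
    if len(data) < 8 or data["n_individuals"].nunique() < 2:
        return {"assessable": False}
    comparison = covariate_model_comparison(
        data,
        "shoot_dry_weight",
        ["arrival", "composition"],
        "n_individuals",
        alpha=config.alpha,
    )
    r, p = pearson_correlation(
        data["n_individuals"].to_numpy(), data["shoot_dry_weight"].to_numpy()
    )
    return {
        "assessable": True,
        "covariate": "n_individuals",
        "F": comparison.f_row.F,
        "df": [comparison.f_row.df_num, comparison.f_row.df_den],
        "p": comparison.f_row.p,
        "delta_aic": comparison.delta_aic,
        "retained": comparison.retained,
        "correlation_r": r,
        "correlation_p": p,
    }


def run_full_analysis(config: RunConfig, records: pd.DataFrame | None = None) -> dict:
    """Run the whole pipeline and write all products plus a manifest.

    ``records`` overrides ``config.input_path``; with neither given, the
    built-in synthetic preset is generated from the run seed.  Returns the
    manifest dictionary.
    """
    from priorityfx.synthetic_data import generate_experiment, paper_like_spec

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if records is None:
        if config.input_path is not None:
            frame = read_experiment_csv(
                config.input_path, r_standard=config.isotope_r_standard
            )
            source = str(config.input_path)
        else:
            frame = generate_experiment(paper_like_spec(), seed=config.seed)
            source = "synthetic:paper_like_spec"
    else:
        frame = records_to_frame(records)
        source = "in-memory records"

    report = validate_design(frame)
    matrix = aggregate_performance(frame, config.response)
    tidy = compute_all_indices(matrix, pairing_policy=config.pairing_policy,
                               seed=config.seed)
    summary = summarize_indices(tidy, config)
    pct = _percent_change_table(matrix)
    anova = _index_anova(tidy, config)
    glms = _biomass_glms(frame, config)
    covariate = _covariate_report(frame, config)
    isotope = nitrogen_facilitation_contrasts(frame, alpha=config.alpha).to_frame()

    products = {
        "indices.csv": tidy,
        "index_summary.csv": summary,
        "percent_change.csv": pct,
        "index_anova.csv": anova,
        "glm_biomass.csv": glms,
        "isotope_report.csv": isotope,
    }
    for name, df in products.items():
        df.to_csv(out_dir / name, index=False)

    config_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "package": "priorityfx",
        "version": priorityfx.__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "source": source,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "design": {
            "n_pots": report.n_pots,
            "flags": report.flags,
        },
        "covariate_comparison": covariate,
        "products": sorted(products),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
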
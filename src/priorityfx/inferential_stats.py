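"""Gamma log-link GLMs, fixed-effects ANOVA and single-step adjusted contrasts.

The model mathematics is implemented directly rather than delegated:

* **Gamma GLM, log link** — fitted by iteratively reweighted least squares
  (IRLS).  For the log link the working weights are identically one, so
  each iteration is an ordinary least-squares solve on the working
  response ``eta + (y - mu)/mu``.  The dispersion is estimated from the
  Pearson statistic; term tests use deviance-based F statistics, the
  standard quasi-likelihood analysis of deviance.
* **ANOVA** — least-squares decompositions with Type-II sums of squares
  (each term tested against the model containing all other terms at the
  same or lower order), the appropriate choice when one cell loses a
  replicate and the design becomes unbalanced.  Type II reduces to the
  classical balanced-design decomposition when the design is balanced.
* **Post-hoc contrasts** — simultaneous general linear hypotheses with
  single-step adjusted p-values: the adjusted p of a contrast is the
  probability that the maximum absolute component of a multivariate t
  (or normal, for GLM z statistics) with the contrasts' correlation
  matrix exceeds the observed statistic, evaluated by seeded Monte Carlo.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats, special, optimize

from priorityfx.errors import (
    AliasingError,
    ConfigurationError,
    DomainError,
    InvalidInputError,
)


# ---------------------------------------------------------------------------
# design matrices


@dataclass
class DesignInfo:
    """Treatment-coded design matrix with enough metadata to build contrasts."""

    matrix: np.ndarray
    labels: list[str]
    factors: dict[str, list[str]]  # factor name -> ordered levels
    covariates: list[str] = field(default_factory=list)
    interaction: tuple[str, str] | None = None

    def row(self, assignment: dict[str, object]) -> np.ndarray:
        """X-row for one combination of factor levels (covariates at 0)."""
        row = np.zeros(len(self.labels))
        row[0] = 1.0
        for j, label in enumerate(self.labels[1:], start=1):
            if ":" in label:
                parts = label.split(":")
                row[j] = float(all(self._indicator(p, assignment) for p in parts))
            elif "[" in label:
                row[j] = float(self._indicator(label, assignment))
            else:  # covariate
                row[j] = float(assignment.get(label, 0.0))
        return row

    @staticmethod
    def _indicator(term: str, assignment: dict[str, object]) -> bool:
        name, level = term[:-1].split("[")
        return assignment.get(name) == level


def design_matrix(
    data: pd.DataFrame,
    factors: Sequence[str] = (),
    covariates: Sequence[str] = (),
    interaction: bool = False,
) -> DesignInfo:
    """Build a full-rank treatment-coded (first level = reference) design.

    ``interaction=True`` adds the product terms of the first two factors.
    """
    n = len(data)
    cols = [np.ones(n)]
    labels = ["Intercept"]
    level_map: dict[str, list[str]] = {}
    for f in factors:
        levels = sorted(map(str, pd.unique(data[f].astype(str))))
        level_map[f] = levels
        for lev in levels[1:]:
            cols.append((data[f].astype(str) == lev).to_numpy(float))
            labels.append(f"{f}[{lev}]")
    if interaction:
        if len(factors) < 2:
            raise ConfigurationError("interaction requires two factors")
        fa, fb = factors[0], factors[1]
        for la in level_map[fa][1:]:
            for lb in level_map[fb][1:]:
                cols.append(
                    (data[fa].astype(str) == la).to_numpy(float)
                    * (data[fb].astype(str) == lb).to_numpy(float)
                )
                labels.append(f"{fa}[{la}]:{fb}[{lb}]")
    for c in covariates:
        cols.append(data[c].to_numpy(float))
        labels.append(c)
    X = np.column_stack(cols)
    _check_rank(X, labels)
    return DesignInfo(
        matrix=X,
        labels=labels,
        factors=level_map,
        covariates=list(covariates),
        interaction=(factors[0], factors[1]) if interaction else None,
    )


def _check_rank(X: np.ndarray, labels: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the first column adding no rank
        for j in range(1, X.shape[1] + 1):
            if np.linalg.matrix_rank(X[:, :j]) < j:
                raise AliasingError(
                    f"design is rank deficient: column {labels[j - 1]!r} is "
                    "aliased with earlier columns"
                )
        raise AliasingError("design is rank deficient")


# ---------------------------------------------------------------------------
# Gamma GLM by IRLS


@dataclass
class GammaGLMFit:
    """Gamma log-link fit: coefficients on the log scale, Pearson dispersion."""

    coefficients: np.ndarray
    cov_params: np.ndarray
    dispersion: float
    deviance: float
    df_resid: int
    iterations: int
    converged: bool
    labels: list[str]
    fitted: np.ndarray
    y: np.ndarray
    X: np.ndarray
    design: DesignInfo | None = None

    @property
    def n_params(self) -> int:
        return len(self.coefficients)

    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))


def _gamma_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    return float(2.0 * np.sum((y - mu) / mu - np.log(y / mu)))


def fit_gamma_glm(
    X: np.ndarray | DesignInfo,
    y,
    labels: Sequence[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GammaGLMFit:
    """Fit a Gamma GLM with log link by IRLS.

    Starts from the least-squares regression of log(y); iterates working
    least squares with step-halving whenever a step would increase the
    deviance; converges when the relative deviance change drops below
    ``tol``.  Dispersion is the Pearson statistic over the residual
    degrees of freedom.
    """
    design = None
    if isinstance(X, DesignInfo):
        design = X
        labels = X.labels
        X = X.matrix
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise InvalidInputError("X must be (n, p) with len(y) == n")
    if np.any(y <= 0):
        raise DomainError("Gamma GLM requires strictly positive responses")
    if labels is None:
        labels = [f"x{j}" for j in range(X.shape[1])]
    _check_rank(X, labels)

    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, np.log(y), rcond=None)
    eta = X @ beta
    mu = np.exp(eta)
    dev = _gamma_deviance(y, mu)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        z = eta + (y - mu) / mu  # working response; working weights are 1
        beta_new, *_ = np.linalg.lstsq(X, z, rcond=None)
        step = 1.0
        for _ in range(40):  # step-halving keeps the deviance non-increasing
            cand = beta + step * (beta_new - beta)
            eta_c = X @ cand
            mu_c = np.exp(eta_c)
            dev_c = _gamma_deviance(y, mu_c)
            if np.isfinite(dev_c) and dev_c <= dev + 1e-14 * (1 + abs(dev)):
                break
            step /= 2.0
        beta, eta, mu = cand, eta_c, mu_c
        rel = abs(dev - dev_c) / (abs(dev) + 0.1)
        dev = dev_c
        if rel < tol:
            converged = True
            break

    df_resid = n - p
    pearson = float(np.sum(((y - mu) / mu) ** 2))
    dispersion = pearson / df_resid if df_resid > 0 else np.nan
    xtx_inv = np.linalg.inv(X.T @ X)
    cov = dispersion * xtx_inv if df_resid > 0 else np.full((p, p), np.nan)
    return GammaGLMFit(
        coefficients=beta,
        cov_params=cov,
        dispersion=dispersion,
        deviance=dev,
        df_resid=df_resid,
        iterations=it,
        converged=converged,
        labels=list(labels),
        fitted=mu,
        y=y,
        X=X,
        design=design,
    )


# ---------------------------------------------------------------------------
# analysis-of-deviance / ANOVA tables


@dataclass
class AnovaRow:
    term: str
    df_num: int
    df_den: int
    F: float
    p: float


@dataclass
class AnovaTable:
    rows: list[AnovaRow]
    notes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"term": r.term, "df_num": r.df_num, "df_den": r.df_den,
                 "F": r.F, "p": r.p}
                for r in self.rows
            ]
        )

    def __getitem__(self, term: str) -> AnovaRow:
        for r in self.rows:
            if r.term == term:
                return r
        raise KeyError(term)


def glm_term_tests(
    full: GammaGLMFit, reduced: GammaGLMFit, term: str = "term"
) -> AnovaRow:
    """Deviance-based F test of a reduced model nested in a full model.

    F = (D_reduced - D_full) / (ddf * dispersion_full) on
    (ddf, df_resid_full) degrees of freedom.  Also drives the
    interaction-dropping rule at the analysis alpha.
    """
    if full.y.shape != reduced.y.shape or not np.allclose(full.y, reduced.y):
        raise InvalidInputError("models must be fitted to the same response")
    ddf = reduced.df_resid - full.df_resid
    if ddf < 0:
        raise InvalidInputError("reduced model must be nested in the full model")
    if ddf == 0:
        return AnovaRow(term, 0, full.df_resid, 0.0, 1.0)
    ddev = max(reduced.deviance - full.deviance, 0.0)
    F = ddev / (ddf * full.dispersion)
    p = float(stats.f.sf(F, ddf, full.df_resid))
    return AnovaRow(term, ddf, full.df_resid, float(F), p)


@dataclass
class OLSFit:
    """Least-squares fit retained for contrast construction."""

    coefficients: np.ndarray
    cov_params: np.ndarray
    sigma2: float
    df_resid: int
    labels: list[str]
    design: DesignInfo | None = None


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), X.shape[0] - np.linalg.matrix_rank(X)


def anova_fixed_effects(
    data: pd.DataFrame,
    response: str,
    factor_a: str,
    factor_b: str | None = None,
    interaction: bool = True,
) -> tuple[AnovaTable, OLSFit]:
    """One- or two-way fixed-effects ANOVA with Type-II sums of squares.

    Every term's SS is the residual-SS drop when it is added to the model
    holding the other main effects; the error MS comes from the fullest
    model requested.  Returns the table and the full-model OLS fit (for
    post-hoc contrasts).
    """
    y = data[response].to_numpy(float)
    if np.any(~np.isfinite(y)):
        raise InvalidInputError("response contains non-finite values")

    if factor_b is None:
        d_a = design_matrix(data, [factor_a])
        d_0 = design_matrix(data, [])
        rss_a, df_a = _ols_rss(d_a.matrix, y)
        rss_0, df_0 = _ols_rss(d_0.matrix, y)
        full_design, rss_full, df_full = d_a, rss_a, df_a
        terms = [(factor_a, rss_0 - rss_a, df_0 - df_a)]
    else:
        d_ab = design_matrix(data, [factor_a, factor_b])
        d_a = design_matrix(data, [factor_a])
        d_b = design_matrix(data, [factor_b])
        rss_ab, df_ab = _ols_rss(d_ab.matrix, y)
        rss_a, df_a = _ols_rss(d_a.matrix, y)
        rss_b, df_b = _ols_rss(d_b.matrix, y)
        terms = [
            (factor_a, rss_b - rss_ab, df_b - df_ab),
            (factor_b, rss_a - rss_ab, df_a - df_ab),
        ]
        if interaction:
            d_full = design_matrix(data, [factor_a, factor_b], interaction=True)
            rss_x, df_x = _ols_rss(d_full.matrix, y)
            terms.append(
                (f"{factor_a}:{factor_b}", rss_ab - rss_x, df_ab - df_x)
            )
            full_design, rss_full, df_full = d_full, rss_x, df_x
        else:
            full_design, rss_full, df_full = d_ab, rss_ab, df_ab

    if df_full <= 0:
        raise InvalidInputError("zero residual degrees of freedom")
    mse = rss_full / df_full
    rows = []
    for term, ss, df_num in terms:
        ss = max(ss, 0.0)
        if df_num <= 0:
            F, p = 0.0, 1.0
        elif mse == 0.0:
            # perfect fit: no term variation left means no evidence either way
            F = 0.0 if ss == 0.0 else np.inf
            p = 1.0 if ss == 0.0 else 0.0
        else:
            F = (ss / df_num) / mse
            p = float(stats.f.sf(F, df_num, df_full))
        rows.append(AnovaRow(term, int(df_num), int(df_full), float(F), p))

    X = full_design.matrix
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    cov = mse * np.linalg.inv(X.T @ X)
    fit = OLSFit(
        coefficients=beta,
        cov_params=cov,
        sigma2=mse,
        df_resid=int(df_full),
        labels=full_design.labels,
        design=full_design,
    )
    return AnovaTable(rows), fit


# ---------------------------------------------------------------------------
# single-step adjusted contrasts


@dataclass
class ContrastResult:
    label: str
    estimate: float
    se: float
    statistic: float
    statistic_kind: str  # "t" or "z"
    p_raw: float
    p_adjusted: float


def tukey_single_step(
    fit: OLSFit | GammaGLMFit,
    contrasts: np.ndarray,
    labels: Sequence[str] | None = None,
    n_draws: int = 100_000,
    seed: int = 0,
) -> list[ContrastResult]:
    """Simultaneous general linear hypotheses with single-step adjustment.

    Each row of ``contrasts`` is a coefficient-space contrast c with
    statistic c'beta / se(c'beta): a t statistic for least-squares fits
    (on the residual df) and a z statistic for GLM fits.  The adjusted p
    of contrast i is P(max_j |T_j| >= |t_i|) under the joint null, where
    T follows a multivariate t (or normal) with the contrasts'
    correlation matrix, evaluated by seeded Monte Carlo; with a single
    contrast the adjusted p equals the raw p exactly.  Monte-Carlo
    adjusted values are floored at the raw p so the ordering
    p_adjusted >= p_raw holds deterministically.
    """
    C = np.atleast_2d(np.asarray(contrasts, dtype=float))
    beta = fit.coefficients
    if C.shape[1] != len(beta):
        raise InvalidInputError(
            f"contrast length {C.shape[1]} != number of coefficients {len(beta)}"
        )
    k = C.shape[0]
    if labels is None:
        labels = [f"contrast{i + 1}" for i in range(k)]
    V = C @ fit.cov_params @ C.T
    se = np.sqrt(np.diag(V))
    if np.any(se <= 0) or not np.all(np.isfinite(se)):
        raise InvalidInputError("singular contrast covariance")
    est = C @ beta
    stat = est / se

    is_ols = isinstance(fit, OLSFit)
    df = fit.df_resid if is_ols else None
    kind = "t" if is_ols else "z"
    if is_ols:
        p_raw = 2.0 * stats.t.sf(np.abs(stat), df)
    else:
        p_raw = 2.0 * stats.norm.sf(np.abs(stat))

    if k == 1:
        p_adj = p_raw.copy()
    else:
        R = V / np.outer(se, se)
        try:
            L = np.linalg.cholesky(R + 1e-12 * np.eye(k))
        except np.linalg.LinAlgError as exc:
            raise InvalidInputError("singular contrast covariance") from exc
        rng = np.random.default_rng(seed)
        Z = rng.standard_normal((n_draws, k)) @ L.T
        if is_ols:
            scale = np.sqrt(rng.chisquare(df, size=n_draws) / df)
            Z = Z / scale[:, None]
        maxabs = np.max(np.abs(Z), axis=1)
        p_adj = np.array([np.mean(maxabs >= abs(s)) for s in stat])
        p_adj = np.maximum(p_adj, p_raw)

    return [
        ContrastResult(
            label=str(labels[i]),
            estimate=float(est[i]),
            se=float(se[i]),
            statistic=float(stat[i]),
            statistic_kind=kind,
            p_raw=float(p_raw[i]),
            p_adjusted=float(min(p_adj[i], 1.0)),
        )
        for i in range(k)
    ]


# ---------------------------------------------------------------------------
# covariate comparison, correlation, orchestration helpers


def _gamma_loglik_ml_shape(y: np.ndarray, mu: np.ndarray) -> tuple[float, float]:
    """Profile the Gamma log likelihood over the shape parameter."""

    def negll(log_a: float) -> float:
        a = np.exp(log_a)
        return -float(
            np.sum(
                a * np.log(a * y / mu) - a * y / mu - np.log(y) - special.gammaln(a)
            )
        )

    res = optimize.minimize_scalar(negll, bounds=(-6, 12), method="bounded")
    return -res.fun, float(np.exp(res.x))


@dataclass
class CovariateComparison:
    f_row: AnovaRow
    aic_without: float
    aic_with: float
    retained: bool

    @property
    def delta_aic(self) -> float:
        return self.aic_with - self.aic_without


def covariate_model_comparison(
    data: pd.DataFrame,
    response: str,
    factors: Sequence[str],
    covariate: str,
    interaction: bool = False,
    alpha: float = 0.05,
) -> CovariateComparison:
    """Compare Gamma GLMs fitted with and without a numeric covariate.

    Reports the deviance F test plus a full-likelihood AIC difference
    (shape estimated by maximum likelihood); the covariate is retained
    iff it significantly improves the fit at ``alpha``.
    """
    y = data[response].to_numpy(float)
    d_without = design_matrix(data, factors, interaction=interaction)
    d_with = design_matrix(
        data, factors, covariates=[covariate], interaction=interaction
    )
    fit_without = fit_gamma_glm(d_without, y)
    fit_with = fit_gamma_glm(d_with, y)
    row = glm_term_tests(fit_with, fit_without, term=covariate)
    ll0, _ = _gamma_loglik_ml_shape(y, fit_without.fitted)
    ll1, _ = _gamma_loglik_ml_shape(y, fit_with.fitted)
    aic0 = -2 * ll0 + 2 * (fit_without.n_params + 1)
    aic1 = -2 * ll1 + 2 * (fit_with.n_params + 1)
    return CovariateComparison(
        f_row=row,
        aic_without=aic0,
        aic_with=aic1,
        retained=bool(row.p < alpha),
    )


def pearson_correlation(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t test on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InvalidInputError("pearson_correlation needs n >= 3 paired values")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise InvalidInputError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def gamma_glm_analysis(
    data: pd.DataFrame,
    response: str,
    factor_a: str,
    factor_b: str | None = None,
    alpha: float = 0.05,
) -> tuple[AnovaTable, GammaGLMFit]:
    """Analysis of deviance for one or two factors with interaction dropping.

    Fits the interaction model first; if the interaction term does not
    significantly improve the fit at ``alpha`` the additive model is
    refitted and reported (the decision is recorded in the table notes).
    Main effects are tested Type-II style: each against the model holding
    the other.
    """
    y = data[response].to_numpy(float)
    notes: list[str] = []
    if factor_b is None:
        fit_a = fit_gamma_glm(design_matrix(data, [factor_a]), y)
        fit_0 = fit_gamma_glm(design_matrix(data, []), y)
        rows = [glm_term_tests(fit_a, fit_0, term=factor_a)]
        return AnovaTable(rows, notes), fit_a

    fit_x = fit_gamma_glm(design_matrix(data, [factor_a, factor_b], interaction=True), y)
    fit_ab = fit_gamma_glm(design_matrix(data, [factor_a, factor_b]), y)
    inter_row = glm_term_tests(fit_x, fit_ab, term=f"{factor_a}:{factor_b}")
    keep_interaction = inter_row.p < alpha
    final = fit_x if keep_interaction else fit_ab
    notes.append(
        f"interaction {'retained' if keep_interaction else 'dropped'} "
        f"(F = {inter_row.F:.3g}, p = {inter_row.p:.3g}, alpha = {alpha})"
    )
    fit_a = fit_gamma_glm(design_matrix(data, [factor_a]), y)
    fit_b = fit_gamma_glm(design_matrix(data, [factor_b]), y)
    rows = [
        glm_term_tests(fit_ab, fit_b, term=factor_a),
        glm_term_tests(fit_ab, fit_a, term=factor_b),
        inter_row,
    ]
    return AnovaTable(rows, notes), final
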
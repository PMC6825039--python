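"""Independent brute-force oracles used to pin the implementation.

Everything here is deliberately written through a *different* route than
the package: direct likelihood optimisation instead of IRLS, projection
matrices instead of incremental least squares, plain resampling loops
instead of the vectorised bootstrap.  None of it imports the code paths
it checks.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy import optimize


def bootstrap_mean_ci_oracle(values, n_iterations, level, seed):
    """Percentile CI for the mean via an explicit resampling loop."""
    rng = np.random.default_rng(seed)
    x = np.asarray(values, dtype=float)
    means = []
    for _ in range(n_iterations):
        sample = rng.choice(x, size=len(x), replace=True)
        means.append(sample.mean())
    alpha = 1.0 - level
    lo, hi = np.quantile(np.array(means), [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def exhaustive_bootstrap_means(values):
    """Means of every one of the n**n possible resamples."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    return np.array(
        [np.mean([x[i] for i in combo]) for combo in product(range(n), repeat=n)]
    )


def gamma_deviance(y, mu):
    return 2.0 * np.sum((y - mu) / mu - np.log(y / mu))


def gamma_glm_optimizer_oracle(X, y):
    """Gamma log-link fit by generic numerical optimisation of the deviance.

    For fixed shape the Gamma log likelihood is maximised exactly where
    the deviance is minimised, so this is a likelihood maximiser that
    never touches IRLS.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)

    def dev(beta):
        mu = np.exp(X @ beta)
        return gamma_deviance(y, mu)

    beta0 = np.linalg.lstsq(X, np.log(y), rcond=None)[0]
    res = optimize.minimize(dev, beta0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12,
                                     "maxiter": 20000, "maxfev": 20000})
    res = optimize.minimize(dev, res.x, method="Powell",
                            options={"xtol": 1e-12, "ftol": 1e-14})
    return res.x, dev(res.x)


def rss_projection(X, y):
    """Residual sum of squares through the explicit hat matrix."""
    X = np.asarray(X, float)
    H = X @ np.linalg.pinv(X)
    r = y - H @ y
    return float(r @ r)


def dummies(levels):
    """Full indicator (cell-mean) coding, one column per level."""
    levels = np.asarray(levels)
    cats = sorted(set(map(str, levels)))
    return np.column_stack([(levels.astype(str) == c).astype(float) for c in cats])


def maxabs_tail_oracle(R, df, threshold, n_draws, seed):
    """P(max_j |T_j| >= threshold) for equicorrelated-or-not multivariate t."""
    rng = np.random.default_rng(seed)
    k = R.shape[0]
    L = np.linalg.cholesky(R + 1e-12 * np.eye(k))
    Z = rng.standard_normal((n_draws, k)) @ L.T
    if df is not None:
        Z = Z / np.sqrt(rng.chisquare(df, size=n_draws) / df)[:, None]
    return float(np.mean(np.max(np.abs(Z), axis=1) >= threshold))
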
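"""Independent reference implementations used to cross-check the package.

Everything here deliberately avoids the production code paths: subset
fits go through statsmodels OLS, subsets come from itertools, and the
posterior weights are recomputed from first principles.
"""
import itertools
import math

import numpy as np
import statsmodels.api as sm


def ols_fit(y, X_subset):
    """statsmodels OLS with intercept; returns (intercept, slopes, rss)."""
    A = sm.add_constant(np.asarray(X_subset, dtype=float), has_constant="add")
    fit = sm.OLS(np.asarray(y, dtype=float), A).fit()
    return float(fit.params[0]), np.asarray(fit.params[1:]), float(fit.ssr)


def bma_oracle(y, X):
    """Exhaustive BIC-weighted model averaging over all feasible subsets.

    Returns (inclusion, avg_coef) arrays aligned with the columns of X.
    Subsets larger than n - 2 predictors are outside the model space.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    eps_rss = max(1e-12 * float(np.var(y)) * n, 1e-30)
    records = []
    for size in range(min(p, n - 2) + 1):
        for subset in itertools.combinations(range(p), size):
            if size == 0:
                intercept = float(y.mean())
                slopes = np.empty(0)
                rss = float(((y - intercept) ** 2).sum())
            else:
                intercept, slopes, rss = ols_fit(y, X[:, list(subset)])
            bic = n * math.log(max(rss, eps_rss) / n) + (size + 1) * math.log(n)
            records.append((subset, slopes, bic))
    bics = np.array([r[2] for r in records])
    w = np.exp(-(bics - bics.min()) / 2.0)
    w /= w.sum()
    inclusion = np.zeros(p)
    avg_coef = np.zeros(p)
    for (subset, slopes, _), weight in zip(records, w):
        for pos, j in enumerate(subset):
            inclusion[j] += weight
            avg_coef[j] += weight * slopes[pos]
    return inclusion, avg_coef


def univariate_r2_order(y, X, names):
    """Squared-correlation sort, ties broken by name."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    r2 = []
    for j in range(X.shape[1]):
        with np.errstate(invalid="ignore"):
            c = np.corrcoef(X[:, j], y)[0, 1]
        r2.append(0.0 if not np.isfinite(c) else c * c)
    return [n for _, n in sorted(zip(r2, names), key=lambda t: (-t[0], t[1]))]
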
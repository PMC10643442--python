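"""Cross-spouse phenotypic association: adjusted correlations and MV regression.

The spousal correlation is a covariate-adjusted Pearson correlation:
both traits are residualised on the covariates (own age, spouse's age,
recruitment centre in the standard analysis) and the correlation of the
residuals is reported with a Fisher-z interval whose degrees of freedom
subtract the covariate count, n - 3 - k.  Multivariable regression of the
spouse's standardized trait on the index standardized trait approximates
the partial correlation, which is why the two sets of estimates are
directly comparable.
"""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm
from scipy import stats

from ._utils import check_full_rank, design_matrix, ols_residuals
from .results import Z95, CorrelationResult, EffectEstimate


def _complete_cases(*arrays):
    mask = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        if a is None:
            continue
        a = np.asarray(a, dtype=float)
        mask &= ~np.isnan(a).any(axis=1) if a.ndim == 2 else ~np.isnan(a)
    return mask


def adjusted_pearson(
    x,
    y,
    covariates=None,
    trait_a: str = "x",
    trait_b: str = "y",
) -> CorrelationResult:
    """Covariate-adjusted Pearson correlation with Fisher-z interval.

    One unique orientation per couple is assumed (each individual appears
    once).  Complete-case analysis; categorical covariate columns are
    one-hot encoded dropping one level.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_all = len(x)
    Z, names = design_matrix(covariates, n_all)
    numeric = Z[:, 1:]
    mask = _complete_cases(x, y, numeric if numeric.size else None)
    x, y, Z = x[mask], y[mask], Z[mask]
    n = len(x)
    k = Z.shape[1] - 1
    if n < k + 4:
        raise ValueError(f"too few complete cases (n={n}) for {k} covariates")
    check_full_rank(Z, names)
    rx = ols_residuals(x, Z)
    ry = ols_residuals(y, Z)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("zero residual variance; correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = min(1.0, max(-1.0, r))
    se_z = 1.0 / np.sqrt(n - 3 - k)
    if abs(r) < 1.0:
        z = np.arctanh(r)
        lo, hi = np.tanh(z - Z95 * se_z), np.tanh(z + Z95 * se_z)
        p = 2 * stats.norm.sf(abs(z) / se_z)
    else:
        lo = hi = r
        p = 0.0
    return CorrelationResult(
        r=r, n=n, ci_low=float(lo), ci_high=float(hi), p=float(p),
        n_covariates=k, trait_a=trait_a, trait_b=trait_b,
    )


def mv_regression(
    outcome,
    exposure,
    covariates=None,
    exposure_label: str = "exposure",
    outcome_label: str = "outcome",
) -> EffectEstimate:
    """Least-squares slope of the spouse's trait on the index trait.

    Conventional (homoskedastic) standard error.  For traits standardized
    to unit SD the slope approximates the partial correlation; binary
    snoring stays on the 0/1 scale so the slope is a risk difference.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    Z, names = design_matrix(covariates, len(y))
    X = np.column_stack([x, Z])
    names = [exposure_label] + names
    mask = _complete_cases(y, X)
    y, X = y[mask], X[mask]
    n = len(y)
    if np.nanstd(X[:, 0]) == 0:
        raise ValueError("zero-variance exposure")
    check_full_rank(X, names)
    fit = sm.OLS(y, X).fit()
    return EffectEstimate(
        beta=float(fit.params[0]), se=float(fit.bse[0]), n=n, method="MV",
        p=float(fit.pvalues[0]), exposure=exposure_label, outcome=outcome_label,
    )


def cross_trait_matrix(index_traits, spouse_traits, covariates=None):
    """Adjusted correlation for every (index trait, spouse trait) pair.

    ``index_traits`` and ``spouse_traits`` are DataFrames with one column
    per trait; returns a DataFrame of correlations (index trait rows,
    spouse trait columns).
    """
    import pandas as pd

    out = pd.DataFrame(
        index=index_traits.columns, columns=spouse_traits.columns, dtype=float
    )
    for a in index_traits.columns:
        for b in spouse_traits.columns:
            res = adjusted_pearson(
                index_traits[a], spouse_traits[b], covariates, trait_a=a, trait_b=b
            )
            out.loc[a, b] = res.r
    return out
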
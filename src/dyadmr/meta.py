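"""Inverse-variance meta-analysis with Cochran heterogeneity statistics.

Used in two places: combining the two sex-stratified cross-partner MR
estimates (random effects), and synthesising effect-modification
subgroups (fixed effect, with I^2 and P_het as the modification
evidence).  ``ci_to_se`` lets printed subgroup confidence intervals be
reused as inputs when only summary tables are available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .results import Z95, EffectEstimate, MetaResult


def ci_to_se(ci_low: float, ci_high: float, level: float = 0.95) -> float:
    """Standard error implied by a symmetric normal confidence interval."""
    if ci_high <= ci_low:
        raise ValueError("ci_high must exceed ci_low")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return float((ci_high - ci_low) / (2.0 * z))


def _validate(betas, ses, k_min=2):
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.shape != s.shape or b.ndim != 1:
        raise ValueError("betas and ses must be 1-d and the same length")
    if len(b) < k_min:
        raise ValueError(f"need at least {k_min} estimates")
    if (s <= 0).any() or not np.isfinite(s).all():
        raise ValueError("standard errors must be positive and finite")
    return b, s


def fixed_effect_meta(betas, ses) -> MetaResult:
    """Fixed-effect pooled estimate with Q, I^2 and P_het.

    weights = se^-2; Q = sum w (beta - pooled)^2 on chi2(k-1);
    I^2 = max(0, (Q - df)/Q) * 100.
    """
    b, s = _validate(betas, ses)
    w = s**-2.0
    pooled = float(np.sum(w * b) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (b - pooled) ** 2))
    df = len(b) - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    p_het = float(stats.chi2.sf(q, df))
    z = pooled / se
    return MetaResult(
        beta=pooled,
        se=se,
        ci_low=pooled - Z95 * se,
        ci_high=pooled + Z95 * se,
        p=float(2 * stats.norm.sf(abs(z))),
        q=q,
        df=df,
        i2=float(i2),
        p_het=p_het,
        k=len(b),
        tau2=0.0,
        model="fixed",
    )


def random_effects_meta(betas, ses) -> MetaResult:
    """DerSimonian-Laird random-effects pooling.

    tau^2 = max(0, (Q - df) / (sum w - sum w^2 / sum w)) from the
    fixed-effect Q; estimates are re-weighted by (se^2 + tau^2)^-1.
    Collapses to the fixed-effect result whenever Q <= df.
    """
    b, s = _validate(betas, ses)
    fixed = fixed_effect_meta(b, s)
    w = s**-2.0
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (fixed.q - fixed.df) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (s**2 + tau2)
    pooled = float(np.sum(w_star * b) / np.sum(w_star))
    se = float(np.sum(w_star) ** -0.5)
    z = pooled / se
    return MetaResult(
        beta=pooled,
        se=se,
        ci_low=pooled - Z95 * se,
        ci_high=pooled + Z95 * se,
        p=float(2 * stats.norm.sf(abs(z))),
        q=fixed.q,
        df=fixed.df,
        i2=fixed.i2,
        p_het=fixed.p_het,
        k=len(b),
        tau2=float(tau2),
        model="random",
    )


def meta_from_cis(estimates, level: float = 0.95, model: str = "fixed") -> MetaResult:
    """Meta-analysis directly from (beta, ci_low, ci_high) triples."""
    betas = [e[0] for e in estimates]
    ses = [ci_to_se(e[1], e[2], level) for e in estimates]
    fn = fixed_effect_meta if model == "fixed" else random_effects_meta
    return fn(betas, ses)


# ---------------------------------------------------------------------------
# Subgroup scans (effect modification)
# ---------------------------------------------------------------------------


@dataclass
class SubgroupScanResult:
    subgroups: pd.DataFrame  # label, beta, se, ci_low, ci_high, n
    meta: MetaResult | None  # None when only one subgroup remains

    def summary(self) -> str:
        lines = [self.subgroups.to_string(index=False)]
        lines.append(
            self.meta.summary() if self.meta is not None
            else "single subgroup: heterogeneity not applicable"
        )
        return "\n".join(lines)


def tertile_labels(values) -> np.ndarray:
    """Tertile assignment with linear-interpolation quantile boundaries.

    Ties on a boundary go to the lower stratum.
    """
    v = np.asarray(values, dtype=float)
    q1, q2 = np.quantile(v, [1 / 3, 2 / 3])
    out = np.where(v <= q1, 0, np.where(v <= q2, 1, 2))
    return out


def subgroup_scan(
    data: pd.DataFrame,
    modifier,
    estimator,
    n_groups: str | int = "auto",
    min_n: int = 30,
) -> SubgroupScanResult:
    """Run an estimator within modifier subgroups and pool fixed-effect.

    ``modifier`` is a column name or an array; continuous modifiers are cut
    into tertiles, discrete ones use their levels.  ``estimator`` maps a
    subgroup DataFrame to an :class:`EffectEstimate`.  Subgroups below
    ``min_n`` rows are dropped with a warning entry.
    """
    mod = data[modifier] if isinstance(modifier, str) else pd.Series(modifier)
    mod = mod.reset_index(drop=True)
    data = data.reset_index(drop=True)
    if n_groups == "auto":
        discrete = mod.dtype.kind in "OUSb" or mod.nunique() <= 6
    else:
        discrete = False
    labels = mod if discrete else pd.Series(tertile_labels(mod))

    rows = []
    for lab, idx in labels.groupby(labels).groups.items():
        sub = data.loc[idx]
        if len(sub) < min_n:
            rows.append(dict(label=lab, beta=np.nan, se=np.nan, n=len(sub), dropped=True))
            continue
        est: EffectEstimate = estimator(sub)
        rows.append(
            dict(
                label=lab, beta=est.beta, se=est.se, ci_low=est.ci_low,
                ci_high=est.ci_high, n=est.n, dropped=False,
            )
        )
    table = pd.DataFrame(rows)
    used = table[~table["dropped"]]
    meta = (
        fixed_effect_meta(used["beta"], used["se"]) if len(used) >= 2 else None
    )
    return SubgroupScanResult(table, meta)
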
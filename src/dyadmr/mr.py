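"""Cross-partner one-sample Mendelian randomisation.

The index individual's genotype (an unweighted GRS, or the per-variant
dosages) instruments their own phenotype; the outcome is the spouse's
phenotype.  Because genotypes are fixed at conception and — absent
assortment — independent of the partner's environment, the two-stage
least squares (2SLS) estimate identifies the structural partner effect
even when the observational association is confounded by the shared
household.

Two surfaces are provided:

* :class:`SpousalMR` — an individual-level model (statsmodels style):
  ``SpousalMR(outcome, exposure, instrument, covariates, couple_id).fit()``
  returns a :class:`SpousalMRResults` with the IV estimate, first-stage
  diagnostics, Sargan over-identification test (when over-identified) and
  a ``summary()`` table.  Dyadic pooling duplicates each person as index
  and spouse, so couple-clustered sandwich SEs are available.

* :class:`SummaryMR` / the ``*_estimate`` functions — summary-statistic
  estimators over per-variant Wald ratios (IVW, MR-Egger, weighted LAD),
  the pleiotropy-sensitivity toolbox.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import check_full_rank, design_matrix, substream
from .dyadic import _complete_cases
from .results import (
    EffectEstimate,
    InstrumentDiagnostics,
    SarganResult,
    ZTestResult,
)

# ---------------------------------------------------------------------------
# Individual-level 2SLS
# ---------------------------------------------------------------------------


@dataclass
class SpousalMRResults:
    """Fitted cross-partner 2SLS results."""

    estimate: EffectEstimate
    first_stage: InstrumentDiagnostics
    sargan: SarganResult | None
    cov_type: str
    params: np.ndarray = field(repr=False)
    param_names: list = field(repr=False)
    residuals: np.ndarray = field(repr=False)

    @property
    def beta(self) -> float:
        return self.estimate.beta

    @property
    def se(self) -> float:
        return self.estimate.se

    def conf_int(self):
        return self.estimate.ci_low, self.estimate.ci_high

    def summary(self) -> str:
        lines = [
            "Cross-partner two-stage least squares",
            "=" * 48,
            self.estimate.summary(),
            f"  first stage: {self.first_stage.summary()}",
            f"  SE type: {self.cov_type}",
        ]
        if self.sargan is not None:
            lines.append(f"  {self.sargan.summary()}")
        return "\n".join(lines)


class SpousalMR:
    """One-sample MR of a spouse's trait on the index trait.

    Parameters
    ----------
    outcome : spouse trait vector.
    exposure : index trait vector.
    instrument : index GRS (1-d) or per-variant dosage matrix (2-d).
    covariates : optional array/DataFrame (age, centre, chip, PCs, ...).
    couple_id : optional labels enabling couple-clustered SEs for the
        pooled two-orientation analysis.
    """

    def __init__(
        self,
        outcome,
        exposure,
        instrument,
        covariates=None,
        couple_id=None,
        exposure_label: str = "exposure",
        outcome_label: str = "outcome",
    ):
        self.y = np.asarray(outcome, dtype=float)
        self.x = np.asarray(exposure, dtype=float)
        inst = np.asarray(instrument, dtype=float)
        self.inst = inst[:, None] if inst.ndim == 1 else inst
        n = len(self.y)
        if not (len(self.x) == n == self.inst.shape[0]):
            raise ValueError("outcome, exposure and instrument lengths differ")
        self.W, self.w_names = design_matrix(covariates, n)
        self.couple_id = None if couple_id is None else np.asarray(couple_id)
        self.exposure_label = exposure_label
        self.outcome_label = outcome_label

        mask = _complete_cases(
            self.y, self.x, self.inst, self.W[:, 1:] if self.W.shape[1] > 1 else None
        )
        self.y, self.x, self.inst, self.W = (
            self.y[mask], self.x[mask], self.inst[mask], self.W[mask]
        )
        if self.couple_id is not None:
            self.couple_id = self.couple_id[mask]

    def fit(self, cov_type: str = "unadjusted") -> SpousalMRResults:
        """Estimate by 2SLS.

        ``cov_type`` is ``"unadjusted"`` (IV variance with structural
        residuals) or ``"cluster"`` (sandwich by couple id, for the pooled
        dyadic-duplication analysis).
        """
        y, x, W = self.y, self.x, self.W
        n = len(y)
        J = self.inst.shape[1]
        Z = np.column_stack([self.inst, W])
        X = np.column_stack([x, W])
        names = [self.exposure_label] + self.w_names
        check_full_rank(Z, [f"iv{j}" for j in range(J)] + self.w_names)
        check_full_rank(X, names)

        # projection of X on the instrument set
        coef_zx, *_ = np.linalg.lstsq(Z, X, rcond=None)
        Xhat = Z @ coef_zx
        XtPzX = X.T @ Xhat
        try:
            beta = np.linalg.solve(XtPzX, Xhat.T @ y)
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(f"2SLS normal equations singular: {e}")
        first = self.first_stage_diagnostics()
        if first.f_stat < 1e-12:
            raise ValueError("unidentified model: first-stage coefficient is zero")

        # structural residuals use the *observed* exposure
        u = y - X @ beta
        bread = np.linalg.inv(XtPzX)
        dof = n - X.shape[1]
        if cov_type == "unadjusted":
            sigma2 = float(u @ u) / dof
            cov = sigma2 * bread
        elif cov_type == "cluster":
            if self.couple_id is None:
                raise ValueError("cluster SEs require couple_id")
            meat = np.zeros((X.shape[1], X.shape[1]))
            df = pd.DataFrame({"g": self.couple_id})
            for _, idx in df.groupby("g").indices.items():
                s = Xhat[idx].T @ u[idx]
                meat += np.outer(s, s)
            G = len(df["g"].unique())
            adj = G / (G - 1) * (n - 1) / dof
            cov = adj * bread @ meat @ bread
        else:
            raise ValueError(f"unknown cov_type {cov_type!r}")

        se = float(np.sqrt(cov[0, 0]))
        est = EffectEstimate(
            beta=float(beta[0]), se=se, n=n, method="2SLS",
            exposure=self.exposure_label, outcome=self.outcome_label,
        )
        sargan = self.sargan(u) if J >= 2 else SarganResult(0.0, 0, float("nan"))
        return SpousalMRResults(
            estimate=est,
            first_stage=first,
            sargan=sargan if J >= 2 else None,
            cov_type=cov_type,
            params=beta,
            param_names=names,
            residuals=u,
        )

    def first_stage_diagnostics(self) -> InstrumentDiagnostics:
        from .grs import instrument_strength

        inst = self.inst[:, 0] if self.inst.shape[1] == 1 else self.inst.sum(axis=1)
        covs = self.W[:, 1:] if self.W.shape[1] > 1 else None
        return instrument_strength(inst, self.x, covs)

    def sargan(self, structural_residuals: np.ndarray) -> SarganResult:
        return sargan_test(
            structural_residuals,
            self.inst,
            self.W[:, 1:] if self.W.shape[1] > 1 else None,
        )


def sargan_test(residuals, instruments, covariates=None) -> SarganResult:
    """Over-identification: n * R^2 of structural residuals on instruments.

    df = J - 1 for a single endogenous exposure; with one instrument the
    model is just-identified and the result is flagged not applicable.
    """
    u = np.asarray(residuals, dtype=float)
    Zi = np.asarray(instruments, dtype=float)
    if Zi.ndim == 1:
        Zi = Zi[:, None]
    J = Zi.shape[1]
    if J == 1:
        return SarganResult(0.0, 0, float("nan"))
    n = len(u)
    W, names = design_matrix(covariates, n)
    A = np.column_stack([W, Zi])
    check_full_rank(A, names + [f"iv{j}" for j in range(J)])
    fitted = A @ np.linalg.lstsq(A, u, rcond=None)[0]
    tss = float(((u - u.mean()) ** 2).sum())
    rss = float(((u - fitted) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    stat = n * r2
    df = J - 1
    return SarganResult(float(stat), df, float(stats.chi2.sf(stat, df)))


def mv_vs_mr_ztest(mv: EffectEstimate, mr: EffectEstimate) -> ZTestResult:
    """z-test for the difference between MV-regression and MR estimates.

    z = (b_MV - b_MR) / sqrt(se_MV^2 + se_MR^2); a small p flags
    disagreement between the observational and instrumented estimates.
    """
    if mv.exposure and mr.exposure and (mv.exposure, mv.outcome) != (mr.exposure, mr.outcome):
        raise ValueError("estimates are not on the same exposure/outcome pair")
    z = (mv.beta - mr.beta) / np.sqrt(mv.se**2 + mr.se**2)
    return ZTestResult(
        z=float(z), p=float(2 * stats.norm.sf(abs(z))), beta_a=mv.beta, beta_b=mr.beta
    )


# ---------------------------------------------------------------------------
# Per-variant Wald ratios and summary-statistic estimators
# ---------------------------------------------------------------------------


@dataclass
class WaldRatioSet:
    """Per-variant instrument-exposure / instrument-outcome associations.

    ratio = beta_gy / beta_gx with first-order SE se_gy / |beta_gx|;
    inverse-variance weights are ratio_se ** -2.
    """

    table: pd.DataFrame  # variant_id, beta_gx, se_gx, beta_gy, se_gy, ratio, ratio_se
    dropped: list = field(default_factory=list)

    def __post_init__(self):
        w = self.table["ratio_se"].to_numpy() ** -2.0
        if not np.isfinite(w).all() or (w <= 0).any():
            raise ValueError("non-finite or non-positive IVW weights")
        self.table = self.table.assign(weight=w)

    def __len__(self) -> int:
        return len(self.table)


def _per_variant_assoc(dosage_col, trait, W):
    X = np.column_stack([dosage_col, W])
    beta, *_ = np.linalg.lstsq(X, trait, rcond=None)
    resid = trait - X @ beta
    dof = len(trait) - X.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[0, 0])
    return float(beta[0]), float(se)


def per_snp_wald_ratios(
    dosage: np.ndarray,
    exposure,
    outcome,
    covariates=None,
    variant_ids=None,
) -> WaldRatioSet:
    """Covariate-adjusted per-variant G->X and G->Y regressions.

    Variants with an exactly zero exposure association are dropped (their
    ratio is undefined) and listed in ``dropped``.
    """
    D = np.asarray(dosage, dtype=float)
    if D.ndim == 1:
        D = D[:, None]
    x = np.asarray(exposure, dtype=float)
    y = np.asarray(outcome, dtype=float)
    W, _ = design_matrix(covariates, len(x))
    mask = _complete_cases(x, y, W[:, 1:] if W.shape[1] > 1 else None, D)
    D, x, y, W = D[mask], x[mask], y[mask], W[mask]
    ids = (
        list(variant_ids)
        if variant_ids is not None
        else [f"v{j + 1}" for j in range(D.shape[1])]
    )
    rows, dropped = [], []
    for j in range(D.shape[1]):
        bgx, segx = _per_variant_assoc(D[:, j], x, W)
        bgy, segy = _per_variant_assoc(D[:, j], y, W)
        if bgx == 0.0:
            dropped.append(ids[j])
            continue
        rows.append(
            dict(
                variant_id=ids[j],
                beta_gx=bgx,
                se_gx=segx,
                beta_gy=bgy,
                se_gy=segy,
                ratio=bgy / bgx,
                ratio_se=segy / abs(bgx),
            )
        )
    if not rows:
        raise ValueError("no variant has a nonzero exposure association")
    return WaldRatioSet(pd.DataFrame(rows), dropped)


def ivw_estimate(ratios: WaldRatioSet) -> EffectEstimate:
    """Fixed-effect inverse-variance weighted mean of the Wald ratios."""
    t = ratios.table
    if len(t) == 0:
        raise ValueError("empty ratio set")
    w = t["weight"].to_numpy()
    beta = float(np.sum(w * t["ratio"]) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    return EffectEstimate(beta=beta, se=se, n=len(t), method="IVW")


def egger_estimate(ratios: WaldRatioSet) -> tuple[EffectEstimate, EffectEstimate]:
    """MR-Egger: weighted regression of beta_gy on beta_gx with intercept.

    beta_gx is oriented non-negative (gy flipped with gx); weights are
    se_gy^-2.  The residual scale is truncated below at 1 (multiplicative
    random-effect convention), and a nonzero intercept signals directional
    pleiotropy.  Returns (slope, intercept) estimates.
    """
    t = ratios.table
    k = len(t)
    if k < 3:
        raise ValueError("MR-Egger requires at least 3 variants")
    sign = np.sign(t["beta_gx"].to_numpy())
    sign[sign == 0] = 1.0
    gx = t["beta_gx"].to_numpy() * sign
    gy = t["beta_gy"].to_numpy() * sign
    w = t["se_gy"].to_numpy() ** -2.0
    X = np.column_stack([gx, np.ones(k)])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ gy)
    resid = gy - X @ coef
    sigma2 = float(np.sum(w * resid**2) / (k - 2))
    sigma2 = max(1.0, sigma2)
    cov = sigma2 * np.linalg.inv(xtwx)
    slope = EffectEstimate(
        beta=float(coef[0]), se=float(np.sqrt(cov[0, 0])), n=k, method="Egger-slope"
    )
    intercept = EffectEstimate(
        beta=float(coef[1]), se=float(np.sqrt(cov[1, 1])), n=k,
        method="Egger-intercept",
    )
    return slope, intercept


def _weighted_lad_objective(b, gx, gy, w):
    return float(np.sum(w * np.abs(gy - b * gx)))


def lad_estimate(
    ratios: WaldRatioSet, n_boot: int = 1000, seed: int = 0
) -> EffectEstimate:
    """Weighted least-absolute-deviation regression through the origin.

    Minimises sum_i (1/se_gy_i) |beta_gy_i - b * beta_gx_i|; the solution
    is the weighted median of the per-variant ratios with weights
    |beta_gx_i| / se_gy_i (similar in spirit to the weighted-median
    estimator).  The default SE bootstraps ratio rows.
    """
    t = ratios.table
    if len(t) == 0:
        raise ValueError("empty ratio set")
    gx = t["beta_gx"].to_numpy()
    gy = t["beta_gy"].to_numpy()
    w = t["se_gy"].to_numpy() ** -1.0

    def solve(gx, gy, w):
        r = gy / gx
        wm = np.abs(gx) * w
        order = np.argsort(r)
        r, wm = r[order], wm[order]
        cum = np.cumsum(wm)
        half = 0.5 * cum[-1]
        i = int(np.searchsorted(cum, half))
        return float(r[min(i, len(r) - 1)])

    beta = solve(gx, gy, w)
    if len(t) == 1 or n_boot <= 0:
        se = float(t["ratio_se"].iloc[0]) if len(t) == 1 else float("nan")
    else:
        rng = substream(seed, "lad-bootstrap")
        reps = np.empty(n_boot)
        k = len(t)
        for b in range(n_boot):
            idx = rng.integers(0, k, size=k)
            reps[b] = solve(gx[idx], gy[idx], w[idx])
        se = float(reps.std(ddof=1))
    return EffectEstimate(beta=beta, se=se, n=len(t), method="LAD")


def weak_instrument_diagnostics(ratios: WaldRatioSet) -> tuple[float, float]:
    """Mean per-variant first-stage F and the I^2_GX index.

    I^2_GX applies the heterogeneity decomposition to the instrument-
    exposure estimates: Q = sum w (b_gx - weighted mean)^2 with
    w = se_gx^-2, I^2 = max(0, (Q - df) / Q) * 100.  Low values flag
    regression-dilution bias in MR-Egger.
    """
    t = ratios.table
    f_mean = float(np.mean((t["beta_gx"] / t["se_gx"]) ** 2))
    if len(t) < 2:
        return f_mean, 0.0
    w = t["se_gx"].to_numpy() ** -2.0
    bx = t["beta_gx"].to_numpy()
    mu = np.sum(w * bx) / np.sum(w)
    q = float(np.sum(w * (bx - mu) ** 2))
    df = len(t) - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return f_mean, float(i2)


@dataclass
class MrSensitivityBundle:
    """Summary-statistic estimators plus weak-instrument context."""

    ivw: EffectEstimate
    egger_slope: EffectEstimate
    egger_intercept: EffectEstimate
    lad: EffectEstimate
    mean_f: float
    i2_gx: float

    def summary(self) -> str:
        return "\n".join(
            [
                self.ivw.summary(),
                self.egger_slope.summary(),
                self.egger_intercept.summary(),
                self.lad.summary(),
                f"mean per-variant F = {self.mean_f:.2f}, I2_GX = {self.i2_gx:.1f}%",
            ]
        )


class SummaryMR:
    """Summary-statistic MR over a :class:`WaldRatioSet`."""

    def __init__(self, ratios: WaldRatioSet):
        self.ratios = ratios

    def fit(self, method: str = "ivw", **kwargs) -> EffectEstimate:
        if method == "ivw":
            return ivw_estimate(self.ratios)
        if method == "egger":
            return egger_estimate(self.ratios)[0]
        if method == "lad":
            return lad_estimate(self.ratios, **kwargs)
        raise ValueError(f"unknown method {method!r}")

    def fit_all(self, seed: int = 0, n_boot: int = 1000) -> MrSensitivityBundle:
        slope, intercept = egger_estimate(self.ratios)
        mean_f, i2 = weak_instrument_diagnostics(self.ratios)
        return MrSensitivityBundle(
            ivw=ivw_estimate(self.ratios),
            egger_slope=slope,
            egger_intercept=intercept,
            lad=lad_estimate(self.ratios, n_boot=n_boot, seed=seed),
            mean_f=mean_f,
            i2_gx=i2,
        )


def bootstrap_couples_lad(
    dosage,
    exposure,
    outcome,
    couple_id,
    covariates=None,
    n_boot: int = 200,
    seed: int = 0,
) -> EffectEstimate:
    """LAD estimate with a couple-level bootstrap SE.

    Resamples couples (respecting dyadic dependence), recomputes the
    per-variant Wald ratios in each replicate and re-solves the weighted
    LAD fit.  Heavier than the row bootstrap but honest about the
    within-couple correlation of the two orientations.
    """
    D = np.asarray(dosage, dtype=float)
    x = np.asarray(exposure, dtype=float)
    y = np.asarray(outcome, dtype=float)
    cid = np.asarray(couple_id)
    point = lad_estimate(per_snp_wald_ratios(D, x, y, covariates), n_boot=0)
    rng = substream(seed, "couple-bootstrap")
    groups = pd.DataFrame({"g": cid}).groupby("g").indices
    keys = list(groups)
    reps = []
    W = covariates
    for _ in range(n_boot):
        pick = rng.integers(0, len(keys), size=len(keys))
        idx = np.concatenate([groups[keys[i]] for i in pick])
        covs = None if W is None else np.asarray(W, dtype=float)[idx]
        try:
            r = per_snp_wald_ratios(D[idx], x[idx], y[idx], covs)
            reps.append(lad_estimate(r, n_boot=0).beta)
        except ValueError:
            continue
    se = float(np.std(reps, ddof=1)) if len(reps) > 1 else float("nan")
    return EffectEstimate(beta=point.beta, se=se, n=len(x), method="LAD")
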
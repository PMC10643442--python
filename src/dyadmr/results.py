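"""Result containers shared across the dyadic analysis modules.

Each container is a frozen dataclass with a ``summary()`` method returning a
plain-text table, in the spirit of statsmodels Results objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

Z95 = stats.norm.ppf(0.975)  # 1.959964


@dataclass(frozen=True)
class EffectEstimate:
    """Point estimate of a cross-partner effect.

    ``beta`` is a mean difference in the spouse's trait (SD per SD of the
    index trait) for standardized traits, or a risk difference for binary
    traits analysed on the 0/1 scale.
    """

    beta: float
    se: float
    n: int
    method: str
    exposure: str = ""
    outcome: str = ""
    p: float = field(default=None)  # type: ignore[assignment]
    ci_low: float = field(default=None)  # type: ignore[assignment]
    ci_high: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.ci_low is None:
            object.__setattr__(self, "ci_low", self.beta - Z95 * self.se)
        if self.ci_high is None:
            object.__setattr__(self, "ci_high", self.beta + Z95 * self.se)
        if self.p is None:
            z = self.beta / self.se if self.se > 0 else np.inf
            object.__setattr__(self, "p", 2 * stats.norm.sf(abs(z)))

    def summary(self) -> str:
        lab = f"{self.exposure} -> {self.outcome}" if self.exposure else ""
        return (
            f"{self.method:12s} {lab}\n"
            f"  beta = {self.beta:+.4f}  se = {self.se:.4f}  "
            f"95% CI [{self.ci_low:+.4f}, {self.ci_high:+.4f}]  "
            f"p = {self.p:.3g}  n = {self.n}"
        )


@dataclass(frozen=True)
class CorrelationResult:
    """Covariate-adjusted Pearson correlation with Fisher-z interval."""

    r: float
    n: int
    ci_low: float
    ci_high: float
    p: float
    n_covariates: int = 0
    trait_a: str = ""
    trait_b: str = ""

    def summary(self) -> str:
        return (
            f"r({self.trait_a}, {self.trait_b}) = {self.r:+.4f} "
            f"[{self.ci_low:+.4f}, {self.ci_high:+.4f}]  p = {self.p:.3g}  "
            f"n = {self.n}  (adjusted for {self.n_covariates} covariates)"
        )


@dataclass(frozen=True)
class ZTestResult:
    """Two-sided z-test for the difference of two independent estimates."""

    z: float
    p: float
    beta_a: float
    beta_b: float

    def summary(self) -> str:
        return f"z = {self.z:+.3f}, p = {self.p:.3f}"


@dataclass(frozen=True)
class InstrumentDiagnostics:
    """First-stage strength of a genetic instrument."""

    partial_r2: float
    f_stat: float
    n: int
    n_covariates: int = 0

    def summary(self) -> str:
        return (
            f"partial R2 = {self.partial_r2:.4f}, F = {self.f_stat:.1f}, "
            f"n = {self.n}"
        )


@dataclass(frozen=True)
class SarganResult:
    """Over-identification test; df = J - 1 for a single exposure."""

    stat: float
    df: int
    p: float  # nan when df == 0 (just-identified, not applicable)

    @property
    def applicable(self) -> bool:
        return self.df > 0

    def summary(self) -> str:
        if not self.applicable:
            return "Sargan: just-identified (df = 0), not applicable"
        return f"Sargan chi2({self.df}) = {self.stat:.3f}, p = {self.p:.3f}"


@dataclass(frozen=True)
class MetaResult:
    """Pooled inverse-variance estimate with Cochran heterogeneity."""

    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    q: float
    df: int
    i2: float  # percentage in [0, 100]
    p_het: float
    k: int
    tau2: float = 0.0
    model: str = "fixed"

    def summary(self) -> str:
        return (
            f"{self.model}-effect meta (k={self.k}): beta = {self.beta:+.4f} "
            f"[{self.ci_low:+.4f}, {self.ci_high:+.4f}], "
            f"Q = {self.q:.3f} (df {self.df}), I2 = {self.i2:.0f}%, "
            f"P_het = {self.p_het:.3g}, tau2 = {self.tau2:.4g}"
        )
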
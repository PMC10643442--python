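"""Unweighted genetic risk scores and assortative-mating diagnostics.

A score is the per-individual count of trait-increasing alleles over a
pre-pruned instrument list.  Orientation bookkeeping: a variant whose
reported GWAS effect is negative contributes its flipped dosage (2 - d),
as does a variant whose genotype-file allele pair is stored in the
swapped order.  Unweighted (rather than beta-weighted) scores limit the
impact of Winner's curse from overlapping discovery samples.

The cross-spouse correlation of the scores is the assortative-mating
diagnostic: phenotypic mate choice induces genotype correlation between
partners, whereas partner interaction and shared environment do not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dyadic import adjusted_pearson
from .results import CorrelationResult, InstrumentDiagnostics
from .simulate import GenotypeMatrix

INSTRUMENT_COLUMNS = ("variant_id", "effect_allele", "other_allele", "beta", "se", "pval")
PVALUE_TIERS = (5e-8, 5e-7, 5e-6, 5e-5)

_PALINDROMIC = {frozenset("AT"), frozenset("CG")}


def read_instruments(path) -> pd.DataFrame:
    """Read an instrument-list TSV with the required header."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in INSTRUMENT_COLUMNS if c not in df.columns]
    if missing:
        raise KeyError(f"instrument list is missing columns: {missing}")
    return df


@dataclass
class GrsVector:
    """Per-individual unweighted allele-count scores."""

    individual_id: np.ndarray
    score: np.ndarray
    n_snps_used: int
    orientation: pd.DataFrame = field(repr=False)  # variant_id, flipped, reason

    def standardized(self) -> np.ndarray:
        return (self.score - self.score.mean()) / self.score.std(ddof=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"individual_id": self.individual_id, "score": self.score}
        )


def build_unweighted_grs(
    genotypes: GenotypeMatrix,
    instruments: pd.DataFrame,
    allow_missing: bool = False,
) -> GrsVector:
    """Count trait-increasing alleles across the instrument variants.

    Sporadically missing dosages are mean-imputed from the variant's
    observed oriented mean (preserves n).  Allele mismatches (neither
    order) raise; absent variants raise unless ``allow_missing``.
    """
    missing_cols = [c for c in INSTRUMENT_COLUMNS if c not in instruments.columns]
    if missing_cols:
        raise KeyError(f"instrument list is missing columns: {missing_cols}")
    if instruments["variant_id"].duplicated().any():
        dups = instruments.loc[
            instruments["variant_id"].duplicated(), "variant_id"
        ].tolist()
        warnings.warn(f"duplicate instrument variant ids (pre-pruning?): {dups}")
        instruments = instruments.drop_duplicates("variant_id")

    var_idx = pd.Index(genotypes.variants["variant_id"])
    oriented_cols = []
    orientation_rows = []
    absent = []
    for row in instruments.itertuples(index=False):
        pos = var_idx.get_indexer([row.variant_id])[0]
        if pos < 0:
            absent.append(row.variant_id)
            continue
        g_ea = genotypes.variants["effect_allele"].iat[pos]
        g_oa = genotypes.variants["other_allele"].iat[pos]
        if {row.effect_allele, row.other_allele} != {g_ea, g_oa}:
            raise ValueError(
                f"allele mismatch for {row.variant_id}: instrument "
                f"{row.effect_allele}/{row.other_allele} vs genotype {g_ea}/{g_oa}"
            )
        if frozenset((row.effect_allele, row.other_allele)) in _PALINDROMIC:
            warnings.warn(
                f"palindromic variant {row.variant_id} accepted as-is "
                "(no frequency-based strand inference)"
            )
        flipped = False
        d = genotypes.dosage[:, pos].astype(float).copy()
        if row.effect_allele != g_ea:  # genotype file stores swapped alleles
            d = 2.0 - d
            flipped = not flipped
        if row.beta < 0:  # stated effect allele is trait-decreasing
            d = 2.0 - d
            flipped = not flipped
        obs = d[~np.isnan(d)]
        if np.isnan(d).any():
            d = np.where(np.isnan(d), obs.mean(), d)
        oriented_cols.append(d)
        orientation_rows.append(
            dict(variant_id=row.variant_id, flipped=flipped)
        )
    if absent and not allow_missing:
        raise KeyError(f"instrument variants absent from genotypes: {absent}")
    if not oriented_cols:
        raise ValueError("no instrument variants available to score")
    score = np.sum(oriented_cols, axis=0)
    return GrsVector(
        individual_id=genotypes.individual_id.copy(),
        score=score,
        n_snps_used=len(oriented_cols),
        orientation=pd.DataFrame(orientation_rows),
    )


def instrument_strength(
    grs, trait, covariates=None
) -> InstrumentDiagnostics:
    """First-stage partial R^2 and F of the score for its trait.

    partial R^2 = (RSS_reduced - RSS_full) / RSS_reduced from the two
    first-stage regressions; F is the squared t-statistic of the score
    coefficient.  F < 10 is the conventional weak-instrument flag.
    """
    from ._utils import check_full_rank, design_matrix, ols_residuals
    from .dyadic import _complete_cases

    g = grs.score if isinstance(grs, GrsVector) else np.asarray(grs, dtype=float)
    y = np.asarray(trait, dtype=float)
    Z, names = design_matrix(covariates, len(y))
    mask = _complete_cases(y, g, Z[:, 1:] if Z.shape[1] > 1 else None)
    y, g, Z = y[mask], np.asarray(g, dtype=float)[mask], Z[mask]
    n = len(y)
    k = Z.shape[1]
    if n < k + 3:
        raise ValueError("too few complete cases for first-stage regression")
    X = np.column_stack([g, Z])
    check_full_rank(X, ["grs"] + names)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r_full = y - X @ beta
    r_red = ols_residuals(y, Z)
    rss_full = float(r_full @ r_full)
    rss_red = float(r_red @ r_red)
    partial_r2 = (rss_red - rss_full) / rss_red
    sigma2 = rss_full / (n - X.shape[1])
    se = float(np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[0, 0]))
    f_stat = float((beta[0] / se) ** 2)
    return InstrumentDiagnostics(
        partial_r2=float(partial_r2), f_stat=f_stat, n=n, n_covariates=k - 1
    )


def grs_spousal_correlation(
    genotypes_index: GenotypeMatrix,
    genotypes_spouse: GenotypeMatrix,
    instruments: pd.DataFrame,
    covariates=None,
    tiers=PVALUE_TIERS,
) -> dict[float, CorrelationResult]:
    """Cross-spouse score correlation at each instrument p-value tier.

    Relaxing the tier can only add variants (monotone n_snps_used).
    A positive adjusted correlation is the assortative-mating signature;
    partner interaction leaves the scores uncorrelated because genotypes
    are fixed at conception.
    """
    out: dict[float, CorrelationResult] = {}
    for tier in tiers:
        sub = instruments[instruments["pval"] <= tier]
        if len(sub) == 0:
            continue
        gi = build_unweighted_grs(genotypes_index, sub)
        gs = build_unweighted_grs(genotypes_spouse, sub)
        out[tier] = adjusted_pearson(
            gi.score,
            gs.score,
            covariates,
            trait_a=f"grs_index@{tier:g}",
            trait_b=f"grs_spouse@{tier:g}",
        )
    if not out:
        raise ValueError("no instruments pass any requested tier")
    return out
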
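"""Configuration-driven orchestration: simulate -> pair -> encode ->
correlate -> MR -> GRS correlation -> sensitivity -> subgroups.

All randomness flows from the single ``seed`` field; re-running an
identical configuration reproduces every numerical output byte for byte
(the manifest separates volatile metadata from the numeric payload).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dyadic import adjusted_pearson, mv_regression
from .grs import grs_spousal_correlation
from .meta import subgroup_scan
from .mr import SpousalMR, SummaryMR, mv_vs_mr_ztest, per_snp_wald_ratios
from .pairing import derive_spouse_pairs
from .phenotypes import accelerometer_qc, encode_ukb_traits
from .simulate import (
    ScenarioParams,
    simulate_couples,
    simulate_household_table,
    simulate_trait_battery,
    ukb_like,
)

DEFAULT_TOGGLES = dict(
    pairing=True,
    encoding=True,
    correlations=True,
    mr=True,
    grs_correlation=True,
    sensitivity=True,
    subgroups=True,
)


@dataclass
class PipelineConfig:
    scenario: str = "interaction"
    preset: str | None = None  # "ukb-like" or None
    n_couples: int = 2000
    beta_i: float = 0.13
    rho_a: float = 0.0
    c_share: float = 0.0
    alpha_g: float = 0.25
    n_snps: int = 30
    seed: int = 0
    out_dir: str = "dyadmr-run"
    decoys: dict = field(
        default_factory=lambda: dict(
            triples=1, same_sex=1, high_ibd=1, parental_death=1, singles=1
        )
    )
    toggles: dict = field(default_factory=lambda: dict(DEFAULT_TOGGLES))

    def __post_init__(self):
        toggles = dict(DEFAULT_TOGGLES)
        toggles.update(self.toggles or {})
        self.toggles = toggles

    def scenario_params(self) -> ScenarioParams:
        if self.preset == "ukb-like":
            return ukb_like(self.scenario, seed=self.seed)
        kwargs = dict(
            scenario=self.scenario,
            n_couples=self.n_couples,
            alpha_g=self.alpha_g,
            n_snps=self.n_snps,
            seed=self.seed,
        )
        if self.scenario in ("interaction", "mixed"):
            kwargs["beta_i"] = self.beta_i
        if self.scenario in ("assortment", "mixed"):
            kwargs["rho_a"] = self.rho_a or 0.3
        if self.scenario in ("confounding", "mixed"):
            kwargs["c_share"] = self.c_share or 0.3
        return ScenarioParams(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class PipelineResult:
    out_dir: Path
    manifest: dict
    tables: dict


def _stage(manifest, name, status, **info):
    manifest["stages"].append(dict(stage=name, status=status, **info))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the enabled stages in dependency order, writing artefacts.

    Output families: pairs + exclusion log (TSV), encoded traits (CSV),
    spousal correlations (TSV), MV/2SLS/z-test results (TSV),
    GRS-correlation tiers (TSV), sensitivity estimators (JSON), subgroup
    meta-analyses (TSV), and ``manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "scenario": config.scenario,
        "stages": [],
    }
    tables: dict = {}
    toggles = config.toggles

    params = config.scenario_params()
    cohort = simulate_couples(params)
    cohort.write_csv(out / "cohort.csv")
    _stage(manifest, "simulate", "ok", n_couples=cohort.n_couples)

    try:
        if toggles["pairing"]:
            hh = simulate_household_table(cohort, config.decoys, seed=config.seed)
            pairing = derive_spouse_pairs(hh.households, hh.ibd)
            pairing.write(out / "pairs.tsv", out / "pairing_exclusions.tsv")
            rule_counts = (
                pairing.exclusions["rule"].value_counts().to_dict()
                if len(pairing.exclusions)
                else {}
            )
            tables["pairs"] = pairing.pairs
            _stage(
                manifest, "pairing", "ok",
                n_pairs=len(pairing.pairs), exclusions=rule_counts,
            )
        else:
            _stage(manifest, "pairing", "skipped")

        if toggles["encoding"]:
            battery = simulate_trait_battery(cohort)
            encoded = encode_ukb_traits(battery)
            qc = accelerometer_qc(battery)
            encoded.to_csv(out / "traits_encoded.csv", index=False)
            qc.dropped.to_csv(out / "accelerometer_qc_drops.tsv", sep="\t", index=False)
            tables["traits"] = encoded
            _stage(
                manifest, "encoding", "ok",
                n_rows=len(encoded), accel_dropped=len(qc.dropped),
            )
        else:
            _stage(manifest, "encoding", "skipped")

        one = cohort.orientations(pooled=False)
        covs = pd.DataFrame(
            {
                "age_index": one["index_age"],
                "age_spouse": one["spouse_age"],
                "centre": one["centre"].astype(str),
            }
        )
        if toggles["correlations"]:
            res = adjusted_pearson(
                one["index_phenotype"], one["spouse_phenotype"], covs,
                trait_a="phenotype_index", trait_b="phenotype_spouse",
            )
            corr_df = pd.DataFrame(
                [
                    dict(
                        trait_a=res.trait_a, trait_b=res.trait_b, r=res.r,
                        ci_low=res.ci_low, ci_high=res.ci_high, p=res.p, n=res.n,
                    )
                ]
            )
            corr_df.to_csv(out / "correlations.tsv", sep="\t", index=False)
            tables["correlations"] = corr_df
            _stage(manifest, "correlations", "ok", n=res.n)
        else:
            _stage(manifest, "correlations", "skipped")

        pooled = cohort.orientations(pooled=True)
        pooled_covs = pd.DataFrame(
            {
                "age_index": pooled["index_age"],
                "age_spouse": pooled["spouse_age"],
                "centre": pooled["centre"].astype(str),
            }
        )
        if toggles["mr"]:
            mv = mv_regression(
                pooled["spouse_phenotype"], pooled["index_phenotype"], pooled_covs,
                exposure_label="phenotype", outcome_label="spouse_phenotype",
            )
            model = SpousalMR(
                pooled["spouse_phenotype"],
                pooled["index_phenotype"],
                pooled["index_grs_std"],
                pooled_covs,
                couple_id=pooled["couple_id"],
                exposure_label="phenotype",
                outcome_label="spouse_phenotype",
            )
            fit = model.fit(cov_type="cluster")
            zt = mv_vs_mr_ztest(mv, fit.estimate)
            mr_df = pd.DataFrame(
                [
                    dict(
                        trait="phenotype",
                        n_pairs=cohort.n_couples,
                        mv_beta=mv.beta, mv_se=mv.se,
                        mv_ci_low=mv.ci_low, mv_ci_high=mv.ci_high, mv_p=mv.p,
                        mr_beta=fit.beta, mr_se=fit.se,
                        mr_ci_low=fit.estimate.ci_low,
                        mr_ci_high=fit.estimate.ci_high,
                        mr_p=fit.estimate.p,
                        ztest_p=zt.p,
                        first_stage_f=fit.first_stage.f_stat,
                        partial_r2=fit.first_stage.partial_r2,
                    )
                ]
            )
            mr_df.to_csv(out / "mr_results.tsv", sep="\t", index=False)
            tables["mr"] = mr_df
            _stage(manifest, "mr", "ok", n=fit.estimate.n)
        else:
            _stage(manifest, "mr", "skipped")

        if toggles["grs_correlation"]:
            geno = cohort.genotypes
            n = cohort.n_couples
            ids = pd.Index(geno.individual_id)
            f_idx = ids.get_indexer(cohort.couples["id_f"])
            m_idx = ids.get_indexer(cohort.couples["id_m"])
            rng = np.random.default_rng(config.seed)
            pvals = rng.choice([4e-9, 4e-8, 4e-7, 4e-6], size=geno.n_variants)
            instruments = pd.DataFrame(
                dict(
                    variant_id=geno.variants["variant_id"],
                    effect_allele=geno.variants["effect_allele"],
                    other_allele=geno.variants["other_allele"],
                    beta=1.0,
                    se=0.01,
                    pval=pvals,
                )
            )
            res = grs_spousal_correlation(
                geno.subset(geno.individual_id[f_idx]),
                geno.subset(geno.individual_id[m_idx]),
                instruments,
                covs,
            )
            grs_df = pd.DataFrame(
                [
                    dict(tier=t, r=c.r, ci_low=c.ci_low, ci_high=c.ci_high, p=c.p, n=c.n)
                    for t, c in res.items()
                ]
            )
            grs_df.to_csv(out / "grs_correlation.tsv", sep="\t", index=False)
            tables["grs_correlation"] = grs_df
            _stage(manifest, "grs_correlation", "ok", tiers=len(grs_df))
        else:
            _stage(manifest, "grs_correlation", "skipped")

        if toggles["sensitivity"]:
            geno = cohort.genotypes
            ids = pd.Index(geno.individual_id)
            idx_idx = ids.get_indexer(pooled["index_id"])
            dose = geno.dosage[idx_idx][:, : min(20, geno.n_variants)]
            ratios = per_snp_wald_ratios(
                dose,
                pooled["index_phenotype"],
                pooled["spouse_phenotype"],
                pooled_covs,
                variant_ids=geno.variants["variant_id"][: dose.shape[1]],
            )
            bundle = SummaryMR(ratios).fit_all(seed=config.seed, n_boot=200)
            payload = dict(
                ivw=dataclasses.asdict(bundle.ivw),
                egger_slope=dataclasses.asdict(bundle.egger_slope),
                egger_intercept=dataclasses.asdict(bundle.egger_intercept),
                lad=dataclasses.asdict(bundle.lad),
                mean_f=bundle.mean_f,
                i2_gx=bundle.i2_gx,
            )
            with open(out / "sensitivity.json", "w") as fh:
                json.dump(payload, fh, indent=2)
            tables["sensitivity"] = payload
            _stage(manifest, "sensitivity", "ok", n_variants=len(ratios))
        else:
            _stage(manifest, "sensitivity", "skipped")

        if toggles["subgroups"]:
            pooled2 = pooled.assign(mean_age=(pooled["index_age"] + pooled["spouse_age"]) / 2)

            def estimator(sub: pd.DataFrame):
                m = SpousalMR(
                    sub["spouse_phenotype"], sub["index_phenotype"],
                    sub["index_grs_std"],
                    pd.DataFrame(
                        {"age_index": sub["index_age"], "age_spouse": sub["spouse_age"]}
                    ),
                    couple_id=sub["couple_id"],
                )
                return m.fit(cov_type="cluster").estimate

            scan = subgroup_scan(pooled2, "mean_age", estimator)
            scan.subgroups.to_csv(out / "subgroups_age.tsv", sep="\t", index=False)
            tables["subgroups"] = scan
            _stage(
                manifest, "subgroups", "ok",
                i2=None if scan.meta is None else scan.meta.i2,
            )
        else:
            _stage(manifest, "subgroups", "skipped")
    except Exception as e:
        _stage(manifest, "FAILED", type(e).__name__, message=str(e))
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return PipelineResult(out, manifest, tables)
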
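"""Synthetic couple-cohort generator.

Generates the data the dyadic MR pipeline consumes — genotypes, paired
spouses with correlated phenotypes, household descriptor tables, and
parent-offspring trios with IBD summaries — under explicit generative
scenarios:

* ``null``         — partners are exchangeable strangers;
* ``assortment``   — mates are chosen on phenotypic similarity
  (Gaussian-copula rank matching with target correlation ``rho_a``);
* ``interaction``  — partners causally influence each other's phenotype
  (a simultaneous linear system with structural effect ``beta_i``, solved
  exactly);
* ``confounding``  — a couple-level shared environment contributes a
  fraction ``c_share`` of phenotype variance to both partners;
* ``mixed``        — all three mechanisms at once.

The three mechanisms leave different fingerprints on (i) the cross-spouse
phenotypic correlation, (ii) the index-genotype -> spouse-phenotype MR
estimate and (iii) the cross-spouse GRS correlation, which is what the
downstream analysis is designed to distinguish.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import reference
from ._utils import substream

SCENARIOS = ("null", "assortment", "interaction", "confounding", "mixed")


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Individuals x variants allele-dosage table.

    ``dosage`` holds counts of the effect allele in {0, 1, 2}, with NaN for
    missing calls. ``variants`` carries variant_id, effect_allele,
    other_allele and maf.
    """

    individual_id: np.ndarray
    variants: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self):
        self.individual_id = np.asarray(self.individual_id)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.individual_id), len(self.variants)):
            raise ValueError("dosage shape does not match ids x variants")
        obs = self.dosage[~np.isnan(self.dosage)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be in {0, 1, 2} or missing")
        if self.variants["variant_id"].duplicated().any():
            raise ValueError("variant ids must be unique")
        maf = self.variants["maf"].to_numpy()
        if ((maf <= 0) | (maf > 0.5)).any():
            raise ValueError("maf must lie in (0, 0.5]")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_id)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset(self, ids) -> "GenotypeMatrix":
        idx = pd.Index(self.individual_id).get_indexer(np.asarray(ids))
        if (idx < 0).any():
            raise KeyError("unknown individual ids in subset")
        return GenotypeMatrix(
            np.asarray(ids), self.variants.copy(), self.dosage[idx]
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.dosage,
            index=pd.Index(self.individual_id, name="individual_id"),
            columns=self.variants["variant_id"].to_numpy(),
        )
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def _resolve_maf(maf_spec, n_snps: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(maf_spec, tuple) and len(maf_spec) == 3 and maf_spec[0] == "uniform":
        _, lo, hi = maf_spec
        maf = rng.uniform(lo, hi, size=n_snps)
    elif np.isscalar(maf_spec):
        maf = np.full(n_snps, float(maf_spec))
    else:
        maf = np.asarray(maf_spec, dtype=float)
        if maf.shape != (n_snps,):
            raise ValueError("maf vector length must equal n_snps")
    if ((maf <= 0) | (maf > 0.5)).any():
        raise ValueError("maf must lie in (0, 0.5]")
    return maf


def simulate_genotypes(
    n_individuals: int,
    n_snps: int,
    maf_spec=("uniform", 0.05, 0.5),
    seed: int = 0,
    id_prefix: str = "ind",
) -> GenotypeMatrix:
    """Draw independent Hardy-Weinberg genotypes.

    Each dosage is the sum of two Bernoulli(maf) allele draws; variants are
    independent (no LD, by design — instrument lists are assumed pre-pruned
    downstream).
    """
    if n_individuals < 1 or n_snps < 1:
        raise ValueError("n_individuals and n_snps must be >= 1")
    rng = substream(seed, "genotypes")
    maf = _resolve_maf(maf_spec, n_snps, rng)
    dosage = rng.binomial(2, maf, size=(n_individuals, n_snps)).astype(float)
    variants = pd.DataFrame(
        {
            "variant_id": [f"rs{j + 1}" for j in range(n_snps)],
            "effect_allele": ["A"] * n_snps,
            "other_allele": ["G"] * n_snps,
            "maf": maf,
        }
    )
    ids = np.array([f"{id_prefix}{i + 1}" for i in range(n_individuals)])
    return GenotypeMatrix(ids, variants, dosage)


def expected_grs_variance(alpha: float, maf_vector, total_variance: float = 1.0) -> float:
    """Phenotype variance fraction explained by an unweighted GRS.

    ``alpha`` is the phenotype effect per trait-increasing allele; an
    unweighted score over independent HWE variants has variance
    sum(2 p (1 - p)), so the explained fraction is
    alpha^2 * sum(2 p (1 - p)) / total_variance.  Used to calibrate the
    simulator to the instrument strengths reported for real sleep GRS
    (0.1-1.4% of trait variance).
    """
    maf = np.asarray(maf_vector, dtype=float)
    if maf.size == 0:
        raise ValueError("maf vector is empty")
    if ((maf <= 0) | (maf > 0.5)).any():
        raise ValueError("maf must lie in (0, 0.5]")
    return float(alpha**2 * np.sum(2 * maf * (1 - maf)) / total_variance)


# ---------------------------------------------------------------------------
# Scenario parameters and couple simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioParams:
    """Generative parameters for one couple-cohort scenario.

    alpha_g   GRS effect on own phenotype, SD of phenotype per SD of score.
    rho_a     target cross-spouse matching correlation under assortment.
    beta_i    partner-interaction structural effect (SD per SD);
              |beta_i| < 1 so the simultaneous system is invertible.
    c_share   fraction of phenotype variance from a couple-shared factor.
    """

    scenario: str = "null"
    n_couples: int = 1000
    alpha_g: float = 0.0
    rho_a: float = 0.0
    beta_i: float = 0.0
    c_share: float = 0.0
    interaction_direction: str = "reciprocal"  # or male_to_female / female_to_male
    n_snps: int = 50
    maf_spec: object = None  # defaults to ("uniform", 0.05, 0.5)
    noise_sd: float | None = None
    n_centres: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n_couples < 1:
            raise ValueError("n_couples must be >= 1")
        if abs(self.beta_i) >= 1:
            raise ValueError("|beta_i| must be < 1 (simultaneous system)")
        if not -1 <= self.rho_a <= 1:
            raise ValueError("rho_a must lie in [-1, 1]")
        if not 0 <= self.c_share < 1:
            raise ValueError("c_share must lie in [0, 1)")
        if self.alpha_g**2 + self.c_share > 1:
            raise ValueError("variance fractions alpha_g^2 + c_share exceed 1")
        if self.maf_spec is None:
            object.__setattr__(self, "maf_spec", ("uniform", 0.05, 0.5))

    @property
    def resolved_noise_sd(self) -> float:
        if self.noise_sd is not None:
            return self.noise_sd
        return float(np.sqrt(max(0.0, 1.0 - self.alpha_g**2 - self.c_share)))


def ukb_like(scenario: str = "interaction", seed: int = 0, **overrides) -> ScenarioParams:
    """Calibration preset mirroring the published cohort scale.

    47,050 couples, GRS explaining 0.6% of trait variance, partner effect
    0.13 SD per SD — the sleep-duration row of the published analysis.
    """
    base = dict(
        scenario=scenario,
        n_couples=47_050,
        alpha_g=float(np.sqrt(0.006)),
        beta_i=0.13 if scenario in ("interaction", "mixed") else 0.0,
        rho_a=0.2 if scenario in ("assortment", "mixed") else 0.0,
        c_share=0.3 if scenario in ("confounding", "mixed") else 0.0,
        n_snps=70,
        seed=seed,
    )
    base.update(overrides)
    return ScenarioParams(**base)


@dataclass
class CoupleCohort:
    """Paired spouse records with phenotypes, covariates and latents.

    ``couples`` is wide, one row per couple with ``_f``/``_m`` suffixed
    person-level columns. Sexes are discordant within a couple by
    construction and each individual belongs to exactly one couple.
    """

    couples: pd.DataFrame
    params: ScenarioParams
    genotypes: GenotypeMatrix | None = None

    @property
    def n_couples(self) -> int:
        return len(self.couples)

    def to_individual_frame(self) -> pd.DataFrame:
        rows = []
        for sex, suf in (("female", "_f"), ("male", "_m")):
            cols = {
                c[: -len(suf)]: c for c in self.couples.columns if c.endswith(suf)
            }
            sub = self.couples[list(cols.values())].rename(
                columns={v: k for k, v in cols.items()}
            )
            sub.insert(0, "couple_id", self.couples["couple_id"].to_numpy())
            sub.insert(1, "sex", sex)
            shared = [
                c
                for c in self.couples.columns
                if not (c.endswith("_f") or c.endswith("_m") or c == "couple_id")
            ]
            for c in shared:
                sub[c] = self.couples[c].to_numpy()
            rows.append(sub)
        out = pd.concat(rows, ignore_index=True)
        return out.rename(columns={"id": "individual_id"})

    def orientations(self, pooled: bool = True) -> pd.DataFrame:
        """Index/spouse-oriented analysis table.

        With ``pooled=True`` each couple contributes two rows (each partner
        once as index, once as spouse) — the dyadic-duplication convention
        of the pooled analysis; couple_id is retained for clustered
        standard errors.  With ``pooled=False`` only the
        female-index orientation is returned (one row per couple).
        """
        f, m = self._oriented("f", "m"), self._oriented("m", "f")
        if not pooled:
            return f
        return pd.concat([f, m], ignore_index=True)

    def _oriented(self, index_suf: str, spouse_suf: str) -> pd.DataFrame:
        c = self.couples
        out = pd.DataFrame({"couple_id": c["couple_id"]})
        out["orientation"] = f"{index_suf}_index"
        for role, suf in (("index", index_suf), ("spouse", spouse_suf)):
            for col in c.columns:
                if col.endswith(f"_{suf}"):
                    out[f"{role}_{col[:-2]}"] = c[col].to_numpy()
        out["centre"] = c["centre"].to_numpy()
        return out

    def write_csv(self, path) -> None:
        self.couples.to_csv(path, index=False)


def _normal_scores(x: np.ndarray) -> np.ndarray:
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / len(x))


def simulate_couples(
    params: ScenarioParams, genotypes: GenotypeMatrix | None = None
) -> CoupleCohort:
    """Simulate a couple cohort under the scenario's structural model.

    Own-phenotype model: X = alpha_g * GRS_std + shared + noise.  Assortative
    pairing is Gaussian-copula rank matching on the pre-partnership phenotype;
    the shared confounder and the partner-interaction system are applied after
    pairing (interaction solved exactly for |beta_i| < 1).
    """
    n = params.n_couples
    if genotypes is None:
        genotypes = simulate_genotypes(
            2 * n, params.n_snps, params.maf_spec, seed=params.seed
        )
    if genotypes.n_individuals < 2 * n:
        raise ValueError("need at least 2 * n_couples genotyped individuals")

    rng = substream(params.seed, "couples")
    grs_raw = np.nansum(genotypes.dosage[: 2 * n], axis=1)
    grs_std = (grs_raw - grs_raw.mean()) / grs_raw.std(ddof=1)

    own = params.alpha_g * grs_std + params.resolved_noise_sd * rng.standard_normal(2 * n)

    fem = np.arange(n)  # females
    mal = np.arange(n, 2 * n)  # males

    # --- pairing ---------------------------------------------------------
    if params.scenario in ("assortment", "mixed") and params.rho_a != 0:
        uf = _normal_scores(own[fem])
        um = _normal_scores(own[mal])
        match = params.rho_a * um + np.sqrt(1 - params.rho_a**2) * rng.standard_normal(n)
        order_f = np.argsort(uf)
        order_m = np.argsort(match)
        fem = fem[order_f]
        mal = mal[order_m]
    # otherwise leave the (already exchangeable) order as-is

    base_f, base_m = own[fem].copy(), own[mal].copy()

    # --- shared couple environment --------------------------------------
    conf = np.zeros(n)
    if params.c_share > 0:
        conf = rng.standard_normal(n)
        base_f += np.sqrt(params.c_share) * conf
        base_m += np.sqrt(params.c_share) * conf

    # --- partner interaction (simultaneous system) -----------------------
    b = params.beta_i
    if b != 0:
        if params.interaction_direction == "reciprocal":
            den = 1.0 - b * b
            x_f = (base_f + b * base_m) / den
            x_m = (base_m + b * base_f) / den
        elif params.interaction_direction == "male_to_female":
            x_m = base_m
            x_f = base_f + b * x_m
        elif params.interaction_direction == "female_to_male":
            x_f = base_f
            x_m = base_m + b * x_f
        else:
            raise ValueError("unknown interaction_direction")
    else:
        x_f, x_m = base_f, base_m

    # --- covariates -------------------------------------------------------
    mu_f, sd_f = reference.AGE_BASELINE["female"]
    age_f = rng.normal(mu_f, sd_f, n)
    age_m = age_f + rng.normal(1.7, 3.0, n)
    centre = rng.integers(0, params.n_centres, n)
    chips = np.array(["axiom", "bileve"])
    chip_f = chips[(rng.random(n) < 0.1).astype(int)]
    chip_m = chips[(rng.random(n) < 0.1).astype(int)]

    ids = genotypes.individual_id
    couples = pd.DataFrame(
        {
            "couple_id": [f"c{i + 1}" for i in range(n)],
            "id_f": ids[fem],
            "id_m": ids[mal],
            "phenotype_f": x_f,
            "phenotype_m": x_m,
            "grs_f": grs_raw[fem],
            "grs_m": grs_raw[mal],
            "grs_std_f": grs_std[fem],
            "grs_std_m": grs_std[mal],
            "age_f": age_f,
            "age_m": age_m,
            "chip_f": chip_f,
            "chip_m": chip_m,
            "centre": centre,
            "confounder": conf,
        }
    )
    for k in range(1, 11):
        couples[f"pc{k}_f"] = rng.standard_normal(n)
        couples[f"pc{k}_m"] = rng.standard_normal(n)
    return CoupleCohort(couples, params, genotypes)


# ---------------------------------------------------------------------------
# Trait battery with published-cohort-like marginals
# ---------------------------------------------------------------------------


def _threshold_ordinal(latent: np.ndarray, props) -> np.ndarray:
    cuts = stats.norm.ppf(np.cumsum(props)[:-1])
    return (np.searchsorted(cuts, latent) + 1).astype(int)


def simulate_trait_battery(
    cohort: CoupleCohort, seed: int | None = None, trait_couple_share: float = 0.05
) -> pd.DataFrame:
    """Raw questionnaire responses and accelerometer summaries per person.

    Each trait is a latent Gaussian correlated with the person's scenario
    phenotype, thresholded (ordinal/binary, sex-specific published category
    proportions as cut-points) or rescaled (continuous marginals).  A small
    trait-specific couple-shared component (``trait_couple_share`` of latent
    variance) adds same-trait spousal convergence beyond the shared scenario
    phenotype, so same-trait correlations dominate cross-trait ones.
    Returns one row per individual with UK-Biobank-style response strings,
    suitable for the questionnaire encoder, plus clean accelerometer QC
    columns.
    """
    from .phenotypes import UKB_CHRONOTYPE_LEVELS, UKB_EASE_LEVELS, UKB_INSOMNIA_LEVELS

    seed = cohort.params.seed if seed is None else seed
    rng = substream(seed, "trait-battery")
    people = cohort.to_individual_frame()
    z = (people["phenotype"] - people["phenotype"].mean()) / people["phenotype"].std(ddof=1)
    z = z.to_numpy()
    npeople = len(people)
    couple_idx = pd.Categorical(people["couple_id"]).codes
    share = trait_couple_share

    def latent(rho: float) -> np.ndarray:
        shared = rng.standard_normal(cohort.n_couples)[couple_idx]
        resid = max(0.0, 1.0 - rho**2 - share)
        return rho * z + np.sqrt(share) * shared + np.sqrt(resid) * rng.standard_normal(npeople)

    out = pd.DataFrame({"individual_id": people["individual_id"], "sex": people["sex"]})
    sexes = people["sex"].to_numpy()

    def per_sex_ordinal(props_by_sex, rho):
        lat = latent(rho)
        codes = np.empty(npeople, dtype=int)
        for s in ("female", "male"):
            mask = sexes == s
            codes[mask] = _threshold_ordinal(lat[mask], props_by_sex[s])
        return codes

    chron = per_sex_ordinal(reference.CHRONOTYPE_PROPS, 0.25)
    out["chronotype"] = [UKB_CHRONOTYPE_LEVELS[c - 1] for c in chron]
    ease = per_sex_ordinal(reference.EASE_OF_WAKING_PROPS, 0.25)
    out["ease_of_waking"] = [UKB_EASE_LEVELS[c - 1] for c in ease]
    insom = per_sex_ordinal(reference.INSOMNIA_PROPS, 0.25)
    out["insomnia"] = [UKB_INSOMNIA_LEVELS[c - 1] for c in insom]

    snore = np.empty(npeople, dtype=int)
    lat = latent(0.25)
    for s in ("female", "male"):
        mask = sexes == s
        prev = reference.snoring_prevalence(s) / 100.0
        snore[mask] = (lat[mask] > stats.norm.ppf(1 - prev)).astype(int)
    out["snoring"] = np.where(snore == 1, "Yes", "No")

    dur = np.empty(npeople)
    lat = latent(0.5)
    for s in ("female", "male"):
        mask = sexes == s
        mu, sd = reference.SLEEP_DURATION_H[s]
        dur[mask] = np.round(mu + sd * lat[mask])
    out["sleep_duration"] = np.clip(dur, 1, 23).astype(int)

    accel_loadings = {
        "l5_timing": 0.45,
        "accel_sleep_duration": 0.40,
        "sleep_episodes": 0.35,
        "sleep_efficiency": 0.30,
    }
    for trait, by_sex in reference.ACCEL_MARGINALS.items():
        lat = latent(accel_loadings[trait])
        vals = np.empty(npeople)
        for s in ("female", "male"):
            mask = sexes == s
            mu, sd = by_sex[s]
            vals[mask] = mu + sd * lat[mask]
        if trait == "sleep_efficiency":
            vals = np.clip(vals, 0.0, 1.0)
        if trait == "l5_timing":
            vals = np.clip(vals, 12.0, 36.0 - 1e-9)
        out[trait] = vals

    for flag in ("data_problem", "poor_wear", "poor_calibration", "calibration_other_data"):
        out[flag] = False
    for cnt in ("recording_errors", "interrupted_periods", "interrupted_duration"):
        out[cnt] = rng.poisson(1.0, npeople)
    return out


# ---------------------------------------------------------------------------
# Household descriptor table (spouse-pairing fixture)
# ---------------------------------------------------------------------------


@dataclass
class HouseholdSim:
    households: pd.DataFrame
    ibd: pd.DataFrame
    true_pairs: pd.DataFrame
    decoys: pd.DataFrame  # individual_id, decoy_type


def _household_rows(rng, ids, sexes, north, east, centre, **overrides):
    shared = dict(
        lives_with="spouse",
        years_at_address=int(rng.integers(1, 41)),
        n_occupants=int(rng.integers(2, 6)),
        n_vehicles=int(rng.integers(0, 4)),
        accommodation_type=str(rng.choice(["house", "flat"])),
        rental_status=str(rng.choice(["own", "rent"])),
        north=int(north),
        east=int(east),
        centre=int(centre),
        genotyped=True,
    )
    shared.update(overrides)
    rows = []
    for ind, sex in zip(ids, sexes):
        row = dict(individual_id=ind, sex=sex, **shared)
        row["paternal_death_age"] = (
            float(rng.integers(50, 95)) if rng.random() < 0.6 else np.nan
        )
        row["maternal_death_age"] = (
            float(rng.integers(50, 95)) if rng.random() < 0.6 else np.nan
        )
        rows.append(row)
    return rows


def simulate_household_table(
    cohort: CoupleCohort, decoy_spec: dict | None = None, seed: int | None = None
) -> HouseholdSim:
    """Household descriptors for every cohort member, plus labelled decoys.

    True couples share every matching field and get unique 1-km coordinates.
    ``decoy_spec`` counts decoy constructs to inject: ``triples`` (three
    people with identical descriptors), ``same_sex`` pairs, ``high_ibd``
    pairs (relatedness 0.15 in the IBD table), ``parental_death`` pairs
    (identical paternal and maternal ages at death) and ``singles``.
    """
    seed = cohort.params.seed if seed is None else seed
    rng = substream(seed, "households")
    spec = dict(triples=0, same_sex=0, high_ibd=0, parental_death=0, singles=0)
    spec.update(decoy_spec or {})

    n = cohort.n_couples
    coords = rng.choice(
        4_000_000, size=n + sum(spec.values()) + 8, replace=False
    )  # unique flattened 1-km grid cells
    rows: list[dict] = []
    ibd_rows: list[dict] = []
    decoys: list[dict] = []

    for i, rec in enumerate(cohort.couples.itertuples(index=False)):
        north, east = divmod(int(coords[i]), 2000)
        rows.extend(
            _household_rows(
                rng,
                [rec.id_f, rec.id_m],
                ["female", "male"],
                north,
                east,
                rec.centre,
            )
        )
        ibd_rows.append(
            dict(id_a=rec.id_f, id_b=rec.id_m, ibd1=0.0, ibd2=0.0, relatedness=0.0)
        )

    k = n
    uid = 0

    def next_ids(m):
        nonlocal uid
        out = [f"decoy{uid + j + 1}" for j in range(m)]
        uid += m
        return out

    def coord():
        nonlocal k
        c = divmod(int(coords[k]), 2000)
        k += 1
        return c

    for _ in range(spec["triples"]):
        ids = next_ids(3)
        north, east = coord()
        rows.extend(
            _household_rows(rng, ids, ["female", "male", "male"], north, east, 0)
        )
        decoys.extend(dict(individual_id=i, decoy_type="triple") for i in ids)
    for _ in range(spec["same_sex"]):
        ids = next_ids(2)
        north, east = coord()
        rows.extend(_household_rows(rng, ids, ["female", "female"], north, east, 1))
        decoys.extend(dict(individual_id=i, decoy_type="same_sex") for i in ids)
    for _ in range(spec["high_ibd"]):
        ids = next_ids(2)
        north, east = coord()
        rows.extend(_household_rows(rng, ids, ["female", "male"], north, east, 2))
        ibd_rows.append(
            dict(id_a=ids[0], id_b=ids[1], ibd1=0.5, ibd2=0.0, relatedness=0.15)
        )
        decoys.extend(dict(individual_id=i, decoy_type="high_ibd") for i in ids)
    for _ in range(spec["parental_death"]):
        ids = next_ids(2)
        north, east = coord()
        pair_rows = _household_rows(rng, ids, ["female", "male"], north, east, 3)
        pat, mat = float(rng.integers(50, 95)), float(rng.integers(50, 95))
        for r in pair_rows:
            r["paternal_death_age"] = pat
            r["maternal_death_age"] = mat
        rows.extend(pair_rows)
        decoys.extend(dict(individual_id=i, decoy_type="parental_death") for i in ids)
    for _ in range(spec["singles"]):
        ids = next_ids(1)
        north, east = coord()
        rows.extend(_household_rows(rng, ids, ["female"], north, east, 4))
        decoys.extend(dict(individual_id=i, decoy_type="single") for i in ids)

    households = pd.DataFrame(rows)
    ibd = pd.DataFrame(ibd_rows)
    true_pairs = cohort.couples[["id_f", "id_m"]].rename(
        columns={"id_f": "female_id", "id_m": "male_id"}
    )
    return HouseholdSim(households, ibd, true_pairs, pd.DataFrame(decoys))


# ---------------------------------------------------------------------------
# Parent-offspring trios with IBD summaries
# ---------------------------------------------------------------------------


@dataclass
class TrioSim:
    ibd: pd.DataFrame
    genotypes: GenotypeMatrix
    truth: pd.DataFrame  # child_id, mother_id, father_id
    decoys: pd.DataFrame


def mendelian_child(rng, mother: np.ndarray, father: np.ndarray) -> np.ndarray:
    """One transmitted allele per parent: Bernoulli(dosage / 2) each."""
    return (
        rng.binomial(1, mother / 2.0) + rng.binomial(1, father / 2.0)
    ).astype(float)


def simulate_trios(
    n_trios: int,
    decoy_spec: dict | None = None,
    seed: int = 0,
    n_snps: int = 120,
    maf_spec=("uniform", 0.31, 0.5),
) -> TrioSim:
    """Parent-offspring trios: Mendelian child genotypes + IBD summaries.

    True parent-child pairs get IBD1 near 1 and IBD2 near 0; the two parents
    share essentially nothing. Decoys (counts in ``decoy_spec``): ``sibling``
    — a sib of the index offered as candidate parent (IBD1 ~ 0.5,
    IBD2 ~ 0.25); ``related_parents`` — a trio whose candidate parents share
    30% of their genome IBD1 with each other; ``weak_parent`` — a candidate
    whose IBD1 with the index falls below the detection threshold.
    """
    if n_trios < 1:
        raise ValueError("n_trios must be >= 1")
    spec = dict(sibling=0, related_parents=0, weak_parent=0)
    spec.update(decoy_spec or {})
    rng = substream(seed, "trios")

    parents = simulate_genotypes(
        2 * (n_trios + spec["related_parents"]),
        n_snps,
        maf_spec,
        seed=seed,
        id_prefix="par",
    )
    variants = parents.variants

    def jitter(x, lo=0.0, hi=1.0):
        return float(np.clip(x + rng.normal(0, 0.005), lo, hi))

    dosages = [parents.dosage]
    ids = list(parents.individual_id)
    ibd_rows: list[dict] = []
    truth_rows: list[dict] = []
    decoys: list[dict] = []

    total = n_trios + spec["related_parents"]
    for t in range(total):
        mo, fa = ids[2 * t], ids[2 * t + 1]
        child = f"child{t + 1}"
        c_dos = mendelian_child(rng, parents.dosage[2 * t], parents.dosage[2 * t + 1])
        dosages.append(c_dos[None, :])
        ids.append(child)
        for par in (mo, fa):
            ibd2 = jitter(0.005)
            ibd_rows.append(
                dict(
                    id_a=child,
                    id_b=par,
                    ibd1=min(jitter(0.99), 1.0 - ibd2),
                    ibd2=ibd2,
                    relatedness=0.5,
                )
            )
        mutual = 0.30 if t >= n_trios else jitter(0.01)
        ibd_rows.append(
            dict(id_a=mo, id_b=fa, ibd1=mutual, ibd2=0.0, relatedness=mutual / 2)
        )
        if t >= n_trios:
            decoys.append(dict(individual_id=child, decoy_type="related_parents"))
        else:
            truth_rows.append(dict(child_id=child, mother_id=mo, father_id=fa))

    for s in range(spec["sibling"]):
        t = s % n_trios
        sib = f"sib{s + 1}"
        s_dos = mendelian_child(rng, parents.dosage[2 * t], parents.dosage[2 * t + 1])
        dosages.append(s_dos[None, :])
        ids.append(sib)
        child = f"child{t + 1}"
        # sib offered as a candidate parent of the index child
        ibd_rows.append(
            dict(id_a=child, id_b=sib, ibd1=jitter(0.5), ibd2=jitter(0.25), relatedness=0.5)
        )
        decoys.append(dict(individual_id=sib, decoy_type="sibling"))

    for w in range(spec["weak_parent"]):
        t = w % n_trios
        weak = f"weak{w + 1}"
        dosages.append(
            rng.binomial(2, variants["maf"].to_numpy(), size=(1, n_snps)).astype(float)
        )
        ids.append(weak)
        ibd_rows.append(
            dict(
                id_a=f"child{t + 1}",
                id_b=weak,
                ibd1=0.40,
                ibd2=0.0,
                relatedness=0.2,
            )
        )
        decoys.append(dict(individual_id=weak, decoy_type="weak_parent"))

    geno = GenotypeMatrix(np.array(ids), variants.copy(), np.vstack(dosages))
    return TrioSim(
        pd.DataFrame(ibd_rows), geno, pd.DataFrame(truth_rows), pd.DataFrame(decoys)
    )
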
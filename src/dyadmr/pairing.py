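"""Spouse-pair and parent-pair inference.

Spouse pairs are reconstructed from household descriptors: two genotyped
individuals who report living with their spouse and agree exactly on every
matching field (years at address, occupants, vehicles, accommodation type,
rental status, 1-km home coordinates, recruitment centre) form a candidate
couple.  Candidates are then excluded — with a rule tag logged per person —
when more than two people share identical descriptors, when the pair is
same-sex, when both reported parental ages at death coincide across the
pair (suggesting siblings), or when genetic relatedness exceeds 0.1.

Mother-father pairs are recovered from pairwise IBD summaries: candidate
parents share at least 42.5% of the genome IBD1 and at most 10% IBD2 with
the index individual, the two candidate parents share at most 20% IBD1
with each other, and the trio must be Mendelian-concordant on at least 95
of 100 high-frequency, well-called SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from ._utils import substream
from .simulate import GenotypeMatrix

MATCH_FIELDS = (
    "years_at_address",
    "n_occupants",
    "n_vehicles",
    "accommodation_type",
    "rental_status",
    "north",
    "east",
    "centre",
)

HOUSEHOLD_COLUMNS = MATCH_FIELDS + (
    "individual_id",
    "lives_with",
    "sex",
    "paternal_death_age",
    "maternal_death_age",
    "genotyped",
)

RELATEDNESS_MAX = 0.1
IBD1_PARENT_MIN = 0.425
IBD2_PARENT_MAX = 0.10
IBD1_COPARENT_MAX = 0.20
CONCORDANCE_MARKERS = 100
CONCORDANCE_MIN = 95
MARKER_MAF_MIN = 0.3
MARKER_CALL_RATE_MIN = 0.999


@dataclass
class PairResult:
    pairs: pd.DataFrame  # index_id, spouse_id, female_id, male_id
    exclusions: pd.DataFrame  # individual_id, rule

    def write(self, pairs_path, log_path) -> None:
        self.pairs.to_csv(pairs_path, sep="\t", index=False)
        self.exclusions.to_csv(log_path, sep="\t", index=False)


def _pair_relatedness(ibd: pd.DataFrame | None) -> dict:
    if ibd is None or len(ibd) == 0:
        return {}
    rel = {}
    col = "relatedness" if "relatedness" in ibd.columns else None
    for row in ibd.itertuples(index=False):
        key = frozenset((row.id_a, row.id_b))
        val = getattr(row, col) if col else row.ibd1 / 2 + row.ibd2
        rel[key] = max(rel.get(key, 0.0), float(val))
    return rel


def derive_spouse_pairs(
    households: pd.DataFrame, ibd: pd.DataFrame | None = None
) -> PairResult:
    """Reconstruct spouse pairs from household descriptors.

    Matching is exact equality on every field in ``MATCH_FIELDS``; no
    tolerance is applied (coordinates are already 1-km quantised upstream).
    Returns accepted pairs and an exhaustive per-individual exclusion log.
    """
    missing = [c for c in HOUSEHOLD_COLUMNS if c not in households.columns]
    if missing:
        raise KeyError(f"household table is missing required columns: {missing}")

    excl: list[dict] = []

    def log(ids, rule):
        excl.extend(dict(individual_id=i, rule=rule) for i in ids)

    df = households.copy()
    dup = df["individual_id"].duplicated(keep=False)
    if dup.any():
        dupped = df.loc[dup, "individual_id"].unique()
        log(dupped, "duplicate_record")
        df = df[~df["individual_id"].isin(dupped)]

    not_spouse = df["lives_with"] != "spouse"
    log(df.loc[not_spouse, "individual_id"], "not_living_with_spouse")
    df = df[~not_spouse]
    not_geno = ~df["genotyped"].astype(bool)
    log(df.loc[not_geno, "individual_id"], "not_genotyped")
    df = df[~not_geno]

    relmap = _pair_relatedness(ibd)
    pairs: list[dict] = []
    for _, grp in df.groupby(list(MATCH_FIELDS), sort=False):
        ids = grp["individual_id"].tolist()
        if len(grp) == 1:
            log(ids, "no_matching_cohabitant")
            continue
        if len(grp) > 2:
            log(ids, "more_than_two_matching")
            continue
        a, b = grp.iloc[0], grp.iloc[1]
        if a["sex"] == b["sex"]:
            log(ids, "same_sex")
            continue
        pat = (a["paternal_death_age"], b["paternal_death_age"])
        mat = (a["maternal_death_age"], b["maternal_death_age"])
        if (
            np.isfinite(pat).all()
            and np.isfinite(mat).all()
            and pat[0] == pat[1]
            and mat[0] == mat[1]
        ):
            log(ids, "identical_parental_death_ages")
            continue
        if relmap.get(frozenset(ids), 0.0) > RELATEDNESS_MAX:
            log(ids, "relatedness")
            continue
        female, male = (a, b) if a["sex"] == "female" else (b, a)
        pairs.append(
            dict(
                index_id=female["individual_id"],
                spouse_id=male["individual_id"],
                female_id=female["individual_id"],
                male_id=male["individual_id"],
            )
        )

    pair_df = pd.DataFrame(pairs, columns=["index_id", "spouse_id", "female_id", "male_id"])
    # conservative guard: an individual matched into two couples discards all
    flat = pd.concat([pair_df["female_id"], pair_df["male_id"]])
    multi = set(flat[flat.duplicated(keep=False)])
    if multi:
        hit = pair_df["female_id"].isin(multi) | pair_df["male_id"].isin(multi)
        for row in pair_df[hit].itertuples(index=False):
            log([row.female_id, row.male_id], "ambiguous_multiple_candidates")
        pair_df = pair_df[~hit].reset_index(drop=True)

    excl_df = pd.DataFrame(excl, columns=["individual_id", "rule"])
    return PairResult(pair_df, excl_df)


# ---------------------------------------------------------------------------
# Trio identification from IBD
# ---------------------------------------------------------------------------


@dataclass
class TrioSet:
    trios: pd.DataFrame
    # child_id, parent_a, parent_b, ibd-rule flags, ambiguous flag

    @property
    def accepted(self) -> pd.DataFrame:
        t = self.trios
        return t[t["accepted"]].reset_index(drop=True)


def _symmetric_lookup(ibd: pd.DataFrame):
    table: dict = {}
    for row in ibd.itertuples(index=False):
        table[frozenset((row.id_a, row.id_b))] = (float(row.ibd1), float(row.ibd2))
    return table


def identify_trios(ibd: pd.DataFrame) -> TrioSet:
    """Candidate parent pairs per index individual from IBD sharing.

    A candidate parent shares >= 42.5% IBD1 and <= 10% IBD2 with the index;
    a retained parent pair shares <= 20% IBD1 with each other.  If several
    parent pairs survive for one index the child is flagged ambiguous and
    none is accepted.
    """
    for c in ("id_a", "id_b", "ibd1", "ibd2"):
        if c not in ibd.columns:
            raise KeyError(f"IBD table is missing column {c!r}")
    lookup = _symmetric_lookup(ibd)
    candidates: dict[str, list[str]] = {}
    for row in ibd.itertuples(index=False):
        for index, other in ((row.id_a, row.id_b), (row.id_b, row.id_a)):
            if row.ibd1 >= IBD1_PARENT_MIN and row.ibd2 <= IBD2_PARENT_MAX:
                candidates.setdefault(index, []).append(other)

    rows: list[dict] = []
    for child, cands in sorted(candidates.items()):
        valid_pairs = []
        for pa, pb in combinations(sorted(set(cands)), 2):
            mutual = lookup.get(frozenset((pa, pb)), (0.0, 0.0))
            if mutual[0] <= IBD1_COPARENT_MAX:
                valid_pairs.append((pa, pb, mutual[0]))
        ambiguous = len(valid_pairs) > 1
        for pa, pb, mutual1 in valid_pairs:
            rows.append(
                dict(
                    child_id=child,
                    parent_a=pa,
                    parent_b=pb,
                    mutual_ibd1=mutual1,
                    ambiguous=ambiguous,
                    accepted=not ambiguous,
                )
            )
    cols = ["child_id", "parent_a", "parent_b", "mutual_ibd1", "ambiguous", "accepted"]
    return TrioSet(pd.DataFrame(rows, columns=cols))


# ---------------------------------------------------------------------------
# Mendelian concordance
# ---------------------------------------------------------------------------


def _transmissible(dosage: float) -> tuple:
    # alleles a parent with this effect-allele count can transmit
    return {0.0: (0,), 1.0: (0, 1), 2.0: (1,)}[float(dosage)]


def trio_concordant(child: float, mother: float, father: float) -> bool:
    """Is the child dosage producible from one allele per parent?"""
    if any(np.isnan([child, mother, father])):
        return False
    return any(
        a + b == child for a in _transmissible(mother) for b in _transmissible(father)
    )


def select_concordance_markers(
    genotypes: GenotypeMatrix,
    n_markers: int = CONCORDANCE_MARKERS,
    maf_min: float = MARKER_MAF_MIN,
    call_rate_min: float = MARKER_CALL_RATE_MIN,
    seed: int = 0,
) -> np.ndarray:
    """Random well-called common markers for the concordance check."""
    call_rate = 1.0 - np.isnan(genotypes.dosage).mean(axis=0)
    ok = (genotypes.variants["maf"].to_numpy() > maf_min) & (call_rate >= call_rate_min)
    idx = np.flatnonzero(ok)
    if len(idx) < n_markers:
        raise ValueError(
            f"only {len(idx)} variants pass MAF > {maf_min} and call rate "
            f">= {call_rate_min}; {n_markers} required"
        )
    rng = substream(seed, "concordance-markers")
    return np.sort(rng.choice(idx, size=n_markers, replace=False))


def mendelian_concordance_check(
    child: np.ndarray,
    mother: np.ndarray,
    father: np.ndarray,
    min_concordant: int = CONCORDANCE_MIN,
) -> tuple[int, bool]:
    """Count concordant markers across a trio; accept at >= 95/100."""
    child = np.asarray(child, dtype=float)
    mother = np.asarray(mother, dtype=float)
    father = np.asarray(father, dtype=float)
    if not (len(child) == len(mother) == len(father)):
        raise ValueError("trio genotype vectors differ in length")
    count = sum(trio_concordant(c, m, f) for c, m, f in zip(child, mother, father))
    return count, count >= min_concordant


def confirm_trios(
    trio_set: TrioSet, genotypes: GenotypeMatrix, seed: int = 0
) -> pd.DataFrame:
    """Apply the Mendelian concordance filter to IBD-accepted trios."""
    markers = select_concordance_markers(genotypes, seed=seed)
    ids = pd.Index(genotypes.individual_id)
    out = []
    for row in trio_set.accepted.itertuples(index=False):
        trio_idx = ids.get_indexer([row.child_id, row.parent_a, row.parent_b])
        if (trio_idx < 0).any():
            continue
        c, m, f = (genotypes.dosage[i][markers] for i in trio_idx)
        count, ok = mendelian_concordance_check(c, m, f)
        out.append(
            dict(
                child_id=row.child_id,
                parent_a=row.parent_a,
                parent_b=row.parent_b,
                concordant=count,
                tested=len(markers),
                accepted=ok,
            )
        )
    return pd.DataFrame(
        out, columns=["child_id", "parent_a", "parent_b", "concordant", "tested", "accepted"]
    )
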
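"""Spouse-pair derivation, trio identification and Mendelian concordance."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dyadmr import (
    ScenarioParams,
    derive_spouse_pairs,
    identify_trios,
    mendelian_concordance_check,
    simulate_couples,
    simulate_household_table,
    simulate_trios,
)
from dyadmr.pairing import (
    confirm_trios,
    select_concordance_markers,
    trio_concordant,
)


def _household_row(ind, sex, **over):
    row = dict(
        individual_id=ind, sex=sex, lives_with="spouse", years_at_address=5,
        n_occupants=2, n_vehicles=1, accommodation_type="house",
        rental_status="own", north=100, east=200, centre=3,
        paternal_death_age=np.nan, maternal_death_age=np.nan, genotyped=True,
    )
    row.update(over)
    return row


class TestDeriveSpousePairs:
    def test_matching_opposite_sex_pair_accepted(self):
        hh = pd.DataFrame([_household_row("a", "female"), _household_row("b", "male")])
        res = derive_spouse_pairs(hh)
        assert len(res.pairs) == 1
        assert res.pairs.female_id.iloc[0] == "a"
        assert res.pairs.male_id.iloc[0] == "b"

    def test_high_relatedness_excluded_with_rule(self):
        hh = pd.DataFrame([_household_row("a", "female"), _household_row("b", "male")])
        ibd = pd.DataFrame(
            [dict(id_a="a", id_b="b", ibd1=0.5, ibd2=0.0, relatedness=0.15)]
        )
        res = derive_spouse_pairs(hh, ibd)
        assert len(res.pairs) == 0
        assert set(res.exclusions.rule) == {"relatedness"}

    def test_three_identical_descriptors_yield_no_pairs(self):
        hh = pd.DataFrame(
            [
                _household_row("a", "female"),
                _household_row("b", "male"),
                _household_row("c", "male"),
            ]
        )
        res = derive_spouse_pairs(hh)
        assert len(res.pairs) == 0
        assert (res.exclusions.rule == "more_than_two_matching").all()
        assert set(res.exclusions.individual_id) == {"a", "b", "c"}

    def test_same_sex_pair_excluded(self):
        hh = pd.DataFrame([_household_row("a", "female"), _household_row("b", "female")])
        res = derive_spouse_pairs(hh)
        assert len(res.pairs) == 0
        assert set(res.exclusions.rule) == {"same_sex"}

    def test_identical_parental_death_ages_excluded(self):
        hh = pd.DataFrame(
            [
                _household_row("a", "female", paternal_death_age=80.0, maternal_death_age=75.0),
                _household_row("b", "male", paternal_death_age=80.0, maternal_death_age=75.0),
            ]
        )
        res = derive_spouse_pairs(hh)
        assert len(res.pairs) == 0
        assert set(res.exclusions.rule) == {"identical_parental_death_ages"}

    def test_missing_parental_age_does_not_fire_rule(self):
        hh = pd.DataFrame(
            [
                _household_row("a", "female", paternal_death_age=80.0),
                _household_row("b", "male", paternal_death_age=80.0),
            ]
        )
        assert len(derive_spouse_pairs(hh).pairs) == 1

    def test_mismatched_field_prevents_pairing(self):
        hh = pd.DataFrame(
            [_household_row("a", "female"), _household_row("b", "male", n_vehicles=2)]
        )
        res = derive_spouse_pairs(hh)
        assert len(res.pairs) == 0
        assert (res.exclusions.rule == "no_matching_cohabitant").all()

    def test_missing_column_is_schema_error(self):
        hh = pd.DataFrame([_household_row("a", "female")]).drop(columns=["north"])
        with pytest.raises(KeyError):
            derive_spouse_pairs(hh)

    def test_planted_cohort_recovered_and_decoys_rejected(self):
        params = ScenarioParams(scenario="null", n_couples=150, seed=21)
        cohort = simulate_couples(params)
        sim = simulate_household_table(
            cohort,
            dict(triples=2, same_sex=2, high_ibd=2, parental_death=2, singles=2),
        )
        res = derive_spouse_pairs(sim.households, sim.ibd)
        truth = set(map(tuple, sim.true_pairs[["female_id", "male_id"]].values))
        got = set(map(tuple, res.pairs[["female_id", "male_id"]].values))
        assert got == truth  # sensitivity 1.0, zero decoys accepted
        decoy_ids = set(sim.decoys.individual_id)
        assert decoy_ids.isdisjoint(set(res.pairs.female_id) | set(res.pairs.male_id))

    def test_exclusion_log_partitions_rejected_candidates(self):
        params = ScenarioParams(scenario="null", n_couples=40, seed=22)
        cohort = simulate_couples(params)
        sim = simulate_household_table(cohort, dict(triples=1, same_sex=1, singles=1))
        res = derive_spouse_pairs(sim.households, sim.ibd)
        accepted = set(res.pairs.female_id) | set(res.pairs.male_id)
        rejected = set(sim.households.individual_id) - accepted
        assert rejected == set(res.exclusions.individual_id)


class TestIdentifyTrios:
    def _ibd(self, rows):
        return pd.DataFrame(rows, columns=["id_a", "id_b", "ibd1", "ibd2"])

    def test_valid_trio_retained(self):
        ibd = self._ibd(
            [
                ("child", "mo", 0.50, 0.05),
                ("child", "fa", 0.50, 0.05),
                ("mo", "fa", 0.05, 0.0),
            ]
        )
        acc = identify_trios(ibd).accepted
        assert len(acc) == 1
        assert {acc.parent_a.iloc[0], acc.parent_b.iloc[0]} == {"mo", "fa"}

    def test_low_ibd1_candidate_rejected(self):
        ibd = self._ibd(
            [
                ("child", "mo", 0.40, 0.05),  # below 42.5% bound
                ("child", "fa", 0.50, 0.05),
                ("mo", "fa", 0.05, 0.0),
            ]
        )
        assert len(identify_trios(ibd).accepted) == 0

    def test_high_ibd2_candidate_rejected(self):
        # a sibling shares IBD2 ~ 0.25 with the index
        ibd = self._ibd(
            [
                ("child", "sib", 0.50, 0.25),
                ("child", "fa", 0.50, 0.05),
                ("sib", "fa", 0.05, 0.0),
            ]
        )
        assert len(identify_trios(ibd).accepted) == 0

    def test_related_parent_pair_rejected(self):
        ibd = self._ibd(
            [
                ("child", "mo", 0.50, 0.05),
                ("child", "fa", 0.50, 0.05),
                ("mo", "fa", 0.30, 0.0),  # above the 20% co-parent bound
            ]
        )
        assert len(identify_trios(ibd).accepted) == 0

    def test_simulated_decoys_filtered(self):
        sim = simulate_trios(
            6, dict(sibling=2, related_parents=1, weak_parent=1), seed=31
        )
        acc = confirm_trios(identify_trios(sim.ibd), sim.genotypes, seed=0)
        acc = acc[acc.accepted]
        truth = {
            (r.child_id, frozenset((r.mother_id, r.father_id)))
            for r in sim.truth.itertuples(index=False)
        }
        got = {
            (r.child_id, frozenset((r.parent_a, r.parent_b)))
            for r in acc.itertuples(index=False)
        }
        assert got == truth


def _enumeration_oracle(c, m, f):
    """Brute force over transmitted-allele outcomes."""
    tm = {0: [0], 1: [0, 1], 2: [1]}
    return any(a + b == c for a in tm[m] for b in tm[f])


class TestMendelianConcordance:
    def test_forced_transmission_concordant(self):
        assert trio_concordant(1, 0, 2)

    def test_impossible_transmission_discordant(self):
        assert not trio_concordant(2, 0, 2)

    def test_all_27_combinations_match_enumeration_oracle(self):
        for c, m, f in itertools.product((0, 1, 2), repeat=3):
            assert trio_concordant(c, m, f) == _enumeration_oracle(c, m, f)

    def test_acceptance_threshold(self):
        child = np.ones(100)
        mother = np.ones(100)
        father = np.ones(100)
        child[:6] = 2
        mother[:6] = 0
        father[:6] = 0  # six impossible markers
        count, ok = mendelian_concordance_check(child, mother, father)
        assert count == 94 and not ok
        child[0] = 0  # now producible from two dosage-0 parents
        count, ok = mendelian_concordance_check(child, mother, father)
        assert count == 95 and ok

    def test_insufficient_markers_error(self):
        sim = simulate_trios(2, seed=40, n_snps=50)
        with pytest.raises(ValueError, match="pass"):
            select_concordance_markers(sim.genotypes)
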
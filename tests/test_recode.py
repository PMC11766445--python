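"""Synonymous Q-codon mutation and the profile-guided recoder."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codonmod import (
    CodingSequence,
    RecodeRule,
    default_q_rules,
    mutate_q_codons,
    profile_guided_recode,
    translate,
)
from codonmod.recode import RecodeError, gc_content

from conftest import TOY_NAY_CENSUS, random_cds


class TestMutateQCodons:
    def test_all_c_to_u(self, table):
        cds = CodingSequence("x", "ATGAACGACCACTACTAA")
        mutated, report = mutate_q_codons(cds, table, "ALL", "C_to_U")
        assert mutated.sequence == "ATGAATGATCATTATTAA"
        assert report.n_codons_changed == 4
        assert report.protein_identical
        assert translate(mutated, table) == "MNDHY"

    def test_subset_tyr_only(self, table):
        cds = CodingSequence("x", "ATGAACGACCACTACTAA")
        mutated, report = mutate_q_codons(cds, table, {"Y"}, "C_to_U")
        assert report.n_codons_changed == 1
        assert mutated.sequence == "ATGAACGACCACTATTAA"
        assert report.changes_by_amino_acid == {"Y": 1}

    def test_no_nay_codons_is_identity(self, table):
        cds = CodingSequence("x", "ATGGGGCCCTAA")
        mutated, report = mutate_q_codons(cds, table, "ALL", "C_to_U")
        assert mutated.sequence == cds.sequence
        assert report.n_codons_changed == 0

    def test_only_third_positions_touched(self, table):
        cds = CodingSequence("x", "ATGAACGACCACTACTAA")
        mutated, report = mutate_q_codons(cds, table, "ALL", "C_to_U")
        for idx, old, new in report.changed_positions:
            assert old[:2] == new[:2] and old[2] != new[2]

    def test_invalid_inputs(self, table):
        cds = CodingSequence("x", "ATGTAA")
        with pytest.raises(RecodeError, match="direction"):
            mutate_q_codons(cds, table, "ALL", "sideways")
        with pytest.raises(RecodeError, match="subset"):
            mutate_q_codons(cds, table, {"K"}, "C_to_U")

    def test_toy_fluorophore_census(self, table, toy_fluorophore):
        """Mutate-all changes exactly the independently counted NAY census."""
        seq = toy_fluorophore.sequence
        census = {
            codon: sum(
                seq[i : i + 3] == codon for i in range(0, len(seq), 3)
            )
            for codon in ("AAC", "GAC", "CAC", "TAC")
        }
        assert census == TOY_NAY_CENSUS
        mutated, report = mutate_q_codons(toy_fluorophore, table, "ALL", "C_to_U")
        assert report.n_codons_changed == sum(census.values())
        assert report.changes_by_amino_acid == {
            "N": census["AAC"], "D": census["GAC"],
            "H": census["CAC"], "Y": census["TAC"],
        }
        assert translate(mutated, table) == translate(toy_fluorophore, table)

    def test_round_trip_restores_all_c(self, table, toy_fluorophore):
        to_u, _ = mutate_q_codons(toy_fluorophore, table, "ALL", "C_to_U")
        back, _ = mutate_q_codons(to_u, table, "ALL", "U_to_C")
        assert back.sequence == toy_fluorophore.sequence  # census is all-C
        again, rep = mutate_q_codons(back, table, "ALL", "U_to_C")
        assert rep.n_codons_changed == 0  # fixed point

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_round_trip_and_translation_property(self, table, seed):
        cds = random_cds(np.random.default_rng(seed), table, 100)
        protein = translate(cds, table, strict=False)
        to_u, _ = mutate_q_codons(cds, table, "ALL", "C_to_U")
        to_c, _ = mutate_q_codons(to_u, table, "ALL", "U_to_C")
        assert translate(to_u, table, strict=False) == protein
        assert translate(to_c, table, strict=False) == protein
        # after the round trip every NAY codon is C-ending; repeating U_to_C
        # changes nothing (fixed point)
        again, rep = mutate_q_codons(to_c, table, "ALL", "U_to_C")
        assert rep.n_codons_changed == 0

    def test_all_equals_sum_of_subsets(self, table):
        rng = np.random.default_rng(77)
        cds = random_cds(rng, table, 200)
        _, rep_all = mutate_q_codons(cds, table, "ALL", "C_to_U")
        per_aa = sum(
            mutate_q_codons(cds, table, {aa}, "C_to_U")[1].n_codons_changed
            for aa in "NDHY"
        )
        assert rep_all.n_codons_changed == per_aa

    def test_gc_delta_equals_swap_balance(self, table):
        rng = np.random.default_rng(78)
        cds = random_cds(rng, table, 200)
        mutated, report = mutate_q_codons(cds, table, "ALL", "C_to_U")
        c_to_t = sum(1 for _, old, new in report.changed_positions if old[2] == "C")
        t_to_c = sum(1 for _, old, new in report.changed_positions if old[2] == "T")
        delta_gc = gc_content(mutated) * len(mutated.sequence) - gc_content(
            cds
        ) * len(cds.sequence)
        assert round(delta_gc) == -c_to_t + t_to_c


class TestProfileGuidedRecode:
    def test_high_z_prefers_c_ending(self, table):
        cds = CodingSequence("x", "ATGAATGACCATTACTAA")
        mutated, _ = profile_guided_recode(cds, table, {"Q": 1.5}, threshold=0.0)
        assert mutated.sequence == "ATGAACGACCACTACTAA"

    def test_low_z_prefers_t_ending(self, table):
        cds = CodingSequence("x", "ATGAATGACCATTACTAA")
        mutated, _ = profile_guided_recode(cds, table, {"Q": -1.5}, threshold=0.0)
        assert mutated.sequence == "ATGAATGATCATTATTAA"

    def test_infinite_threshold_always_alternative(self, table):
        cds = CodingSequence("x", "ATGAACTAA")
        mutated, _ = profile_guided_recode(
            cds, table, {"Q": 10.0}, threshold=float("inf")
        )
        assert mutated.sequence == "ATGAATTAA"

    def test_multi_codon_family_via_explicit_rule(self, table):
        rules = (RecodeRule("mcm5U", "E", "GAA", "GAG"),)
        cds = CodingSequence("x", "ATGGAGGAATAA")
        mutated, report = profile_guided_recode(
            cds, table, {"mcm5U": 2.0}, rules=rules
        )
        assert mutated.sequence == "ATGGAAGAATAA"
        assert report.n_codons_changed == 1

    def test_single_codon_family_rule_rejected(self, table):
        rules = (RecodeRule("Q", "W", "TGG", "TGG"),)
        with pytest.raises(RecodeError, match="single-codon"):
            profile_guided_recode(
                CodingSequence("x", "ATGTAA"), table, {"Q": 1.0}, rules=rules
            )

    def test_missing_zscore_rejected(self, table):
        with pytest.raises(RecodeError, match="Z-score"):
            profile_guided_recode(CodingSequence("x", "ATGTAA"), table, {})

    def test_default_rules_cover_four_families(self, table):
        rules = default_q_rules(table)
        assert {r.amino_acid for r in rules} == {"N", "D", "H", "Y"}
        for rule in rules:
            assert rule.preferred[2] == "C" and rule.alternative[2] == "T"
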
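import logging

import pytest
from Bio.Seq import Seq

from abescan.library import (
    AMINO_ACIDS,
    AminoAcidVariant,
    LibraryError,
    back_translate,
    emit_oligos,
    enumerate_back_mutations,
    enumerate_charge_swap,
    enumerate_range_scan,
    enumerate_site_saturation,
)
from helpers import range_scan_oracle, site_saturation_oracle


class TestVariantModel:
    def test_substitutions_canonically_sorted(self, tada8e):
        v = AminoAcidVariant.build(
            tada8e, [(149, "Y", "W"), (111, "R", "K")], "charge_swap"
        )
        assert [s[0] for s in v.substitutions] == [111, 149]
        assert v.variant_id == "R111K+Y149W"

    def test_parent_mismatch_rejected(self, tada8e):
        with pytest.raises(LibraryError, match="parent has"):
            AminoAcidVariant.build(tada8e, [(111, "K", "H")], "charge_swap")

    def test_identity_substitution_rejected(self, tada8e):
        with pytest.raises(LibraryError, match="identity"):
            AminoAcidVariant.build(tada8e, [(111, "R", "R")], "charge_swap")


class TestRangeScan:
    def test_full_range_matches_pair_grid_oracle(self, tada8e):
        variants = enumerate_range_scan(tada8e, 106, 157)
        expected = range_scan_oracle(tada8e, 106, 157, AMINO_ACIDS)
        assert {frozenset(v.substitutions) for v in variants} == expected
        assert len(variants) == len(expected) == 989

    def test_single_position(self, tada8e):
        variants = enumerate_range_scan(tada8e, 111, 111)
        assert len(variants) == 20
        assert sum(v.is_identity for v in variants) == 1

    def test_empty_alphabet(self, tada8e):
        assert enumerate_range_scan(tada8e, 106, 157, alphabet="") == []

    def test_out_of_bounds_range(self, tada8e):
        with pytest.raises(LibraryError):
            enumerate_range_scan(tada8e, 150, len(tada8e) + 5)

    def test_no_duplicate_ids(self, tada8e):
        variants = enumerate_range_scan(tada8e, 106, 157)
        assert len({v.variant_id for v in variants}) == len(variants)


class TestSiteSaturation:
    def test_three_sites_match_nested_loop_oracle(self, tada8e):
        variants = enumerate_site_saturation(tada8e, [111, 119, 149])
        expected = site_saturation_oracle(tada8e, [111, 119, 149], AMINO_ACIDS)
        assert {frozenset(v.substitutions) for v in variants} == expected
        assert len(variants) == 8000

    def test_one_site(self, tada8e):
        variants = enumerate_site_saturation(tada8e, [119])
        assert len(variants) == 20
        assert sum(v.is_identity for v in variants) == 1

    def test_two_sites_small_alphabet_oracle(self, tada8e):
        alphabet = "ACDR"
        variants = enumerate_site_saturation(tada8e, [111, 119], alphabet)
        expected = site_saturation_oracle(tada8e, [111, 119], alphabet)
        assert {frozenset(v.substitutions) for v in variants} == expected

    def test_duplicate_position_rejected(self, tada8e):
        with pytest.raises(LibraryError, match="duplicate"):
            enumerate_site_saturation(tada8e, [111, 111])

    def test_empty_positions_rejected(self, tada8e):
        with pytest.raises(LibraryError):
            enumerate_site_saturation(tada8e, [])


class TestChargeSwap:
    def test_negative_residue_single_partner(self, tada8e):
        variants = enumerate_charge_swap(tada8e, [(147, "D")])
        assert [v.variant_id for v in variants] == ["D147E"]

    def test_positive_residue_two_partners(self, tada8e):
        variants = enumerate_charge_swap(tada8e, [(111, "R")])
        assert sorted(v.variant_id for v in variants) == ["R111H", "R111K"]

    def test_singleton_class_yields_nothing(self, tada8e):
        classes = {"w_alone": frozenset("W"), "rest": frozenset(set(AMINO_ACIDS) - {"W"})}
        seq = tada8e[:110] + "W" + tada8e[111:]
        assert enumerate_charge_swap(seq, [(111, "W")], classes) == []

    def test_expected_residue_mismatch_names_position(self, tada8e):
        with pytest.raises(LibraryError, match="111"):
            enumerate_charge_swap(tada8e, [(111, "K")])

    def test_all_six_screen_residues(self, tada8e):
        residues = [(109, "S"), (111, "R"), (119, "N"), (122, "N"), (147, "D"), (149, "Y")]
        variants = enumerate_charge_swap(tada8e, residues)
        # S/N/N/Y sit in the 6-member polar class (5 partners each), R has 2, D has 1
        assert len(variants) == 4 * 5 + 2 + 1


class TestBackMutation:
    def seed(self, parent, pos, to="W"):
        return AminoAcidVariant.build(parent, [(pos, parent[pos - 1], to)], "screen_hit")

    def test_one_seed_two_differences_gives_three(self, tada8e, tada710):
        variants = enumerate_back_mutations([self.seed(tada8e, 112)], tada8e, tada710)
        assert len(variants) == 3
        sizes = sorted(len(v.substitutions) for v in variants)
        assert sizes == [2, 2, 3]

    def test_three_seeds_give_nine(self, tada8e, tada710):
        seeds = [self.seed(tada8e, p) for p in (112, 121, 148)]
        variants = enumerate_back_mutations(seeds, tada8e, tada710)
        assert len(variants) == 9

    def test_reversions_restore_ancestral_residue(self, tada8e, tada710):
        variants = enumerate_back_mutations([self.seed(tada8e, 112)], tada8e, tada710)
        for v in variants:
            for pos, _, to_aa in v.substitutions:
                if pos != 112:
                    assert to_aa == tada710[pos - 1]

    def test_nearest_differences_selected_with_tie_toward_lower_index(
        self, tada8e, tada710
    ):
        variants = enumerate_back_mutations([self.seed(tada8e, 148)], tada8e, tada710)
        positions = {p for v in variants for p, _, _ in v.substitutions}
        assert positions == {147, 148, 149}

    def test_seed_far_from_differences_warns_and_yields_nothing(
        self, tada8e, tada710, caplog
    ):
        with caplog.at_level(logging.WARNING, logger="abescan.library"):
            variants = enumerate_back_mutations(
                [self.seed(tada8e, 20)], tada8e, tada710, flank=10
            )
        assert variants == []
        assert any("differing residues" in rec.message for rec in caplog.records)

    def test_multi_substitution_seed_rejected(self, tada8e, tada710):
        bad = AminoAcidVariant.build(
            tada8e, [(111, "R", "K"), (119, "N", "D")], "screen_hit"
        )
        with pytest.raises(LibraryError, match="exactly one"):
            enumerate_back_mutations([bad], tada8e, tada710)


class TestOligos:
    def test_identity_variant_equals_parent_cds(self, tada8e):
        cds = back_translate(tada8e)
        identity = AminoAcidVariant.build(tada8e, [], "range_scan")
        oligos, rejections = emit_oligos([identity], cds)
        assert not rejections
        assert oligos[0].dna == cds

    def test_single_substitution_touches_one_codon(self, tada8e):
        cds = back_translate(tada8e)
        variant = AminoAcidVariant.build(tada8e, [(111, "R", "K")], "range_scan")
        oligos, _ = emit_oligos([variant], cds)
        diffs = [i for i, (a, b) in enumerate(zip(cds, oligos[0].dna)) if a != b]
        assert diffs and all(330 <= i < 333 for i in diffs)

    def test_translation_roundtrip_over_library_sample(self, tada8e):
        cds = back_translate(tada8e)
        variants = enumerate_range_scan(tada8e, 106, 110)
        oligos, rejections = emit_oligos(variants, cds)
        assert not rejections
        by_id = {v.variant_id: v for v in variants}
        for oligo in oligos:
            assert str(Seq(oligo.dna).translate()) == by_id[oligo.variant_id].apply(tada8e)

    def test_forbidden_motif_falls_back_to_next_codon(self):
        parent_cds = "ATGAAAGCC"  # M K A
        variant = AminoAcidVariant.build("MKA", [(2, "K", "E")], "range_scan")
        # top-ranked GAG creates ATG|GAG|GCC containing GAGG; GAA does not
        oligos, rejections = emit_oligos([variant], parent_cds, forbidden_site="GAGG")
        assert not rejections
        assert oligos[0].dna == "ATGGAAGCC"

    def test_unavoidable_motif_yields_rejection_record(self):
        parent_cds = "ATGAAAGGG"  # M K G
        variant = AminoAcidVariant.build("MKG", [(2, "K", "W")], "range_scan")
        # W has the single codon TGG; ATG|TGG|GGG always contains GTGG
        oligos, rejections = emit_oligos([variant], parent_cds, forbidden_site="GTGG")
        assert oligos == []
        assert len(rejections) == 1
        assert rejections[0].variant_id == variant.variant_id

    def test_reverse_strand_motif_detected(self):
        parent_cds = "ATGAAAGCC"
        variant = AminoAcidVariant.build("MKA", [(2, "K", "E")], "range_scan")
        # CCTC is the reverse complement of GAGG; GAG must again be avoided
        oligos, rejections = emit_oligos([variant], parent_cds, forbidden_site="CCTC")
        assert not rejections
        assert oligos[0].dna == "ATGGAAGCC"
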
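import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abescan.coords import EditCall
from abescan.outcomes import (
    TargetSpec,
    TargetSpecError,
    bystander_report,
    cardinality_label,
    classify_outcomes,
    codon_consequence,
    combo_distribution,
    purity_ratio,
)
from abescan.quant import AlleleTable, per_position_frequencies
from abescan import resources
from helpers import classification_oracle, projection_oracle, random_allele_table


def a2g(pos):
    return EditCall(pos, "A", "G")


def table_from(spec, combo_counts, window=(-3, 12)):
    return AlleleTable(spec=spec, combos=dict(combo_counts), window=window)


class TestCodonConsequence:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ("ACG", "GCG", "missense"),   # Thr -> Ala
            ("CAG", "CGG", "missense"),   # Gln -> Arg
            ("TGA", "TGG", "stop_loss"),  # stop -> Trp (reporter rescue)
            ("GCT", "GCC", "synonymous"),
            ("TAT", "TAA", "nonsense"),
        ],
    )
    def test_standard_code(self, ref, alt, expected):
        assert codon_consequence(ref, alt) == expected

    def test_target_position_labelled_corrective(self):
        assert codon_consequence("TAC", "TGC", target=True) == "corrective"

    def test_non_triplet_rejected(self):
        with pytest.raises(TargetSpecError):
            codon_consequence("AC", "GC")

    def test_identical_codons_rejected(self):
        with pytest.raises(TargetSpecError):
            codon_consequence("ACG", "ACG")


class TestComboDistribution:
    def test_worked_example(self, aavs1_spec):
        table = table_from(
            aavs1_spec,
            {frozenset(): 50, frozenset({a2g(6)}): 30, frozenset({a2g(6), a2g(7)}): 20},
        )
        dist = combo_distribution(table, {6, 7})
        assert dist[frozenset()] == pytest.approx(0.50)
        assert dist[frozenset({6})] == pytest.approx(0.30)
        assert dist[frozenset({6, 7})] == pytest.approx(0.20)

    def test_projection_ignores_outside_positions(self, aavs1_spec):
        table = table_from(aavs1_spec, {frozenset({a2g(6), a2g(4)}): 10, frozenset(): 0})
        dist = combo_distribution(table, {6, 7})
        assert dist[frozenset({6})] == pytest.approx(1.0)

    def test_cardinality_labels(self):
        assert cardinality_label(frozenset()) == "none"
        assert cardinality_label(frozenset({6})) == "single"
        assert cardinality_label(frozenset({6, 7})) == "dual"
        assert cardinality_label(frozenset({4, 6, 7})) == "triple"

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50)
    def test_matches_projection_oracle(self, aavs1_spec, seed):
        rng = np.random.default_rng(seed)
        positions = [p for p in aavs1_spec.positions(-3, 12) if aavs1_spec.base_at(p) == "A"]
        table = random_allele_table(rng, aavs1_spec, positions)
        subset = {4, 6}
        assert combo_distribution(table, subset) == projection_oracle(table, subset)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50)
    def test_enlarging_projection_never_increases_wildtype(self, aavs1_spec, seed):
        rng = np.random.default_rng(seed)
        positions = [p for p in aavs1_spec.positions(-3, 12) if aavs1_spec.base_at(p) == "A"]
        table = random_allele_table(rng, aavs1_spec, positions)
        small = combo_distribution(table, {6})[frozenset()]
        large = combo_distribution(table, {4, 6, 7})[frozenset()]
        assert large <= small + 1e-12


class TestPurityRatio:
    def test_simple_ratio(self):
        dist = {frozenset({5}): 0.60, frozenset({5, 8}): 0.40}
        assert purity_ratio(dist, {5}, {5, 8}) == pytest.approx(0.60)

    def test_zero_competitor_gives_one(self):
        assert purity_ratio({frozenset({5}): 0.3}, {5}, {5, 8}) == 1.0

    def test_both_zero_undefined(self):
        assert purity_ratio({}, {5}, {5, 8}) is None


class TestClassifyOutcomes:
    def hfe_table(self, spec, combo_counts):
        return table_from(spec, combo_counts)

    def test_target_only_combo_is_precise(self, hfe_fixture):
        table = self.hfe_table(hfe_fixture.spec, {frozenset({a2g(5)}): 10, frozenset(): 0})
        summary = classify_outcomes(table, hfe_fixture.target)
        assert summary.precise == 1.0

    def test_target_plus_missense_bystander(self, hfe_fixture):
        table = self.hfe_table(
            hfe_fixture.spec, {frozenset({a2g(5), a2g(8)}): 10, frozenset(): 0}
        )
        summary = classify_outcomes(table, hfe_fixture.target)
        assert summary.bystander_missense == 1.0

    def test_all_eight_combos_partition_against_oracle(self, hfe_fixture):
        """Exhaustive 2^3 enumeration over editable {1,5,8}: exactly 1
        precise, 6 missense-containing and 1 wild-type combo."""
        spec, target = hfe_fixture.spec, hfe_fixture.target
        consequence_of = {p: target.consequence_at(p) for p in target.editable_positions}
        tallies = {"precise": 0, "bystander_missense": 0, "other_edited": 0, "wild_type": 0}
        for r in range(4):
            for subset in itertools.combinations((1, 5, 8), r):
                counts = {frozenset(a2g(p) for p in subset): 1}
                counts.setdefault(frozenset(), 0)
                table = self.hfe_table(spec, counts)
                summary = classify_outcomes(table, target)
                expected = classification_oracle(
                    frozenset(subset), target.target_position, consequence_of
                )
                assert getattr(summary, expected) == 1.0
                tallies[expected] += 1
        assert tallies == {
            "precise": 1,
            "bystander_missense": 6,
            "other_edited": 0,
            "wild_type": 1,
        }

    def test_synonymous_bystanders_are_other_edited(self, hbb_fixture):
        table = table_from(
            hbb_fixture.spec, {frozenset({a2g(9), a2g(12)}): 10, frozenset(): 0}
        )
        summary = classify_outcomes(table, hbb_fixture.target)
        assert summary.other_edited == 1.0
        assert summary.three_way()["missense"] == 1.0

    def test_uncovered_position_raises(self, hfe_fixture):
        table = self.hfe_table(hfe_fixture.spec, {frozenset({a2g(4, )}): 1})
        with pytest.raises(TargetSpecError, match="not covered"):
            classify_outcomes(table, hfe_fixture.target)

    def test_projection_removes_uncovered_noise(self, hfe_fixture):
        from abescan.outcomes import project_allele_table

        table = self.hfe_table(
            hfe_fixture.spec,
            {
                frozenset({a2g(5), a2g(4)}): 6,        # noise call at +4
                frozenset({a2g(5), EditCall(6, "C", "T")}): 4,  # C>T byproduct
                frozenset(): 0,
            },
        )
        projected = project_allele_table(table, hfe_fixture.target.editable_positions)
        assert projected.combos == {frozenset({a2g(5)}): 10, frozenset(): 0}
        assert projected.n_total == table.n_total
        summary = classify_outcomes(projected, hfe_fixture.target)
        assert summary.precise == 1.0

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50)
    def test_partition_sums_to_one_exactly(self, hfe_fixture, seed):
        rng = np.random.default_rng(seed)
        table = random_allele_table(rng, hfe_fixture.spec, [1, 5, 8])
        summary = classify_outcomes(table, hfe_fixture.target)
        total = (
            summary.precise
            + summary.bystander_missense
            + summary.other_edited
            + summary.wild_type
        )
        assert total == pytest.approx(1.0, abs=1e-12)


class TestBystanderReport:
    def test_fully_edited_synonymous_bystander(self, hbb_fixture):
        table = table_from(
            hbb_fixture.spec, {frozenset({a2g(7), a2g(9)}): 10, frozenset(): 0}
        )
        rows = {r["position"]: r for r in bystander_report(table, hbb_fixture.target)}
        assert rows[9]["frequency"] == 1.0
        assert rows[9]["consequence"] == "synonymous"
        assert rows[12]["frequency"] == 0.0

    def test_no_bystander_edits_all_zero(self, hbb_fixture):
        table = table_from(hbb_fixture.spec, {frozenset({a2g(7)}): 5, frozenset(): 5})
        assert all(
            r["frequency"] == 0.0 for r in bystander_report(table, hbb_fixture.target)
        )

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30)
    def test_consistent_with_per_position_frequencies(self, hbb_fixture, seed):
        rng = np.random.default_rng(seed)
        table = random_allele_table(rng, hbb_fixture.spec, [7, 9, 12])
        freq = per_position_frequencies(table)
        for row in bystander_report(table, hbb_fixture.target):
            assert row["frequency"] == freq.freqs[row["position"]]


class TestTargetSpecLoading:
    @pytest.mark.parametrize("name", ["hfe_c282y", "hbb_s", "pcsk9_intron1"])
    def test_packaged_specs_load(self, name):
        spec = resources.target_spec(name)
        assert spec.name == name
        assert spec.target_position in spec.editable_positions

    def test_packaged_hfe_matches_code_fixture(self, hfe_fixture):
        assert resources.target_spec("hfe_c282y") == hfe_fixture.target

    def test_packaged_codon_labels_agree_with_genetic_code(self):
        spec = resources.target_spec("hfe_c282y")
        for pos, pc in spec.consequences.items():
            if pos == spec.target_position or not pc.ref_codon:
                continue
            assert codon_consequence(pc.ref_codon, pc.edited_codon) == pc.consequence

    def test_target_outside_editable_rejected(self):
        from abescan.outcomes import PositionConsequence

        with pytest.raises(TargetSpecError):
            TargetSpec(
                name="bad",
                editable_positions=(5,),
                target_position=6,
                consequences={5: PositionConsequence(5, "corrective")},
            )
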
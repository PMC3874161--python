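"""Cloverleaf parsing, identity elements, synthetase classification, mutations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_trna
from mitorecode import simulate, trna
from mitorecode.trna import (
    DEFAULT_RULES,
    CloverleafParseError,
    apply_mutation,
    classify_synthetase,
    extract_identity_elements,
    load_rules_tsv,
    mutation_from_name,
    parse_cloverleaf,
    write_rules_tsv,
)


class TestParseCloverleaf:
    def test_designed_anticodon_recovered(self):
        gene, _, _ = make_trna(
            {"pair_3_70": "G:U", "anticodon": "UAG", "loop_len": "7", "discriminator": "G"},
            seed=1,
        )
        assert gene.anticodon == "UAG"
        assert gene.loop_len == 7
        assert gene.pair(3) == ("G", "U")
        assert gene.discriminator == "G"

    def test_insertion_preserves_anticodon(self):
        """One base inserted 5' of the anticodon: loop 8, anticodon unchanged."""
        gene, _, _ = make_trna(
            {"pair_3_70": "G:U", "anticodon": "UAG", "loop_len": "7", "discriminator": "G"},
            seed=2,
        )
        mutated = apply_mutation(gene, [{"position": 31, "op": "insert", "base": "U"}])
        assert mutated.loop_len == 8
        assert mutated.anticodon == gene.anticodon == "UAG"

    @pytest.mark.parametrize("loop_len", ["7", "8"])
    def test_structure_and_heuristic_parses_agree(self, loop_len):
        """Cross-method oracle: dot-bracket parse == structure-free parse."""
        for seed in range(50):
            els = {
                "pair_3_70": "G:U",
                "anticodon": "UAG",
                "loop_len": loop_len,
                "discriminator": "G",
            }
            if loop_len == "8":
                els["inserted_31"] = "U"
            rng = np.random.default_rng(seed)
            seq, struct = simulate.build_trna(els, rng)
            heur = parse_cloverleaf(seq, cca=False)
            byst = parse_cloverleaf(seq, structure=struct, cca=False)
            assert (heur.loop_start, heur.loop_len, heur.anticodon) == (
                byst.loop_start,
                byst.loop_len,
                byst.anticodon,
            )

    def test_cca_autodetection_and_landmarks(self):
        gene, seq, _ = make_trna(
            {"pair_3_70": "G:U", "anticodon": "UAG", "loop_len": "7", "discriminator": "G"},
            seed=4,
        )
        mature = parse_cloverleaf(seq + "CCA")
        assert mature.cca_present
        assert mature.discriminator == gene.discriminator
        assert mature.anticodon == gene.anticodon

    def test_no_cloverleaf_raises(self):
        with pytest.raises(CloverleafParseError):
            parse_cloverleaf("A" * 73)

    def test_length_bounds(self):
        with pytest.raises(CloverleafParseError):
            parse_cloverleaf("ACGU" * 10)   # 40 nt

    def test_minus_one_base_held_outside_body(self):
        gene, _, _ = make_trna(
            {"pair_3_70": "G:C", "anticodon": "GUG", "loop_len": "7", "discriminator": "C"},
            seed=5,
            minus_one="G",
        )
        assert gene.minus_one == "G"
        assert gene.sequence[0] == "G"
        assert len(gene.body) == len(gene.sequence) - 1


class TestIdentityElements:
    def test_ala_fixture_pair_3_70(self, ala_trna):
        assert extract_identity_elements(ala_trna).pair_3_70 == "G:U"

    def test_his_fixture_minus1_73_pairing(self, his_trna):
        e = extract_identity_elements(his_trna)
        assert e.minus_one == "G" and e.discriminator == "C"
        assert e.minus1_73_pair is True

    def test_no_minus1_gives_false_pair_flag(self, ala_trna):
        # −1 absent from the gene: the flag is unknown, not false
        assert extract_identity_elements(ala_trna).minus1_73_pair is None
        # −1 present but non-pairing: flag false
        g = apply_mutation(ala_trna, [{"position": -1, "op": "insert", "base": "A"}])
        # discriminator G: A:G does not pair
        assert extract_identity_elements(g).minus1_73_pair is False

    def test_inserted_31_reported_only_for_8nt_loops(self, ala_trna, thr_trna):
        assert extract_identity_elements(ala_trna).inserted_31 is None
        assert extract_identity_elements(thr_trna).inserted_31 == "U"


class TestClassifier:
    def test_ala_fixture_orthogonal_alars(self, ala_trna):
        call = classify_synthetase(ala_trna)
        assert call.matching == ["AlaRS"]
        assert call.orthogonal

    def test_thr_fixture_mst1_only(self, thr_trna):
        call = classify_synthetase(thr_trna)
        assert call.matching == ["ThrRS-MST1"]
        assert call.orthogonal

    def test_his_fixture_hisrs_only(self, his_trna):
        call = classify_synthetase(his_trna)
        assert call.matching == ["HisRS"]
        assert call.orthogonal

    def test_his_anticodon_relaxation(self):
        """A UCG-anticodon tRNA with the G−1/C73 signal scores as HisRS only
        when the anticodon requirement is relaxed."""
        gene, _, _ = make_trna(
            {"pair_3_70": "G:C", "anticodon": "UCG", "loop_len": "7", "discriminator": "C"},
            seed=13,
            minus_one="G",
        )
        strict = classify_synthetase(gene)
        relaxed = classify_synthetase(gene, his_anticodon_required=False)
        assert strict.predictions["HisRS"].status == trna.NO_MATCH
        assert relaxed.predictions["HisRS"].status == trna.MATCH

    def test_every_prediction_cites_elements(self, ala_trna):
        call = classify_synthetase(ala_trna)
        for pred in call.predictions.values():
            assert pred.matched or pred.violated or pred.unknown

    def test_rules_roundtrip_as_tsv(self, tmp_path, ala_trna):
        p = tmp_path / "rules.tsv"
        write_rules_tsv(p)
        loaded = load_rules_tsv(p)
        assert {r.synthetase for r in loaded} == {r.synthetase for r in DEFAULT_RULES}
        assert classify_synthetase(ala_trna, loaded).matching == ["AlaRS"]

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_classification_depends_only_on_elements(self, seed):
        """Randomising non-element positions (loops, variable region) never
        changes the classification."""
        gene, _, _ = make_trna(
            {"pair_3_70": "G:U", "anticodon": "UAG", "loop_len": "7", "discriminator": "G"},
            seed=seed,
        )
        call = classify_synthetase(gene)
        assert call.matching == ["AlaRS"]


class TestMutationLogic:
    def test_g3a_abolishes_alars(self, ala_trna):
        mutated = apply_mutation(ala_trna, [mutation_from_name("G3A")])
        call = classify_synthetase(mutated)
        assert call.predictions["AlaRS"].status == trna.NO_MATCH
        assert "AlaRS" not in call.matching

    def test_a3g_gain_on_thr_trna(self, thr_trna):
        mutated = apply_mutation(thr_trna, [mutation_from_name("A3G")])
        call = classify_synthetase(mutated)
        assert "AlaRS" in call.matching and "ThrRS-MST1" in call.matching
        assert not call.orthogonal

    def test_a3g_du31_restores_orthogonality(self, thr_trna):
        mutated = apply_mutation(
            thr_trna, [mutation_from_name("A3G"), mutation_from_name("dU31")]
        )
        call = classify_synthetase(mutated)
        assert call.matching == ["AlaRS"]
        assert call.orthogonal
        assert mutated.loop_len == 7

    def test_insu31_converts_ala_to_mst1_substrate(self, ala_trna):
        mutated = apply_mutation(ala_trna, [mutation_from_name("InsU31")])
        call = classify_synthetase(mutated)
        assert call.predictions["ThrRS-MST1"].status == trna.MATCH

    def test_mutation_inverse_restores_elements(self, ala_trna):
        before = extract_identity_elements(ala_trna)
        ins = apply_mutation(ala_trna, [{"position": 31, "op": "insert", "base": "U"}])
        restored = apply_mutation(ins, [{"position": 31, "op": "delete", "base": None}])
        assert extract_identity_elements(restored) == before
        sub = apply_mutation(ala_trna, [mutation_from_name("G3A")])
        back = apply_mutation(sub, [mutation_from_name("A3G")])
        assert extract_identity_elements(back) == before

    def test_planted_orthogonality_recovered(self):
        """Random tRNAs with planted single-synthetase element sets classify
        back to exactly the planted synthetase."""
        plans = [
            (
                {"pair_3_70": "G:U", "anticodon": "UAG", "loop_len": "7",
                 "discriminator": "G"},
                None,
                "AlaRS",
            ),
            (
                {"pair_3_70": "A:U", "anticodon": "UAG", "loop_len": "8",
                 "inserted_31": "U", "discriminator": "G"},
                None,
                "ThrRS-MST1",
            ),
            (
                {"pair_3_70": "G:C", "anticodon": "GUG", "loop_len": "7",
                 "discriminator": "C"},
                "G",
                "HisRS",
            ),
            (
                {"pair_3_70": "C:G", "anticodon": "CAA", "loop_len": "7",
                 "discriminator": "A"},
                None,
                "LeuRS-candidate",
            ),
        ]
        for seed in range(50):
            els, minus_one, expected = plans[seed % len(plans)]
            gene, _, _ = make_trna(els, seed=seed, minus_one=minus_one)
            call = classify_synthetase(gene)
            assert call.matching == [expected], (seed, expected, call.matching)
            assert call.orthogonal
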
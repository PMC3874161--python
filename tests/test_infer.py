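"""Conservation-profile codon identity calls."""

import random

import pytest

from conftest import back_translate
from mitorecode import infer, simulate
from mitorecode.infer import (
    ABSENT,
    AMBIGUOUS,
    NO_SIGNAL,
    OrthologAlignment,
    call_all_families,
    column_profile,
    map_codons_to_columns,
    score_codon_family,
)


def make_alignment(gene_id, target_protein, other_rows, cds=None, target="target"):
    rows = dict(other_rows)
    rows[target] = target_protein
    cds = cds if cds is not None else back_translate(target_protein.replace("-", ""))
    cmap = map_codons_to_columns(cds, target_protein)
    return OrthologAlignment(gene_id, rows, target, cds, cmap)


class TestColumnMapping:
    def test_gap_skipping(self):
        cds = back_translate("MKLW")
        assert map_codons_to_columns(cds, "M-KLW") == [0, 2, 3, 4]

    def test_gapless_identity(self):
        cds = back_translate("MKLW")
        assert map_codons_to_columns(cds, "MKLW") == [0, 1, 2, 3]

    def test_random_gap_roundtrip(self):
        """Ungapping the mapped columns reproduces the residue string."""
        rng = random.Random(5)
        for _ in range(20):
            protein = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(40))
            gapped = list(protein)
            for _ in range(10):
                gapped.insert(rng.randrange(len(gapped)), "-")
            gapped = "".join(gapped)
            cmap = map_codons_to_columns(back_translate(protein), gapped)
            assert "".join(gapped[c] for c in cmap) == protein
            assert cmap == sorted(cmap) and len(set(cmap)) == len(cmap)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            map_codons_to_columns(back_translate("MK"), "MKL")


class TestColumnProfile:
    def test_invariant_column(self):
        aln = make_alignment(
            "g", "A", {f"sp{i}": "A" for i in range(10)}
        )
        prof = column_profile(aln, 0, exclude={"target"})
        assert prof.frequencies == {"A": 1.0}
        assert prof.weight == 1.0

    def test_mixed_column_arithmetic(self):
        rows = {f"sp{i}": "T" for i in range(6)}
        rows.update({f"sq{i}": "S" for i in range(4)})
        aln = make_alignment("g", "A", rows)
        prof = column_profile(aln, 0, exclude={"target"})
        assert prof.frequencies == pytest.approx({"T": 0.6, "S": 0.4})
        assert prof.weight == pytest.approx(0.6)

    def test_all_gap_column_flagged_empty(self):
        aln = make_alignment("g", "A", {"sp1": "-", "sp2": "-"})
        prof = column_profile(aln, 0, exclude={"target"})
        assert prof.empty and prof.weight == 0.0

    def test_target_excluded_from_profile(self):
        aln = make_alignment("g", "W", {"sp1": "A", "sp2": "A"})
        prof = column_profile(aln, 0, exclude={"target"})
        assert "W" not in prof.frequencies


def _family_alignment(n_sites, others_residue, other_noise=None, n_species=10):
    """Target uses CUA at every site; others show ``others_residue`` (or the
    per-species residue list in ``other_noise``)."""
    protein = "A" * n_sites
    cds = "CUA" * n_sites
    rows = {}
    for i in range(n_species):
        if other_noise is None:
            rows[f"sp{i}"] = others_residue * n_sites
        else:
            rows[f"sp{i}"] = other_noise[i]
    return make_alignment("g1", protein, rows, cds=cds)


class TestScoreCodonFamily:
    def test_invariant_thr_columns_unanimous(self, yeast_mito):
        aln = _family_alignment(10, "T")
        call = score_codon_family([aln], ["CUA", "CUU", "CUC", "CUG"], yeast_mito)
        assert call.call == "T"
        assert call.support["T"] == pytest.approx(1.0)
        assert call.n_sites == 10

    def test_ninety_percent_ala_columns(self, yeast_mito):
        """30 sites whose columns are 90% Ala in the other species."""
        n_sp = 10
        noise = ["A" * 30] * 9 + ["S" * 30]     # each column: 9 A, 1 S
        aln = _family_alignment(30, "A", other_noise=noise, n_species=n_sp)
        call = score_codon_family([aln], ["CUA"], yeast_mito)
        assert call.call == "A"
        assert call.support["A"] >= 0.9
        # hand-computed weighted average: every site has w=0.9, f(A)=0.9
        assert call.support["A"] == pytest.approx(0.9)
        assert call.support["S"] == pytest.approx(0.1)

    def test_fig1_like_mixed_conservation(self, yeast_mito):
        """Most family sites at weakly conserved columns, a minority at
        conserved-Ala columns: the call still lands on Ala because weak
        columns fall below the conservation floor."""
        n_sites = 12
        rows = {}
        for i in range(10):
            # sites 0-9: near-random residues (weight 0.1-0.2); sites 10-11: all A
            rows[f"sp{i}"] = "".join(
                "ACDEFGHIKL"[(i + s) % 10] for s in range(10)
            ) + "AA"
        aln = _family_alignment(n_sites, "A", other_noise=[rows[f"sp{i}"] for i in range(10)])
        call = score_codon_family([aln], ["CUA"], yeast_mito, min_weight=0.5)
        assert call.call == "A"
        assert call.n_sites == 2

    def test_no_usable_sites_is_no_signal(self, yeast_mito):
        noise = ["ACDEFGHIKL"[i] * 5 for i in range(10)]   # every column maximally split
        aln = _family_alignment(5, "A", other_noise=noise)
        call = score_codon_family([aln], ["CUA"], yeast_mito, min_weight=0.5)
        assert call.call == NO_SIGNAL and call.n_sites == 0

    def test_zero_usage_is_absent(self, yeast_mito):
        aln = make_alignment("g", "MKW", {f"sp{i}": "MKW" for i in range(5)})
        call = score_codon_family([aln], ["CUA", "CUU", "CUC", "CUG"], yeast_mito)
        assert call.call == ABSENT

    def test_margin_yields_ambiguous(self, yeast_mito):
        noise = ["A" * 10] * 5 + ["T" * 10] * 5    # 50/50 split, weight 0.5
        aln = _family_alignment(10, "A", other_noise=noise)
        call = score_codon_family([aln], ["CUA"], yeast_mito, min_weight=0.5, margin=0.2)
        assert call.call == AMBIGUOUS

    def test_species_order_invariance(self, yeast_mito):
        noise = ["A" * 8] * 7 + ["S" * 8] * 3
        aln1 = _family_alignment(8, "A", other_noise=noise)
        aln2 = _family_alignment(8, "A", other_noise=noise[::-1])
        c1 = score_codon_family([aln1], ["CUA"], yeast_mito)
        c2 = score_codon_family([aln2], ["CUA"], yeast_mito)
        assert c1.support == pytest.approx(c2.support)

    def test_support_is_convex_combination(self, yeast_mito):
        noise = ["A" * 6] * 8 + ["T" * 6, "S" * 6]
        aln = _family_alignment(6, "A", other_noise=noise)
        call = score_codon_family([aln], ["CUA"], yeast_mito, min_weight=0.0)
        assert sum(call.support.values()) == pytest.approx(1.0)
        assert all(0.0 <= v <= 1.0 for v in call.support.values())


class TestCallAllFamilies:
    def test_recovers_planted_reassignment(self, yeast_mito):
        truth = simulate.preset("ashbya-like", seed=2)
        alns = simulate.simulate_ortholog_set(truth)
        calls = call_all_families(alns, yeast_mito, per_codon=False)
        nonstd = [
            c
            for c in calls
            if c.call not in (AMBIGUOUS, NO_SIGNAL, ABSENT)
            and any(yeast_mito.amino_acid(x) != c.call for x in c.family)
        ]
        assert len(nonstd) == 1
        assert set(nonstd[0].family) == set(truth.reassigned_family)
        assert nonstd[0].call == truth.planted_aa

    def test_single_codon_calls_included(self, yeast_mito):
        truth = simulate.preset("ashbya-like", seed=2)
        alns = simulate.simulate_ortholog_set(truth)
        calls = call_all_families(alns, yeast_mito, per_codon=True)
        cua = next(c for c in calls if c.family == ("CUA",))
        cuu = next(c for c in calls if c.family == ("CUU",))
        assert cua.call == "A" and cuu.call == "A"

    def test_standard_null_makes_no_nonstandard_calls(self, standard_code):
        truth = simulate.preset("standard-null", seed=4)
        alns = simulate.simulate_ortholog_set(truth)
        calls = call_all_families(alns, standard_code, per_codon=False)
        for c in calls:
            if c.call in (AMBIGUOUS, NO_SIGNAL, ABSENT):
                continue
            assert all(standard_code.amino_acid(x) == c.call for x in c.family)

    def test_klactis_family_reported_absent(self, yeast_mito):
        truth = simulate.preset("klactis-like", seed=6)
        alns = simulate.simulate_ortholog_set(truth)
        calls = call_all_families(alns, yeast_mito, per_codon=False)
        cun = next(c for c in calls if set(c.family) == {"CUA", "CUC", "CUG", "CUU"})
        assert cun.call == ABSENT


class TestIO:
    def test_roundtrip_through_readers(self, tmp_path, yeast_mito):
        truth = simulate.preset("ashbya-like", seed=8)
        alns = simulate.simulate_ortholog_set(truth)
        simulate.write_ortholog_set(alns, tmp_path)
        loaded = infer.read_ortholog_set(
            tmp_path / "alignments", tmp_path / "cds.fasta", truth.target
        )
        assert len(loaded) == len(alns)
        for a, b in zip(sorted(alns, key=lambda x: x.gene_id), loaded):
            assert a.gene_id == b.gene_id
            assert a.rows == b.rows
            assert a.cds == b.cds
            assert a.column_map == b.column_map

    def test_outputs_written(self, tmp_path, yeast_mito):
        truth = simulate.preset("ashbya-like", seed=8)
        alns = simulate.simulate_ortholog_set(truth)
        calls = call_all_families(alns, yeast_mito, per_codon=False)
        infer.calls_to_tsv(calls, tmp_path / "calls.tsv")
        audit = infer.calls_to_audit(calls)
        lines = (tmp_path / "calls.tsv").read_text().strip().splitlines()
        assert len(lines) == 1 + len(calls)
        assert all("family" in entry for entry in audit)
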
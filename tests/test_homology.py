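"""Translated alignment and multi-k merging, checked against independent
oracles: a literal codon table, a hand-coded affine Smith-Waterman DP,
and a brute-force subject-set union."""

import math
import random

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from btdpipe import simdata
from btdpipe.homology import (
    ProteinIndex,
    assign_best_homologue,
    check_gap_consistency,
    hit_to_tabular,
    karlin_altschul_evalue,
    local_align_protein,
    merge_multi_k,
    translate_six_frames,
    translated_scan,
    validate_against_known,
)

AA = "ACDEFGHIKLMNPQRSTVWY"

# literal standard codon table (independent of Bio.Seq)
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def oracle_translate(nt, frame):
    s = nt if frame > 0 else "".join(RC[b] for b in reversed(nt))
    off = abs(frame) - 1
    pep = []
    for i in range(off, len(s) - 2, 3):
        pep.append(CODON_TABLE[s[i : i + 3]])
    return "".join(pep)


def oracle_smith_waterman(a, b, gap_open=12, gap_extend=1):
    """Gotoh local alignment score with affine gaps (first gap position
    costs gap_open, each further position gap_extend)."""
    blosum = substitution_matrices.load("BLOSUM62")
    n, m = len(a), len(b)
    NEG = -1e9
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = blosum[a[i - 1], b[j - 1]]
            M[i][j] = max(0.0, max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s)
            Ix[i][j] = max(M[i - 1][j] - gap_open, Ix[i - 1][j] - gap_extend,
                           Iy[i - 1][j] - gap_open)
            Iy[i][j] = max(M[i][j - 1] - gap_open, Iy[i][j - 1] - gap_extend,
                           Ix[i][j - 1] - gap_open)
            best = max(best, M[i][j])
    return best


class TestTranslateSixFrames:
    def test_codon_table_basics(self):
        frames = translate_six_frames("ATGGCC")
        assert frames[1] == "MA"

    def test_insufficient_codons_give_empty(self):
        frames = translate_six_frames("ATG")
        assert frames[2] == "" and frames[3] == ""
        assert frames[1] == "M"

    def test_below_one_codon(self):
        assert set(translate_six_frames("AC").values()) == {""}

    def test_random_sequences_match_codon_table_oracle(self, rng):
        for _ in range(20):
            nt = "".join(rng.choice(list("ACGT"), size=300))
            frames = translate_six_frames(nt)
            for f in (1, 2, 3, -1, -2, -3):
                assert frames[f] == oracle_translate(nt, f), f"frame {f}"


class TestLocalAlignment:
    def test_self_alignment(self):
        pep = "MKVLAWYQQHDERKT*"[:20].replace("*", "W")
        hit = local_align_protein(pep, pep)
        assert hit.identity == 1.0
        assert hit.query_span == hit.subject_span == (0, len(pep))

    def test_disjoint_alphabets_score_nothing(self):
        assert local_align_protein("AAAAAAAAAA", "WWWWWWWWWW") is None

    def test_scores_equal_dp_oracle_on_random_pairs(self):
        rnd = random.Random(99)
        for _ in range(60):
            a = "".join(rnd.choices(AA, k=rnd.randint(5, 50)))
            b = "".join(rnd.choices(AA, k=rnd.randint(5, 50)))
            expected = oracle_smith_waterman(a, b)
            hit = local_align_protein(a, b)
            got = hit.score if hit else 0.0
            assert got == pytest.approx(expected), (a, b)

    def test_evalue_strictly_monotone_in_score(self):
        evs = [karlin_altschul_evalue(s, 200, 10_000) for s in range(20, 200, 7)]
        assert all(x > y for x, y in zip(evs, evs[1:]))

    def test_match_count_is_integral(self, rng):
        a = "".join(rng.choice(list(AA), size=40))
        b = "".join(rng.choice(list(AA), size=40))
        hit = local_align_protein(a, b)
        if hit is not None:
            assert hit.identity * hit.aligned_len == pytest.approx(
                round(hit.identity * hit.aligned_len)
            )

    def test_tabular_rendering_is_twelve_columns(self):
        hit = local_align_protein("MKVLAWYQQHDERKTW", "MKVLAWYQQHDERKTW")
        assert len(hit_to_tabular(hit).split("\t")) == 12


class TestAssignBestHomologue:
    def test_exact_backtranslation_hits_truth_in_frame_one(self, rng):
        pep = "".join(rng.choice(list(AA), size=100))
        nt = simdata.back_translate(pep, rng)
        db = {"right": pep, "wrong": "".join(rng.choice(list(AA), size=100))}
        a = assign_best_homologue("q", nt, db)
        assert a.subject_id == "right"
        assert a.hit.identity == 1.0
        assert a.hit.frame == 1

    def test_sixty_aa_boundary_is_strict(self, rng):
        pep = "".join(rng.choice(list(AA), size=60))
        nt = simdata.back_translate(pep, rng)
        assert assign_best_homologue("q", nt, {"p": pep}) is None
        pep61 = pep + "W"
        nt61 = simdata.back_translate(pep61, rng)
        assert assign_best_homologue("q", nt61, {"p": pep61}) is not None

    def test_simulated_isotigs_assigned_to_true_gene(self):
        """At 70% database identity, >=95% of assignments hit the true source."""
        cfg = simdata.SimConfig(n_genes=40, isoform_probability=0.0, seed=21)
        ts = simdata.generate_transcriptome(cfg)
        db = simdata.build_protein_db(ts, target_identity=0.7, seed=22)
        index = ProteinIndex(db)
        correct = total = 0
        for t in ts:
            a = assign_best_homologue(t.isoform_id, t.sequence, index)
            if a is None:
                continue
            total += 1
            correct += a.subject_id == f"prot_{t.gene_id}"
        assert total >= 38
        assert correct / total >= 0.95


class FakeIsotig:
    def __init__(self, iid):
        self.isotig_id = iid


class TestMergeMultiK:
    def test_no_new_subjects_means_base_only(self):
        per_k = {31: [FakeIsotig("b1"), FakeIsotig("b2")], 21: [FakeIsotig("x1")]}
        assignments = {"b1": "A", "b2": "B", "x1": "A"}
        merged, tally = merge_multi_k(per_k, assignments)
        assert [i.isotig_id for i in merged] == ["b1", "b2"]
        assert tally == {21: 0}

    def test_new_subjects_added_once_across_ks(self):
        per_k = {
            31: [FakeIsotig("b1"), FakeIsotig("b2")],
            21: [FakeIsotig("x1"), FakeIsotig("x2")],
            41: [FakeIsotig("y1"), FakeIsotig("y2")],
        }
        assignments = {"b1": "A", "b2": "B", "x1": "B", "x2": "C", "y1": "C", "y2": "D"}
        merged, tally = merge_multi_k(per_k, assignments)
        ids = [i.isotig_id for i in merged]
        assert ids == ["b1", "b2", "x2", "y2"]
        assert tally == {21: 1, 41: 1}

    def test_missing_base_k_is_hard_error(self):
        with pytest.raises(ValueError, match="base"):
            merge_multi_k({21: []}, {}, base_k=31)

    def test_empty_non_base_sets(self):
        per_k = {31: [FakeIsotig("b1")], 25: [], 37: []}
        merged, tally = merge_multi_k(per_k, {"b1": "A"})
        assert len(merged) == 1 and tally == {25: 0, 37: 0}

    def test_subject_union_equals_brute_force_oracle(self, rng):
        """Merged subject set == union of per-k subject sets, 100 random trials."""
        for trial in range(100):
            ks = [21, 25, 31, 35, 41]
            per_k = {}
            assignments = {}
            for k in ks:
                items = []
                for i in range(int(rng.integers(0, 8))):
                    iid = f"k{k}_i{i}"
                    items.append(FakeIsotig(iid))
                    subj = f"S{int(rng.integers(0, 10))}"
                    assignments[iid] = None if rng.random() < 0.3 else subj
                per_k[k] = items
            merged, _ = merge_multi_k(per_k, assignments)
            merged_subjects = {
                assignments[i.isotig_id]
                for i in merged
                if assignments.get(i.isotig_id) is not None
            }
            oracle = {
                s
                for items in per_k.values()
                for s in (assignments[i.isotig_id] for i in items)
                if s is not None
            }
            assert merged_subjects == oracle, f"trial {trial}"


class TestValidateAgainstKnown:
    def test_exact_substring_passes_with_full_scores(self, rng):
        mrna = "".join(rng.choice(list("ACGT"), size=1000))
        isotig = mrna[50:950]
        rows = validate_against_known({"i1": isotig}, {"m1": mrna})
        assert len(rows) == 1
        assert rows[0]["identity"] == pytest.approx(1.0)
        assert rows[0]["coverage_ratio"] == pytest.approx(1.0)

    def test_below_identity_threshold_excluded(self, rng):
        mrna = "".join(rng.choice(list("ACGT"), size=600))
        arr = list(mrna)
        for pos in rng.choice(600, size=36, replace=False):  # 6% divergence
            arr[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[pos]]
        rows = validate_against_known({"i1": "".join(arr)}, {"m1": mrna})
        assert rows == []

    def test_planted_pass_fail_status_recovered(self, rng):
        mrna = "".join(rng.choice(list("ACGT"), size=1200))
        isotigs = {}
        expected_pass = set()
        for i in range(10):
            frag = mrna[i * 20 : i * 20 + 700]
            if i % 2 == 0:
                isotigs[f"pass{i}"] = frag
                expected_pass.add(f"pass{i}")
            else:
                isotigs[f"fail{i}"] = "".join(rng.choice(list("ACGT"), size=700))
        rows = validate_against_known(isotigs, {"m": mrna})
        assert {r["isotig_id"] for r in rows} == expected_pass


class TestGapConsistency:
    def _nt_for(self, pep, rng):
        return simdata.back_translate(pep, rng)

    def test_collinear_segments_consistent(self, rng):
        prot = "".join(rng.choice(list(AA), size=200))
        seg1 = self._nt_for(prot[0:60], rng)
        seg2 = self._nt_for(prot[100:160], rng)
        seq = seg1 + "N" * 20 + seg2
        res = check_gap_consistency("i", seq, {"P": prot})
        assert res.consistent and res.subject_id == "P"

    def test_two_proteins_inconsistent(self, rng):
        p1 = "".join(rng.choice(list(AA), size=120))
        p2 = "".join(rng.choice(list(AA), size=120))
        seq = self._nt_for(p1[:60], rng) + "N" * 15 + self._nt_for(p2[:60], rng)
        res = check_gap_consistency("i", seq, {"P1": p1, "P2": p2})
        assert not res.consistent

    def test_reversed_subject_order_inconsistent(self, rng):
        prot = "".join(rng.choice(list(AA), size=200))
        seg1 = self._nt_for(prot[100:160], rng)
        seg2 = self._nt_for(prot[0:60], rng)
        res = check_gap_consistency("i", seg1 + "N" * 20 + seg2, {"P": prot})
        assert not res.consistent
        assert "order" in res.reason

    def test_no_gap_is_a_flagged_noop(self, rng):
        prot = "".join(rng.choice(list(AA), size=100))
        res = check_gap_consistency("i", self._nt_for(prot, rng), {"P": prot})
        assert res.consistent and "nothing to check" in res.reason


class TestTranslatedScan:
    def test_exact_subsequence_full_identity(self, rng):
        ref = "".join(rng.choice(list("ACGT"), size=900))
        isotig = ref[200:500]
        rows = translated_scan({"i1": isotig}, {"r1": ref})
        assert rows and rows[0]["identity"] == pytest.approx(1.0)
        assert rows[0]["above_threshold"]

    def test_unrelated_sequences_no_hit(self, rng):
        rows = translated_scan(
            {"i1": "".join(rng.choice(list("ACGT"), size=300))},
            {"r1": "".join(rng.choice(list("ACGT"), size=300))},
        )
        assert all(not r["above_threshold"] for r in rows)

    def test_fragments_tiling_long_reference_all_reported(self, rng):
        """Fragments of one long gene all group under that reference, the way
        a sodium-channel gene is recovered piecewise from many isotigs."""
        ref = "".join(rng.choice(list("ACGT"), size=2000))
        isotigs = {f"frag{i}": ref[i * 180 : i * 180 + 300] for i in range(10)}
        rows = translated_scan(isotigs, {"vgsc": ref})
        above = [r for r in rows if r["above_threshold"]]
        assert {r["isotig_id"] for r in above} == set(isotigs)
        assert all(r["reference"] == "vgsc" for r in rows)
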
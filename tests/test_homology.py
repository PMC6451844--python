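"""Local alignment, E-value statistics, miRBase parsing and the search filter."""

import math

import numpy as np
import pytest

from conmir.homology import (
    MatureRef,
    align_local,
    evalue,
    karlin_altschul_params,
    parse_mirbase_fasta,
    search,
    summarize_families,
)
from conmir.smallrna_prep import UniqueRead
from oracles import biopython_local, bisect_lambda, brute_local


class TestParseMirbase:
    def test_family_and_species(self, tmp_path):
        fa = tmp_path / "m.fa"
        fa.write_text(
            ">osa-miR156a-5p\nUGACAGAAGAGAGUGAGCACA\n"
            ">tae-miR5049-3p\nAUAUAGGAAGGAUCUGAGGGG\n"
            ">ath-miR172b\nAGAAUCUUGAUGAUGCUGCAU\n"
        )
        refs = parse_mirbase_fasta(fa)
        assert [(r.species_code, r.family) for r in refs] == [
            ("osa", "miR156"),
            ("tae", "miR5049"),
            ("ath", "miR172"),
        ]
        assert refs[0].sequence == "TGACAGAAGAGAGTGAGCACA"  # U -> T

    def test_bad_header_skipped(self, tmp_path, caplog):
        fa = tmp_path / "m.fa"
        fa.write_text(">not_a_mirna\nACGUACGUACGUACGU\n>osa-miR156a-5p\nUGACAGAAGAGAGUGAGCACA\n")
        with caplog.at_level("WARNING"):
            refs = parse_mirbase_fasta(fa)
        assert len(refs) == 1
        assert "skipped 1" in caplog.text


class TestAlignLocal:
    def test_identical_sequences(self):
        a = align_local("TGACAGAAGAGAGTGAGCACA", "TGACAGAAGAGAGTGAGCACA")
        assert (a.matches, a.mismatches, a.gaps) == (21, 0, 0)
        assert a.identity == 1.0 and a.score == 21

    def test_single_internal_mismatch(self):
        q = "TGACAGAAGAGAGTGAGCACA"
        s = q[:10] + ("A" if q[10] != "A" else "C") + q[11:]
        a = align_local(q, s)
        assert (a.matches, a.mismatches) == (20, 1)
        assert a.identity == pytest.approx(20 / 21)

    def test_n_never_scores_as_match(self):
        # N aligned to N counts as a mismatch, so the self-alignment of a
        # 10-mer with one N scores 9 - 2 = 7, not 10
        a = align_local("ACGTNACGTT", "ACGTNACGTT")
        assert (a.matches, a.mismatches, a.score) == (9, 1, 7)

    @pytest.mark.parametrize("case", range(40))
    def test_matches_brute_force_on_tiny_pairs(self, case):
        rng = np.random.default_rng(1000 + case)
        a = "".join(rng.choice(list("ACGT"), rng.integers(4, 8)))
        b = "".join(rng.choice(list("ACGT"), rng.integers(4, 8)))
        assert align_local(a, b).score == brute_local(a, b)

    def test_matches_biopython_on_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            a = "".join(rng.choice(list("ACGT"), rng.integers(10, 13)))
            b = "".join(rng.choice(list("ACGT"), rng.integers(10, 13)))
            expected = max(biopython_local(a, b), 0.0)
            assert align_local(a, b).score == expected

    def test_reverse_pair_equals_oracle(self):
        rng = np.random.default_rng(3)
        a = "".join(rng.choice(list("ACGT"), 12))
        assert align_local(a, a[::-1]).score == brute_local(a, a[::-1])


class TestKarlinAltschul:
    def test_lambda_matches_bisection_oracle(self):
        params = karlin_altschul_params()
        assert params.lam == pytest.approx(bisect_lambda(), abs=1e-9)

    def test_high_score_drives_e_to_zero(self):
        assert evalue(500, 21, 10_000) < 1e-200

    def test_e_linear_in_search_space(self):
        e1 = evalue(15, 21, 1000)
        e2 = evalue(15, 21, 2000)
        assert e2 == pytest.approx(2 * e1)

    def test_nonpositive_score_capped_at_space(self):
        params = karlin_altschul_params()
        assert evalue(0, 20, 100) == pytest.approx(params.K * 20 * 100)
        assert evalue(-5, 20, 100) == pytest.approx(params.K * 20 * 100)

    def test_monotone_decreasing_in_score(self):
        es = [evalue(s, 21, 1000) for s in range(1, 25)]
        assert all(x > y for x, y in zip(es, es[1:]))


def _refs():
    return [
        MatureRef("osa-miR156a-5p", "osa", "miR156", "TGACAGAAGAGAGTGAGCACA"),
        MatureRef("tae-miR156b-5p", "tae", "miR156", "TGACAGAAGAGAGTGAGCACC"),
        MatureRef("ath-miR172b", "ath", "miR172", "AGAATCTTGATGATGCTGCAT"),
    ]


class TestSearch:
    def test_exact_read_retained(self):
        hits = search([UniqueRead("TGACAGAAGAGAGTGAGCACA", 5)], _refs())
        assert len(hits) == 1
        assert hits[0].ref.ref_id == "osa-miR156a-5p"
        assert hits[0].alignment.identity == 1.0
        assert hits[0].e_value <= 1e-4

    def test_identity_exactly_090_rejected(self):
        # two internal substitutions in a 20-mer: 18/20 columns = 0.90, not > 0.90
        ref = MatureRef("osa-miR399a", "osa", "miR399", "TGCCAAAGGAGAGTTGCCCT")
        seq = list(ref.sequence)
        seq[5] = "T" if seq[5] != "T" else "A"
        seq[12] = "A" if seq[12] != "A" else "C"
        hits = search([UniqueRead("".join(seq), 1)], [ref])
        assert hits == []

    def test_random_reads_yield_no_hits(self):
        rng = np.random.default_rng(5)
        uniques = [
            UniqueRead("".join(rng.choice(list("ACGT"), 22)), 1) for _ in range(2000)
        ]
        assert search(uniques, _refs()) == []

    def test_hits_satisfy_all_filters_post_hoc(self):
        rng = np.random.default_rng(9)
        refs = _refs()
        uniques = []
        for r in refs:
            seq = list(r.sequence)
            k = int(rng.integers(0, len(seq)))
            seq[k] = "ACGT"[int(rng.integers(4))]
            uniques.append(UniqueRead("".join(seq), 2))
        hits = search(uniques, refs)
        for h in hits:
            assert h.alignment.identity > 0.90
            assert h.e_value <= 1e-4
            shorter = min(len(h.read.sequence), len(h.ref.sequence))
            span = h.alignment.query_end - h.alignment.query_start
            assert span >= 0.90 * shorter

    def test_one_hit_per_read(self):
        hits = search([UniqueRead("TGACAGAAGAGAGTGAGCACA", 1)], _refs())
        assert len(hits) == 1  # both miR156 refs match; only the best is kept


class TestSummarize:
    def test_family_grouping(self):
        refs = _refs()
        hits = search(
            [
                UniqueRead("TGACAGAAGAGAGTGAGCACA", 3),
                UniqueRead("AGAATCTTGATGATGCTGCAT", 1),
            ],
            refs,
        )
        s = summarize_families(hits)
        assert (s.n_sequences, s.n_families) == (2, 2)
        assert s.n_families <= s.n_sequences

    def test_empty(self):
        s = summarize_families([])
        assert (s.n_sequences, s.n_families) == (0, 0)
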
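"""Weighted-pairing fold, stem-loop classification and ct round trips."""

import numpy as np
import pytest

from conmir.folding import (
    classify_stem_loop,
    fold_mfe,
    hairpin_loops,
    read_ct,
    write_ct,
)
from conmir.sequtils import revcomp
from oracles import best_fold_weight


class TestFold:
    def test_simple_hairpin(self):
        s = fold_mfe("GGGAAACCC")
        assert s.dot_bracket == "(((...)))"
        assert s.weighted_sum == 9
        assert s.weighted_sum == best_fold_weight("GGGAAACCC")

    def test_unpairable_sequence(self):
        s = fold_mfe("AAAAAA")
        assert s.pairs == () and s.score == 0.0

    def test_invalid_base_rejected(self):
        with pytest.raises(ValueError):
            fold_mfe("ACGTNACGTA")

    def test_min_loop_respected(self):
        for s_ in ("GAAAC", "GAAC"):
            st = fold_mfe(s_ + "TTTT")
            for i, j in st.pairs:
                assert j - i >= 4

    @pytest.mark.parametrize("case", range(150))
    def test_dp_equals_enumeration_oracle(self, case):
        rng = np.random.default_rng(5000 + case)
        seq = "".join(rng.choice(list("ACGT"), rng.integers(5, 15)))
        assert fold_mfe(seq).weighted_sum == best_fold_weight(seq)

    def test_reversal_scores_equal(self):
        # reversing the sequence swaps every pair (a, b) -> (b, a), and all
        # pair weights are symmetric under that swap (GC/CG, AU/UA, GU/UG);
        # reverse *complement* does not preserve scores because G:U maps to A:C
        rng = np.random.default_rng(77)
        for _ in range(25):
            seq = "".join(rng.choice(list("ACGT"), 30))
            assert fold_mfe(seq).weighted_sum == fold_mfe(seq[::-1]).weighted_sum

    def test_structures_are_valid(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), 60))
            st = fold_mfe(seq)
            seen = set()
            for i, j in st.pairs:
                assert j - i >= 4
                assert i not in seen and j not in seen
                seen |= {i, j}
            # pseudoknot-free: any two pairs are nested or disjoint
            for a, b in st.pairs:
                for c, d in st.pairs:
                    if a < c:
                        assert d < b or c > b

    def test_deterministic(self):
        seq = "GCGCAAAGCGCTTTGCGCAAAGCGC"
        assert fold_mfe(seq).dot_bracket == fold_mfe(seq).dot_bracket


class TestClassify:
    MATURE = "TGACAGAAGAGAGTGAGCACA"

    def test_perfect_planted_hairpin(self):
        hp = self.MATURE + "GCTAGA" + revcomp(self.MATURE)
        v = classify_stem_loop(fold_mfe(hp), 0, len(self.MATURE))
        assert v.is_stem_loop and v.arm == "5p"
        assert v.mature_paired_fraction == 1.0

    def test_three_prime_arm(self):
        hp = self.MATURE + "GCTAGA" + revcomp(self.MATURE)
        off = len(self.MATURE) + 6
        v = classify_stem_loop(fold_mfe(hp), off, len(self.MATURE))
        assert v.is_stem_loop and v.arm == "3p"

    def test_mature_centered_on_loop_fails(self):
        arm = "GCGCGCGCGC"
        hp = arm + "ATAT" + revcomp(arm)
        v = classify_stem_loop(fold_mfe(hp), 5, 14)  # spans the turn
        assert not v.is_stem_loop
        assert v.mature_crosses_loop

    def test_unstructured_window_fails(self):
        rng = np.random.default_rng(2)
        window = "".join(rng.choice(list("AT"), p=[0.7, 0.3], size=120))
        v = classify_stem_loop(fold_mfe(window), 50, 21)
        assert not v.is_stem_loop
        assert v.arm_paired_fraction < 0.6 or v.n_hairpin_loops != 1

    def test_degraded_star_mostly_fails(self):
        """Eight star substitutions break the duplex for most precursors.

        Chance pairing with flanks (and substitutions that land on wobble
        partners) lets a minority of degraded hairpins still pass, so the
        negative control is a rate, not an absolute: well under half classify
        as stem-loops, against 100% for perfect stars under identical
        conditions.
        """
        from conmir.synthetic import generate_reference, plant_precursors
        from conmir.precursor import extract_precursor, find_exact_matches

        n_pass = n_total = 0
        for seed in range(1, 9):
            refs, _ = generate_reference(6, 1, seed=seed)
            genome, truth = plant_precursors(
                refs, n_scaffolds=2, scaffold_length=4000, star_mismatches=8, seed=seed
            )
            for row in truth.itertuples():
                for locus in find_exact_matches(row.sequence, genome):
                    c = extract_precursor(row.mature_id, locus, genome)
                    v = classify_stem_loop(
                        fold_mfe(c.sequence), c.mature_offset, c.mature_length
                    )
                    n_total += 1
                    n_pass += v.is_stem_loop
        assert n_pass < 0.5 * n_total

    def test_flank_truncation_invariance(self):
        """Removing flank that holds no mature partners keeps the verdict."""
        hp = self.MATURE + "GCTAGA" + revcomp(self.MATURE)
        rng = np.random.default_rng(6)
        flank = "".join(rng.choice(list("ACGT"), 20))
        with_flank = classify_stem_loop(fold_mfe(flank + hp), 20, len(self.MATURE))
        without = classify_stem_loop(fold_mfe(hp), 0, len(self.MATURE))
        assert with_flank.is_stem_loop == without.is_stem_loop is True

    def test_span_outside_sequence_rejected(self):
        with pytest.raises(ValueError):
            classify_stem_loop(fold_mfe("GGGAAACCC"), 5, 10)


class TestCt:
    def test_nine_mer_layout(self):
        st = fold_mfe("GGGAAACCC")
        lines = write_ct(st, "toy").splitlines()
        assert lines[0].startswith("9\t")
        row1 = lines[1].split("\t")
        assert row1[1] == "G" and row1[4] == "9"  # base 1 pairs base 9

    def test_unpaired_structure_all_zero(self):
        st = fold_mfe("AAAAAA")
        assert all(l.split("\t")[4] == "0" for l in write_ct(st).splitlines()[1:])

    def test_round_trip_on_folded_sequences(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), rng.integers(15, 80)))
            st = fold_mfe(seq)
            assert read_ct(write_ct(st)) == st

    def test_malformed_line_reports_number(self):
        text = write_ct(fold_mfe("GGGAAACCC"))
        broken = text.splitlines()
        broken[3] = "badline"
        with pytest.raises(ValueError, match="line 4"):
            read_ct("\n".join(broken))


def test_hairpin_loops_found():
    st = fold_mfe("GGGAAACCC")
    assert hairpin_loops(st) == [(3, 5)]
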
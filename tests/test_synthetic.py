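"""Determinism, constraints and truth-table completeness of the generator."""

import numpy as np
import pytest

from conmir.synthetic import (
    SimConfig,
    default_site_specs,
    generate_go,
    generate_reference,
    generate_transcriptome,
    pick_stress_genes,
    plant_precursors,
    simulate_all,
    simulate_reads,
)


class TestReference:
    def test_counts_and_families(self):
        refs, truth = generate_reference(12, 3, seed=7)
        assert len(refs) == 36
        assert len({r.family for r in refs}) == 12
        assert len(truth) == 36

    def test_seed_reproducibility(self):
        a, _ = generate_reference(5, 2, seed=9)
        b, _ = generate_reference(5, 2, seed=9)
        assert a == b

    def test_variants_within_two_substitutions(self):
        _, truth = generate_reference(12, 3, seed=7)
        for row in truth.itertuples():
            diffs = sum(x != y for x, y in zip(row.sequence, row.canonical))
            assert diffs <= 2
            assert diffs == row.n_substitutions

    def test_lengths_in_mature_range(self):
        refs, _ = generate_reference(12, 3, seed=7)
        assert all(20 <= len(r.sequence) <= 22 for r in refs)


class TestPrecursors:
    def test_truth_complete_and_exact(self):
        refs, _ = generate_reference(6, 2, seed=1)
        genome, truth = plant_precursors(refs, n_scaffolds=2, seed=1)
        assert len(truth) == len(refs)
        from conmir.sequtils import revcomp

        for row in truth.itertuples():
            segment = genome[row.scaffold][row.mature_start : row.mature_end]
            expected = row.sequence if row.strand == "+" else revcomp(row.sequence)
            assert segment == expected

    def test_edge_planting_forces_truncation(self):
        from conmir.precursor import GenomeLocus, extract_precursor

        refs, _ = generate_reference(4, 1, seed=2)
        genome, truth = plant_precursors(refs, n_scaffolds=2, seed=2, n_edge=2)
        edge = truth[truth.hairpin_start == 30].iloc[0]
        locus = GenomeLocus(edge.scaffold, int(edge.mature_start), int(edge.mature_end), edge.strand)
        c = extract_precursor(edge.mature_id, locus, genome)
        assert min(c.upstream_flank, c.downstream_flank) < 80

    def test_capacity_overflow_rejected(self):
        refs, _ = generate_reference(12, 3, seed=1)
        with pytest.raises(ValueError, match="do not fit"):
            plant_precursors(refs, n_scaffolds=1, scaffold_length=1000, seed=1)


class TestReads:
    def test_seed_reproducibility(self):
        refs, _ = generate_reference(4, 1, seed=3)
        a, _ = simulate_reads(refs, seed=3)
        b, _ = simulate_reads(refs, seed=3)
        assert a == b

    def test_error_free_reads_recover_matures(self):
        from conmir import smallrna_prep as prep

        refs, _ = generate_reference(6, 1, seed=4)
        reads, truth = simulate_reads(
            refs, error_rate=0.0, decoy_fraction=0.0, depth_mean=50, seed=4
        )
        raws = [
            prep.RawRead(i, s, tuple(ord(c) - 33 for c in q)) for i, s, q in reads
        ]
        trimmed = list(prep.trim_reads(raws, adapter="TGGAATTCTCGGGTGCCAAGG"))
        assert len(trimmed) == len(reads)
        uniques = prep.collapse(r.sequence for r in trimmed)
        assert sum(u.count for u in uniques) == len(reads)
        unique_seqs = {u.sequence for u in uniques}
        assert all(r.sequence in unique_seqs for r in refs)

    def test_decoy_fraction_within_three_sigma(self):
        refs, _ = generate_reference(12, 3, seed=5)
        reads, truth = simulate_reads(
            refs[:30], decoy_fraction=0.3, depth_mean=120, seed=5
        )
        n = len(truth)
        n_decoy = int((truth.origin != "mature").sum())
        p = 0.3
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(n_decoy - n * p) < 3 * sigma

    def test_truth_has_row_per_read(self):
        refs, _ = generate_reference(3, 1, seed=6)
        reads, truth = simulate_reads(refs, seed=6)
        assert len(truth) == len(reads)
        assert set(truth.read_id) == {r[0] for r in reads}

    def test_error_rate_validated(self):
        refs, _ = generate_reference(2, 1, seed=7)
        with pytest.raises(ValueError):
            simulate_reads(refs, error_rate=0.2, seed=7)


class TestTranscriptome:
    def test_central_mismatch_spec_found_as_translation(self):
        from conmir.targets import scan_transcripts

        refs, _ = generate_reference(3, 1, seed=8)
        mirnas = [(r.ref_id, r.sequence) for r in refs]
        from conmir.synthetic import SiteSpec

        spec = SiteSpec(mirna_id=mirnas[0][0], mirna_seq=mirnas[0][1], states={10: "mismatch"})
        transcripts, truth = generate_transcriptome([spec], seed=8)
        row = truth.iloc[0]
        assert row.expectation == 2.0
        assert row.inhibition == "translation"
        hits = scan_transcripts(spec.mirna_id, spec.mirna_seq, transcripts)
        hit = next(h for h in hits if h.transcript_id == row.transcript_id)
        assert hit.duplex.expectation == 2.0
        assert hit.inhibition == "translation"

    def test_planted_ratio(self):
        refs, _ = generate_reference(12, 3, seed=9)
        mirnas = [(r.ref_id, r.sequence) for r in refs[:30]]
        specs = default_site_specs(mirnas, n_cleavage=20, n_translation=5, seed=9)
        _, truth = generate_transcriptome(specs, seed=9)
        assert (truth.inhibition == "cleavage").sum() == 20
        assert (truth.inhibition == "translation").sum() == 5
        assert (truth.expectation <= 3.0).all()

    def test_seed_reproducibility(self):
        refs, _ = generate_reference(3, 1, seed=10)
        mirnas = [(r.ref_id, r.sequence) for r in refs]
        specs = default_site_specs(mirnas, 4, 1, seed=10)
        a, _ = generate_transcriptome(specs, seed=10)
        b, _ = generate_transcriptome(specs, seed=10)
        assert a == b


class TestGoAndStress:
    def test_namespace_weights_within_three_sigma(self):
        genes = [f"g{i}" for i in range(50)]
        df = generate_go(
            genes,
            namespace_weights={"biological process": 0.4, "cellular component": 0.3,
                               "molecular function": 0.3},
            n_annotations=1000,
            seed=11,
        )
        counts = df.namespace.value_counts()
        for ns, w in [("biological process", 0.4), ("cellular component", 0.3),
                      ("molecular function", 0.3)]:
            sigma = np.sqrt(1000 * w * (1 - w))
            assert abs(counts[ns] - 1000 * w) < 3 * sigma

    def test_stress_genes_deterministic_subset(self):
        refs, _ = generate_reference(4, 1, seed=12)
        mirnas = [(r.ref_id, r.sequence) for r in refs]
        specs = default_site_specs(mirnas, 3, 1, seed=12)
        _, truth = generate_transcriptome(specs, seed=12)
        a = pick_stress_genes(truth, seed=12)
        b = pick_stress_genes(truth, seed=12)
        assert a == b
        assert set(a) <= set(truth.transcript_id)


def test_simulate_all_reproducible_bytes(tmp_path):
    cfg = SimConfig(n_families=3, n_species=1, n_planted=3, n_scaffolds=1,
                    scaffold_length=2500, depth_mean=5.0, n_cleavage_sites=2,
                    n_translation_sites=1, n_extra_transcripts=1,
                    transcript_length=200)
    pa = simulate_all(tmp_path / "a", seed=13, config=cfg)
    pb = simulate_all(tmp_path / "b", seed=13, config=cfg)
    for key in pa:
        assert pa[key].read_bytes() == pb[key].read_bytes()
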
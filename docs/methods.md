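# Methods

This note records the models and procedures implemented in `conmir`, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Read preparation

Adapter removal scans for the left-most occurrence of the 3' adapter
(default: the TruSeq small-RNA 3' adapter, `TGGAATTCTCGGGTGCCAAGG`). A
full-length occurrence may carry one mismatch; a partial occurrence is
accepted only as an exact suffix overlap of ≥ 6 nt at the read end — shorter
or inexact overlaps are indistinguishable from genomic sequence at useful
error rates. Quality trimming cuts the 3' tail after the last base with
phred ≥ 20. The retained length window is 16–30 nt: wide enough to bracket
the 18–24-nt range where plant mature miRNAs live, while excluding primer
dimers and longer degradation products. Reads with more than one N are
dropped; a single N is tolerated but can never score as a match downstream.

Class profiling replaces genome mapping with exact substring matching
against per-class reference sets, on either strand, with a fixed priority
order (first match wins). This keeps the profiling semantics (each read
assigned to exactly one class; counts sum to retained reads) without an
external aligner or a reference genome.

## Homology search

The aligner is a plain Smith–Waterman with linear gap penalty
(+1/−2/−3). Determinism: among co-optimal alignments the one with the
smallest subject start (then query start, subject end, query end) is
reported; traceback prefers diagonal over up over left.

E-values follow the Karlin–Altschul theory for ungapped scoring with i.i.d.
letters: λ is the positive root of Σ p_s e^(λ s) = 1 (solved by Brent's
method), H = λ Σ q_s s with q_s = p_s e^(λ s), and K uses the lattice-case
expression K = d·λ·e^(−2σ) / (H·(1 − e^(−λd))), σ accumulated over the
convolved distributions of k-step score sums until terms vanish. For
+1/−2 at uniform composition this gives λ = 1.3327, K = 0.6210, matching
the published ungapped constants for this scheme. Gapped alignments are
scored with the ungapped constants — with a −3 linear gap on 20-mers, gaps
are vanishingly rare in accepted hits, so the approximation is immaterial
here.

Filters: identity strictly > 0.90 with the BLAST convention (matches /
alignment columns), plus a coverage requirement — the alignment must span
≥ 90% of the shorter of read and reference. Identity alone would admit
10-nt perfect sub-alignments of longer reads; the coverage rule closes that
hole. E ≤ 10⁻⁴ computed against the total reference length. One best hit
per read, chosen by (lowest E, highest identity, lexicographic reference
id).

A shared-6-mer prefilter skips alignments that cannot pass the filters: any
hit with identity > 0.9 and coverage ≥ 0.9 must contain a common exact run
of ≥ 6 nt (pigeonhole over ≤ 2 non-matching columns in ≥ 14 aligned
columns), so the prefilter provably never changes search output.

## Precursor extraction and folding

Candidate windows are exact mature matches ± 80 nt, both strands, truncated
silently (but recorded) at scaffold edges; windows shorter than
mature + 40 nt are flagged short and excluded from folding. Minus-strand
windows are reverse-complemented so the mature always reads 5'→3'.

Folding maximises a weighted pair sum (GC = 3, AU = 2, GU = 1, minimum
hairpin loop 3, pseudoknot-free, lone pairs allowed) by the Nussinov
recurrence, reported as a negative "energy-like" score. This is a
deliberate simplification of full nearest-neighbour thermodynamics: the
pipeline uses folding only as a stem-loop screen, so duplex topology — not
kcal/mol — is the contract. Traceback is deterministic: leaving i unpaired
is preferred on ties (this avoids spurious enclosing pairs that pure
pairing-maximisation makes free), then pairing (i, j), then bifurcation at
the smallest split point. Note one consequence of allowing G:U — the fold
score is invariant under sequence *reversal* (pair partners swap, weights
are symmetric) but not under reverse complement, which maps G·U onto A·C.

Stem-loop classification is evaluated on the mature's *dominant arm*: the
largest subset of mature base pairs whose partners fall within one
contiguous window of mature length + 12 nt (the slack absorbs asymmetric
bulges). The verdict requires: no mature-internal pairs (a mature folded
onto its own terminal loop fails, reported as crossing the loop); the
dominant-arm partners entirely on one side of the mature; ≥ 60% of mature
bases paired into that arm; and exactly one hairpin loop strictly between
the mature and the arm. The dominant-arm framing exists because a
pairing-maximisation fold of a 181-nt window routinely adds a few stray
pairs from the mature termini into the flanks; a visual stem-loop screen
tolerates those, and so does this rule. The 0.60 threshold and the window
slack are configuration knobs.

Specificity of this screen is limited by the fold model: with no loop
penalties, random 181-nt windows can present chance "arms". Measured on
synthetic data, precursors whose star arm carries 8 substitutions still
classify as stem-loops in roughly a quarter of cases, and fully randomised
stars in about one in ten. Perfect-star precursors classify correctly at
100% across seeds. Real pre-miRNA screening should treat the verdict as a
filter, not proof.

Structures are emitted in dot-bracket and standard 6-column connect (ct)
format; `read_ct(write_ct(s))` is the identity.

## Target prediction

Duplexes are scored ungapped over the full miRNA length: miRNA position k
(1-based from the 5' end) faces site position L−k+1. Penalties: Watson–
Crick 0, G:U wobble 0.5, mismatch 1.0, doubled over positions 2–13 — the
seed-extended region where complementarity matters most for plant miRNAs.
The expectation is the penalty sum; sites above 3.0 are discarded, the best
site per transcript is kept, and hits are ranked by ascending expectation,
truncated to 50 per miRNA. A true mismatch (wobbles excluded) at positions
9–11 — the cleavage-site region — calls translational inhibition, otherwise
cleavage.

`hspsize` (default 18) is interpreted as the minimum length of the scored
complementary duplex: miRNAs shorter than it are not scanned, and the full
miRNA length is always scored. The alternative reading — requiring 18
*consecutive* non-mismatch positions — would make any site with a central
mismatch invisible at default parameters (the longest clean run around a
position-10 mismatch in a 21-mer is 11), i.e. no translational-inhibition
target could ever be reported; that cannot be the intended semantics of a
tool that reports both inhibition modes. Gapped sites (target bulges) are
out of scope.

## Conservation analysis and reports

The packaged evidence table is a 30-family × (5 species × 2 conditions)
boolean matrix of literature support for salt- and drought-responsiveness.
A family is stress-related for a condition when at least one species
carries evidence — under this reading the table yields 23 salt families,
24 drought families and 17 shared, with no family supported in all five
species, and these counts are locked in the acceptance tests. The packaged
stress-target table carries 30 records; gene identifiers are matched
case-insensitively with version suffixes stripped.

Composition reports merge U and T into one symbol (reported as U, the
mature-miRNA convention). GO clustering counts gene–term matches (each
distinct gene–term pair once), restricted to the three root namespaces,
with a top-10 table per namespace.

## Synthetic data

The generator emulates, from a single seed: a mature reference of 12
families × 3 species (random 20–22-mers, ≤ 2 substitutions between
variants of a family — enough to exercise the > 90% identity filter both
ways); genome scaffolds with one planted hairpin per mature (mature +
8-nt loop + reverse-complement star, perfect by default), strands
alternating, two hairpins deliberately placed 30 nt from a scaffold edge to
force flank truncation; reads at negative-binomial depth (mean 50,
dispersion 5 — heterogeneous abundance), each the mature with occasional
1-nt 3' jitter plus adapter and fill, 0.5% substitution errors, constant
Q35, and 30% decoys drawn from random sequence and toy class references; a
transcriptome with 20 cleavage-type and 5 translation-type planted sites of
exact specified mismatch structure; a GO table at 39/35/26%
BP/CC/MF proportions; and a stress-gene list drawn from the planted target
genes. Every generator draws from a per-function tagged seed stream, so a
shared seed never correlates two generators' outputs.

What it does not emulate: realistic Illumina error and quality profiles,
ligation bias, isomiR distributions beyond 1-nt jitter, repetitive or
low-complexity genomic background, paralogous precursor families, UTR/CDS
structure in transcripts, or a real GO DAG. Passing the recovery tests
therefore demonstrates the pipeline's internal correctness — that planted
signal at realistic signal-to-noise is recovered and decoys are rejected —
not performance on real libraries.

## Problem sizes and numerics

The test suite and the acceptance script run the full synthetic study at
its default size (≈ 2,000 reads, ≈ 60 precursor windows of 181 nt, ≈ 35
transcripts of 600 nt); folding is O(n³) per window and the whole
acceptance run completes in seconds. Oracles: the folding DP is checked
against exhaustive structure enumeration for sequences ≤ 14 nt; the aligner
against an independent implementation (Biopython's PairwiseAligner) and an
O(n⁴) substring brute force on very short pairs; λ against plain bisection.
Ties everywhere are broken deterministically (documented per module), and
reruns with identical configuration and seed are byte-identical, which the
suite asserts on whole output trees.

## Limitations

Lone pairs are allowed in folds; no MFEI or free-energy statistics are
computed. The homology search scans the given orientation only (small-RNA
reads are sequenced sense). Target scanning is ungapped and
single-site-per-transcript; multi-site synergy and site accessibility are
out of scope. The evidence and stress-target tables are static inputs — the
package does no literature mining.
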
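"""Small-RNA read preparation: adapter/quality trimming, collapsing, class profiling.

Reads come off a small-RNA library as insert + 3' adapter.  ``trim_read``
removes the adapter at its best left-most occurrence (allowing a single
mismatch for full-length occurrences and exact terminal overlaps of >= 6 nt),
clips low-quality 3' tails, and length-filters the insert.  ``collapse`` merges
identical inserts into unique sequences with occurrence counts, the standard
redundancy reduction before homology search.  ``classify_known_rna`` assigns
each unique read to the first known-RNA class (rRNA, tRNA, ...) whose
reference contains it as an exact substring on either strand.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

from Bio import SeqIO

from .sequtils import normalize, revcomp


@dataclass(frozen=True)
class RawRead:
    """A sequencing read with per-base phred qualities."""

    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id}: {len(self.sequence)} bases but "
                f"{len(self.qualities)} quality values"
            )
        if len(self.sequence) == 0:
            raise ValueError(f"read {self.id}: empty sequence")


@dataclass(frozen=True)
class UniqueRead:
    """A collapsed read: one distinct sequence and how often it was seen."""

    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclass
class ClassProfile:
    """Read counts per known-RNA class, in a fixed priority order.

    ``counts`` maps class label -> number of reads (weighted by collapse
    counts, so the values sum to the number of retained trimmed reads).
    """

    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def fractions(self) -> dict[str, float]:
        t = self.total
        return {k: (v / t if t else 0.0) for k, v in self.counts.items()}

    def write_tsv(self, path) -> None:
        t = self.total
        with open(path, "w") as fh:
            fh.write("class\treads\tfraction\n")
            for label, n in self.counts.items():
                frac = n / t if t else 0.0
                fh.write(f"{label}\t{n}\t{frac:.6f}\n")


def read_fastq(path) -> Iterator[RawRead]:
    """Stream phred+33 FASTQ into :class:`RawRead` (sequence normalised to DNA)."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield RawRead(
            id=rec.id,
            sequence=normalize(str(rec.seq)),
            qualities=tuple(rec.letter_annotations["phred_quality"]),
        )


def _find_adapter(sequence: str, adapter: str) -> int:
    """Left-most 3' adapter start, or -1.

    Full-length occurrences may carry one mismatch; partial occurrences are
    accepted only as exact suffix overlaps of >= 6 nt at the read end.
    """
    n, a = len(sequence), len(adapter)
    for p in range(n):
        overlap = min(a, n - p)
        window = sequence[p : p + overlap]
        if overlap == a:
            mm = sum(1 for x, y in zip(window, adapter) if x != y)
            if mm <= 1:
                return p
        elif overlap >= 6 and window == adapter[:overlap]:
            return p
    return -1


def trim_read(
    read: RawRead,
    adapter: str,
    quality_cutoff: int = 20,
    min_len: int = 16,
    max_len: int = 30,
) -> Optional[RawRead]:
    """Trim adapter and low-quality 3' tail; return the insert or None if rejected.

    Rejection reasons: trimmed length outside [min_len, max_len], or more than
    one ambiguous (N) base.  The output is always a prefix of the input insert.
    """
    adapter = normalize(adapter)
    if len(adapter) == 0:
        raise ValueError("adapter must be non-empty")
    if len(adapter) < 8:
        raise ValueError("adapter must be at least 8 nt")
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")

    seq, quals = read.sequence, read.qualities
    p = _find_adapter(seq, adapter)
    if p >= 0:
        seq, quals = seq[:p], quals[:p]

    # cut the 3' tail at the last base meeting the quality cutoff
    keep = len(seq)
    while keep > 0 and quals[keep - 1] < quality_cutoff:
        keep -= 1
    seq, quals = seq[:keep], quals[:keep]

    if not (min_len <= len(seq) <= max_len):
        return None
    if seq.count("N") > 1:
        return None
    return RawRead(id=read.id, sequence=seq, qualities=tuple(quals))


def trim_reads(
    reads: Iterable[RawRead],
    adapter: str,
    quality_cutoff: int = 20,
    min_len: int = 16,
    max_len: int = 30,
) -> Iterator[RawRead]:
    for read in reads:
        trimmed = trim_read(read, adapter, quality_cutoff, min_len, max_len)
        if trimmed is not None:
            yield trimmed


def collapse(sequences: Iterable[str]) -> list[UniqueRead]:
    """Merge identical sequences, keeping occurrence counts.

    Output is sorted by descending count, ties broken lexicographically, and
    conserves the total: sum of counts == number of input sequences.
    """
    counter: Counter[str] = Counter()
    for seq in sequences:
        if not seq:
            raise ValueError("collapse: empty sequence in input")
        counter[seq] += 1
    return [
        UniqueRead(sequence=s, count=c)
        for s, c in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def write_collapsed_fasta(path, uniques: Sequence[UniqueRead]) -> None:
    """Write collapsed reads as FASTA with ``>u{rank}_x{count}`` headers."""
    with open(path, "w") as fh:
        for rank, u in enumerate(uniques, start=1):
            fh.write(f">u{rank}_x{u.count}\n{u.sequence}\n")


def classify_known_rna(
    uniques: Sequence[UniqueRead],
    references: Sequence[tuple[str, Sequence[str]]],
) -> ClassProfile:
    """Assign each unique read to the first class containing it as a substring.

    ``references`` is an ordered list of (class label, reference sequences);
    the order is the priority.  Matching is exact, on either strand.  Reads
    containing an N are never counted as a match.  Unmatched reads fall into
    the terminal "unannotated" class.  Counts are weighted by collapse counts.
    """
    labels = [label for label, _ in references]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate class labels in references")

    # concatenate each class's references with a separator that can never match
    haystacks = [
        (label, "#".join(normalize(s) for s in seqs)) for label, seqs in references
    ]
    counts: dict[str, int] = {label: 0 for label in labels}
    counts["unannotated"] = 0
    for u in uniques:
        assigned = "unannotated"
        if "N" not in u.sequence:
            rc = revcomp(u.sequence)
            for label, hay in haystacks:
                if u.sequence in hay or rc in hay:
                    assigned = label
                    break
        counts[assigned] += u.count
    return ClassProfile(counts=counts)
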
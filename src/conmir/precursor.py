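"""Precursor candidate extraction: exact genomic matches of matures plus flanks.

A putative mature miRNA is located by exact string match in genome scaffolds
(both strands), and a candidate precursor window is cut out with up to 80 nt
of flank on each side, truncated silently at scaffold edges but with the
truncation recorded.  Minus-strand windows are reverse-complemented so the
candidate sequence always carries the mature itself (5'->3') at
``mature_offset``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .sequtils import normalize, revcomp

DEFAULT_FLANK = 80
#: candidates shorter than mature + this many flank nt are flagged "short"
MIN_EXTRA = 40


@dataclass(frozen=True)
class GenomeLocus:
    scaffold_id: str
    start: int  # 0-based half-open, plus-strand coordinates
    end: int
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid locus coordinates {self.start}..{self.end}")


@dataclass(frozen=True)
class PrecursorCandidate:
    """A strand-oriented precursor window containing the mature sequence."""

    mature_id: str
    sequence: str
    locus: GenomeLocus  # full window, plus-strand genome coordinates
    mature_offset: int
    mature_length: int
    upstream_flank: int
    downstream_flank: int

    @property
    def mature_sequence(self) -> str:
        return self.sequence[self.mature_offset : self.mature_offset + self.mature_length]

    @property
    def is_short(self) -> bool:
        """True when edge truncation left too little flank to fold informatively."""
        return len(self.sequence) < self.mature_length + MIN_EXTRA


def find_exact_matches(
    mature: str, scaffolds: Mapping[str, str] | Sequence[tuple[str, str]]
) -> list[GenomeLocus]:
    """Every exact occurrence of ``mature`` on either strand of the scaffolds.

    Minus-strand loci are occurrences of the reverse complement, reported in
    plus-strand coordinates.  Sorted by (scaffold, start, strand).
    """
    mature = normalize(mature)
    if "N" in mature:
        raise ValueError("mature sequence contains N; not searchable")
    if len(mature) < 15:
        raise ValueError("mature sequence shorter than 15 nt")
    items = scaffolds.items() if isinstance(scaffolds, Mapping) else scaffolds
    loci: list[GenomeLocus] = []
    rc = revcomp(mature)
    for scaffold_id, seq in items:
        seq = normalize(seq)
        for needle, strand in ((mature, "+"), (rc, "-")):
            p = seq.find(needle)
            while p >= 0:
                loci.append(GenomeLocus(scaffold_id, p, p + len(needle), strand))
                p = seq.find(needle, p + 1)
    loci.sort(key=lambda l: (l.scaffold_id, l.start, l.strand))
    return loci


def extract_precursor(
    mature_id: str,
    locus: GenomeLocus,
    scaffolds: Mapping[str, str],
    flank: int = DEFAULT_FLANK,
) -> PrecursorCandidate:
    """Cut the [start - flank, end + flank) window, clipped to scaffold bounds.

    For minus-strand loci the window is reverse-complemented and the offsets
    recomputed so the mature reads 5'->3' inside the candidate sequence.
    """
    seq = normalize(scaffolds[locus.scaffold_id])
    left = max(0, locus.start - flank)
    right = min(len(seq), locus.end + flank)
    window = seq[left:right]
    left_flank = locus.start - left
    right_flank = right - locus.end
    if locus.strand == "+":
        upstream, downstream = left_flank, right_flank
    else:
        window = revcomp(window)
        upstream, downstream = right_flank, left_flank
    return PrecursorCandidate(
        mature_id=mature_id,
        sequence=window,
        locus=GenomeLocus(locus.scaffold_id, left, right, locus.strand),
        mature_offset=upstream,
        mature_length=locus.end - locus.start,
        upstream_flank=upstream,
        downstream_flank=downstream,
    )


def candidate_header(c: PrecursorCandidate) -> str:
    """FASTA header, genome coordinates 1-based inclusive."""
    l = c.locus
    return (
        f"{c.mature_id}|{l.scaffold_id}:{l.start + 1}-{l.end}({l.strand})"
        f"|offset={c.mature_offset}"
    )


def write_candidates(fasta_path, tsv_path, candidates: Sequence[PrecursorCandidate]) -> None:
    with open(fasta_path, "w") as fa, open(tsv_path, "w") as tsv:
        tsv.write(
            "mature_id\tscaffold\tstart\tend\tstrand\tmature_offset\t"
            "mature_length\tupstream_flank\tdownstream_flank\tshort\n"
        )
        for c in candidates:
            fa.write(f">{candidate_header(c)}\n{c.sequence}\n")
            l = c.locus
            tsv.write(
                f"{c.mature_id}\t{l.scaffold_id}\t{l.start + 1}\t{l.end}\t{l.strand}\t"
                f"{c.mature_offset}\t{c.mature_length}\t{c.upstream_flank}\t"
                f"{c.downstream_flank}\t{int(c.is_short)}\n"
            )
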
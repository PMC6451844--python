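"""Small shared sequence helpers (DNA alphabet, reverse complement, FASTA I/O)."""

from __future__ import annotations

from typing import Iterable, Iterator

from Bio import SeqIO

DNA = "ACGT"
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Watson-Crick partners on the DNA alphabet (U is normalised to T upstream).
WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
#: G:U wobble written on the DNA alphabet (U == T).
GU_PAIRS = {("G", "T"), ("T", "G")}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def normalize(seq: str) -> str:
    """Uppercase and convert RNA U to DNA T."""
    return seq.upper().replace("U", "T")


def read_fasta(path) -> Iterator[tuple[str, str]]:
    for rec in SeqIO.parse(str(path), "fasta"):
        yield rec.description, normalize(str(rec.seq))


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n{seq}\n")
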
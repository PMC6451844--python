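"""Complementarity-based miRNA target prediction with inhibition-mode calls.

A duplex between a miRNA (5'->3') and a same-length transcript window is
scored by an expectation penalty in the psRNATarget style: Watson-Crick match
0, G:U wobble 0.5, mismatch 1.0, with penalties doubled over the functionally
critical miRNA positions 2-13; lower expectation means stronger
complementarity.  miRNA position k pairs with window position L-k+1.  A site
with any true mismatch (wobbles excluded) at the central positions 9-11 is
predicted to act by translational inhibition, otherwise by transcript
cleavage.

``scan_transcripts`` slides the miRNA over every transcript window, keeps the
best site per transcript under the expectation ceiling, and returns the
``top_n`` hits ranked by ascending expectation.  ``hspsize`` is the minimum
length of the scored complementary duplex: miRNAs shorter than it are not
scanned (the full miRNA length is always scored).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .sequtils import GU_PAIRS, WC_PAIRS, normalize

MATCH, GU, MISMATCH = 0, 1, 2
_STATE_NAMES = {MATCH: "match", GU: "GU", MISMATCH: "mismatch"}

#: miRNA positions (1-based, inclusive) whose penalties are doubled
SEED_REGION = (2, 13)
#: central positions whose mismatches flip the call to translational inhibition
CENTRAL_REGION = (9, 11)

DEFAULT_MAX_EXPECTATION = 3.0
DEFAULT_HSPSIZE = 18
DEFAULT_TOP_N = 50

_BASE_INDEX = {b: i for i, b in enumerate("ACGTN")}


def _state_table() -> np.ndarray:
    t = np.full((5, 5), MISMATCH, dtype=np.int8)
    for a, b in WC_PAIRS:
        t[_BASE_INDEX[a], _BASE_INDEX[b]] = MATCH
    for a, b in GU_PAIRS:
        t[_BASE_INDEX[a], _BASE_INDEX[b]] = GU
    return t


_STATES = _state_table()
_PENALTY = np.array([0.0, 0.5, 1.0])


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(b, 4) for b in seq], dtype=np.int8)


def _position_weights(L: int, seed_region: tuple[int, int] = SEED_REGION) -> np.ndarray:
    k = np.arange(1, L + 1)
    return np.where((k >= seed_region[0]) & (k <= seed_region[1]), 2.0, 1.0)


@dataclass(frozen=True)
class DuplexScore:
    """Expectation penalty and per-position pairing states of one site."""

    expectation: float
    states: tuple[str, ...]  # indexed by miRNA position 1..L from the 5' end
    site_start: int  # 0-based half-open on the transcript
    site_end: int


@dataclass(frozen=True)
class TargetHit:
    mirna_id: str
    transcript_id: str
    duplex: DuplexScore
    inhibition: str  # 'cleavage' or 'translation'
    rank: int


def score_duplex(mirna: str, site: str, site_start: int = 0) -> DuplexScore:
    """Score an ungapped duplex of ``mirna`` against a same-length site window."""
    mirna, site = normalize(mirna), normalize(site)
    L = len(mirna)
    if len(site) != L:
        raise ValueError(f"site length {len(site)} != miRNA length {L}")
    m = _encode(mirna)
    s = _encode(site)[::-1]  # miRNA position k faces site position L-k+1
    states = _STATES[m, s]
    expectation = float((_PENALTY[states] * _position_weights(L)).sum())
    return DuplexScore(
        expectation=expectation,
        states=tuple(_STATE_NAMES[int(x)] for x in states),
        site_start=site_start,
        site_end=site_start + L,
    )


def classify_inhibition(d: DuplexScore, central: tuple[int, int] = CENTRAL_REGION) -> str:
    """'translation' iff a true mismatch occurs at a central miRNA position."""
    lo, hi = central
    for k in range(lo, min(hi, len(d.states)) + 1):
        if d.states[k - 1] == "mismatch":
            return "translation"
    return "cleavage"


def _best_site(mirna_arr: np.ndarray, transcript: str, max_expectation: float):
    """Best (lowest-expectation, then leftmost) window, or None."""
    L = len(mirna_arr)
    t = _encode(normalize(transcript))
    if len(t) < L:
        return None
    windows = np.lib.stride_tricks.sliding_window_view(t, L)[:, ::-1]
    states = _STATES[mirna_arr[None, :], windows]
    expectations = (_PENALTY[states] * _position_weights(L)[None, :]).sum(axis=1)
    best = int(np.argmin(expectations))  # argmin takes the leftmost tie
    if expectations[best] > max_expectation:
        return None
    return best, float(expectations[best])


def scan_transcripts(
    mirna_id: str,
    mirna: str,
    transcripts: Mapping[str, str] | Sequence[tuple[str, str]],
    max_expectation: float = DEFAULT_MAX_EXPECTATION,
    hspsize: int = DEFAULT_HSPSIZE,
    top_n: int = DEFAULT_TOP_N,
) -> list[TargetHit]:
    """Best target site per transcript for one miRNA, ranked and truncated.

    Transcripts are scanned on the given (sense) strand only.  Hits are kept
    when expectation <= ``max_expectation``, sorted ascending by expectation
    with ties on transcript id, truncated to ``top_n`` and ranked from 1.
    """
    mirna = normalize(mirna)
    if len(mirna) < hspsize:
        return []
    items = transcripts.items() if isinstance(transcripts, Mapping) else transcripts
    m = _encode(mirna)
    found: list[tuple[float, str, int]] = []
    for transcript_id, seq in items:
        best = _best_site(m, seq, max_expectation)
        if best is not None:
            found.append((best[1], transcript_id, best[0]))
    found.sort(key=lambda x: (x[0], x[1]))
    lookup = dict(items)
    hits = []
    for rank, (_, transcript_id, start) in enumerate(found[:top_n], start=1):
        site = normalize(lookup[transcript_id])[start : start + len(mirna)]
        d = score_duplex(mirna, site, site_start=start)
        hits.append(
            TargetHit(
                mirna_id=mirna_id,
                transcript_id=transcript_id,
                duplex=d,
                inhibition=classify_inhibition(d),
                rank=rank,
            )
        )
    return hits


def summarize_cleavage_fraction(hits: Iterable[TargetHit]) -> tuple[float, int, int]:
    """(cleavage fraction, n_cleavage, n_translation); fraction 0 when empty."""
    n_cleav = n_trans = 0
    for h in hits:
        if h.inhibition == "cleavage":
            n_cleav += 1
        else:
            n_trans += 1
    total = n_cleav + n_trans
    return (n_cleav / total if total else 0.0), n_cleav, n_trans


def write_targets_tsv(path, hits: Sequence[TargetHit]) -> None:
    """Target table with 1-based inclusive site coordinates and a duplex line.

    The duplex column draws the site 5'->3' with '|' for Watson-Crick pairs,
    'o' for G:U wobbles and '.' for mismatches.
    """
    bonds = {"match": "|", "GU": "o", "mismatch": "."}
    with open(path, "w") as fh:
        fh.write(
            "mirna\ttranscript\tsite_start\tsite_end\texpectation\t"
            "inhibition\trank\tduplex\n"
        )
        for h in hits:
            diagram = "".join(bonds[s] for s in reversed(h.duplex.states))
            fh.write(
                f"{h.mirna_id}\t{h.transcript_id}\t{h.duplex.site_start + 1}\t"
                f"{h.duplex.site_end}\t{h.duplex.expectation:g}\t{h.inhibition}\t"
                f"{h.rank}\t{diagram}\n"
            )
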
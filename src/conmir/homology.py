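"""Homology search of collapsed reads against a mature miRNA reference.

Putative conserved mature miRNAs are recognised by optimal local alignment
(Smith-Waterman, match +1 / mismatch -2 / gap -3) of each unique read against
every reference mature, with three filters: alignment identity strictly above
a cutoff (default 0.90), alignment coverage of at least 90% of the shorter
sequence, and a Karlin-Altschul E-value at most 1e-4.  The E-value follows
E = K * m * n * exp(-lambda * S) with lambda and K computed once for the
scoring scheme under a uniform base composition: lambda solves
sum_s p_s * exp(lambda * s) = 1 and K is evaluated with the lattice-case
formula K = d * lambda * exp(-2*sigma) / (H * (1 - exp(-lambda*d))), where
sigma accumulates contributions from the distributions of k-step score sums.

Family assignment parses miRBase-style identifiers: ``osa-miR156a-5p`` has
species code ``osa`` and family ``miR156`` (letter variants and arm suffixes
do not split families).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .sequtils import normalize, read_fasta
from .smallrna_prep import UniqueRead

logger = logging.getLogger(__name__)

_MIRBASE_ID = re.compile(r"^([a-zA-Z]{3,4})-(miR\d+)[a-zA-Z]*(?:[-.].*)?$")


@dataclass(frozen=True)
class MatureRef:
    """One mature miRNA reference record (U already normalised to T)."""

    ref_id: str
    species_code: str
    family: str
    sequence: str


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -2
    gap: int = -3


@dataclass(frozen=True)
class Alignment:
    """A local alignment in 0-based half-open coordinates."""

    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    matches: int
    mismatches: int
    gaps: int
    score: float

    @property
    def columns(self) -> int:
        return self.matches + self.mismatches + self.gaps

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


@dataclass(frozen=True)
class MiRnaHit:
    """Best homology match of one unique read, with E-value and family."""

    read: UniqueRead
    ref: MatureRef
    alignment: Alignment
    e_value: float

    @property
    def family(self) -> str:
        return self.ref.family


def parse_mirbase_fasta(path) -> list[MatureRef]:
    """Parse a mature-miRNA FASTA with miRBase-style headers.

    Records whose identifier does not match ``xxx-miR{N}...`` are skipped with
    a logged warning (and counted in the log message).
    """
    refs: list[MatureRef] = []
    skipped = 0
    for header, seq in read_fasta(path):
        ref_id = header.split()[0]
        m = _MIRBASE_ID.match(ref_id)
        if m is None:
            skipped += 1
            logger.warning("skipping non-miRBase header: %s", ref_id)
            continue
        refs.append(
            MatureRef(
                ref_id=ref_id,
                species_code=m.group(1),
                family=m.group(2),
                sequence=seq,
            )
        )
    if skipped:
        logger.warning("parse_mirbase_fasta: skipped %d records", skipped)
    return refs


def align_local(query: str, subject: str, scoring: Scoring = Scoring()) -> Alignment:
    """Optimal local alignment (Smith-Waterman, linear gap penalty).

    Deterministic: among co-optimal alignments the one with the smallest
    subject_start (then query_start, subject_end, query_end) is returned.
    Traceback prefers diagonal over up (query gap consumed) over left.
    An N never scores as a match.
    """
    q, s = normalize(query), normalize(subject)
    m, n = len(q), len(s)
    ms, mm, g = scoring.match, scoring.mismatch, scoring.gap
    H = [[0] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        row, prev = H[i], H[i - 1]
        for j in range(1, n + 1):
            sub = ms if (qi == s[j - 1] and qi != "N") else mm
            h = max(0, prev[j - 1] + sub, prev[j] + g, row[j - 1] + g)
            row[j] = h
            if h > best:
                best = h
    if best == 0:
        return Alignment(0, 0, 0, 0, 0, 0, 0, 0.0)

    ends = [(i, j) for i in range(1, m + 1) for j in range(1, n + 1) if H[i][j] == best]
    candidates = []
    for ei, ej in ends:
        i, j = ei, ej
        matches = mismatches = gaps = 0
        while H[i][j] > 0:
            sub = ms if (q[i - 1] == s[j - 1] and q[i - 1] != "N") else mm
            if i > 0 and j > 0 and H[i][j] == H[i - 1][j - 1] + sub:
                if sub == ms:
                    matches += 1
                else:
                    mismatches += 1
                i, j = i - 1, j - 1
            elif i > 0 and H[i][j] == H[i - 1][j] + g:
                gaps += 1
                i -= 1
            else:
                gaps += 1
                j -= 1
        candidates.append(
            ((j, i, ej, ei), Alignment(i, ei, j, ej, matches, mismatches, gaps, float(best)))
        )
    return min(candidates, key=lambda c: c[0])[1]


# ---------------------------------------------------------------------------
# Karlin-Altschul statistics


@dataclass
class KarlinAltschul:
    """lambda, K and H for an ungapped scoring scheme under i.i.d. letters."""

    lam: float
    K: float
    H: float


def _score_distribution(scoring: Scoring, p_match: float = 0.25) -> tuple[np.ndarray, int]:
    """Per-column score distribution as (probs over [min..max], min score)."""
    lo, hi = min(scoring.mismatch, scoring.match), max(scoring.mismatch, scoring.match)
    probs = np.zeros(hi - lo + 1)
    probs[scoring.match - lo] += p_match
    probs[scoring.mismatch - lo] += 1.0 - p_match
    return probs, lo


@lru_cache(maxsize=8)
def karlin_altschul_params(scoring: Scoring = Scoring(), p_match: float = 0.25) -> KarlinAltschul:
    """Solve for lambda and evaluate K, H for the per-column score model.

    lambda is the positive root of sum_s p_s exp(lambda*s) = 1 (requires a
    negative expected score).  K uses the lattice-case expression with sigma
    accumulated over convolved k-step score-sum distributions until the terms
    become negligible.
    """
    probs, lo = _score_distribution(scoring, p_match)
    values = np.arange(lo, lo + len(probs))
    if float(probs @ values) >= 0:
        raise ValueError("expected per-column score must be negative")

    def f(lam: float) -> float:
        return float(probs @ np.exp(lam * values)) - 1.0

    lam = float(brentq(f, 1e-9, 50.0, xtol=1e-14, rtol=1e-15))
    H = lam * float(probs @ (values * np.exp(lam * values)))

    d = int(np.gcd.reduce(np.abs(values[probs > 0]).astype(int)))
    sigma = 0.0
    dist = probs.copy()
    dist_lo = lo
    for k in range(1, 400):
        vals_k = np.arange(dist_lo, dist_lo + len(dist))
        nonneg = float(dist[vals_k >= 0].sum())
        neg = float(dist[vals_k < 0] @ np.exp(lam * vals_k[vals_k < 0]))
        term = (nonneg + neg) / k
        sigma += term
        if term < 1e-14 and k > 10:
            break
        dist = np.convolve(dist, probs)
        dist_lo += lo
    K = d * lam * math.exp(-2.0 * sigma) / (H * (1.0 - math.exp(-lam * d)))
    return KarlinAltschul(lam=lam, K=K, H=H)


def evalue(
    score: float,
    m: int,
    n: int,
    params: Optional[KarlinAltschul] = None,
) -> float:
    """Karlin-Altschul expected number of chance alignments scoring >= score.

    E = K*m*n*exp(-lambda*score); a non-positive score is capped at the search
    space size K*m*n (reported, never filter-passing).
    """
    if params is None:
        params = karlin_altschul_params()
    space = params.K * m * n
    if score <= 0:
        return space
    return space * math.exp(-params.lam * score)


# ---------------------------------------------------------------------------
# Search


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}

#: Shortest exact run a qualifying hit can have (identity > 0.9 with coverage
#: >= 0.9 of the shorter sequence forces a common substring of this length),
#: so prefiltering on a shared 6-mer never changes search output.
_PREFILTER_K = 6


def search(
    uniques: Sequence[UniqueRead],
    refs: Sequence[MatureRef],
    min_identity: float = 0.90,
    max_evalue: float = 1e-4,
    min_coverage: float = 0.90,
    scoring: Scoring = Scoring(),
) -> list[MiRnaHit]:
    """Best reference hit per unique read, filtered for confident homology.

    Per read the best alignment is chosen by (lowest E-value, then highest
    identity, then lexicographic ref_id) and retained only if identity is
    strictly greater than ``min_identity``, the alignment covers at least
    ``min_coverage`` of the shorter of read and reference, and E-value is at
    most ``max_evalue``.
    """
    if not refs:
        raise ValueError("reference set must be non-empty")
    params = karlin_altschul_params(scoring)
    n_total = sum(len(r.sequence) for r in refs)
    logger.info(
        "homology search: lambda=%.6f K=%.6f over %d refs (%d nt)",
        params.lam, params.K, len(refs), n_total,
    )
    ref_kmers = [(r, _kmer_set(r.sequence, _PREFILTER_K)) for r in refs]

    hits: list[MiRnaHit] = []
    for u in uniques:
        read_kmers = _kmer_set(u.sequence, _PREFILTER_K)
        best: Optional[tuple[tuple, MiRnaHit]] = None
        for ref, kmers in ref_kmers:
            if not (read_kmers & kmers):
                continue
            aln = align_local(u.sequence, ref.sequence, scoring)
            if aln.score <= 0:
                continue
            e = evalue(aln.score, len(u.sequence), n_total, params)
            key = (e, -aln.identity, ref.ref_id)
            if best is None or key < best[0]:
                best = (key, MiRnaHit(read=u, ref=ref, alignment=aln, e_value=e))
        if best is None:
            continue
        hit = best[1]
        aln = hit.alignment
        shorter_is_query = len(u.sequence) <= len(hit.ref.sequence)
        span = (
            aln.query_end - aln.query_start
            if shorter_is_query
            else aln.subject_end - aln.subject_start
        )
        coverage = span / min(len(u.sequence), len(hit.ref.sequence))
        if (
            aln.identity > min_identity
            and coverage >= min_coverage
            and hit.e_value <= max_evalue
        ):
            hits.append(hit)
    return hits


@dataclass
class FamilySummary:
    n_sequences: int
    n_families: int
    table: pd.DataFrame = field(repr=False)


def summarize_families(hits: Iterable[MiRnaHit]) -> FamilySummary:
    """Count distinct hit sequences and distinct miRNA families.

    The per-family table lists the number of distinct sequences and the summed
    read counts for each family, sorted by descending sequence count.
    """
    rows = [
        {"family": h.family, "sequence": h.read.sequence, "count": h.read.count}
        for h in hits
    ]
    if not rows:
        return FamilySummary(0, 0, pd.DataFrame(columns=["family", "n_sequences", "reads"]))
    df = pd.DataFrame(rows)
    table = (
        df.groupby("family")
        .agg(n_sequences=("sequence", "nunique"), reads=("count", "sum"))
        .reset_index()
        .sort_values(["n_sequences", "family"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return FamilySummary(
        n_sequences=df["sequence"].nunique(),
        n_families=df["family"].nunique(),
        table=table,
    )


def write_hits_tsv(path, hits: Sequence[MiRnaHit]) -> None:
    """Hits table with 1-based inclusive alignment coordinates."""
    with open(path, "w") as fh:
        fh.write(
            "read\tcount\tref_id\tfamily\tidentity\te_value\t"
            "q_start\tq_end\ts_start\ts_end\n"
        )
        for h in hits:
            a = h.alignment
            fh.write(
                f"{h.read.sequence}\t{h.read.count}\t{h.ref.ref_id}\t{h.family}\t"
                f"{a.identity:.4f}\t{h.e_value:.3g}\t"
                f"{a.query_start + 1}\t{a.query_end}\t{a.subject_start + 1}\t{a.subject_end}\n"
            )
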
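"""Secondary-structure prediction and stem-loop classification of precursors.

The folder is a weighted pairing-maximisation dynamic programme (Nussinov
recurrence) over pseudoknot-free structures with a minimum hairpin loop of
3 nt.  Pairs are weighted GC=3, AU=2, GU=1, so the optimum tracks duplex
stability qualitatively without Turner free-energy parameters; the reported
score is the negative weighted sum, an "energy-like" number where lower means
more paired.  Traceback is deterministic: pairing (i, j) is preferred over
leaving i unpaired, which is preferred over bifurcation at the smallest split.

``classify_stem_loop`` applies an explicit, reproducible stand-in for the
visual pre-miRNA check: the mature must lie on one arm of a single-loop stem,
pairing only outside itself, not crossing a terminal loop, with at least 60%
of its bases paired.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .sequtils import normalize

#: pair weights on the DNA alphabet (U normalised to T)
PAIR_WEIGHT = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "T"): 2, ("T", "A"): 2,
    ("G", "T"): 1, ("T", "G"): 1,
}
MIN_LOOP = 3  # unpaired bases enclosed by a pair: j - i > MIN_LOOP


@dataclass(frozen=True)
class SecondaryStructure:
    sequence: str
    pairs: tuple[tuple[int, int], ...]  # (i, j) with i < j, sorted by i
    dot_bracket: str
    score: float  # negative weighted pairing sum

    @property
    def weighted_sum(self) -> float:
        return -self.score

    def partner(self) -> list[Optional[int]]:
        p: list[Optional[int]] = [None] * len(self.sequence)
        for i, j in self.pairs:
            p[i], p[j] = j, i
        return p


@dataclass(frozen=True)
class HairpinVerdict:
    is_stem_loop: bool
    arm: str  # '5p', '3p' or 'none'
    mature_paired_fraction: float  # fraction of mature bases paired at all
    arm_paired_fraction: float  # fraction paired into the dominant arm
    mature_crosses_loop: bool
    n_hairpin_loops: int  # hairpin loops between mature and its arm


def pair_weight(a: str, b: str) -> int:
    return PAIR_WEIGHT.get((a, b), 0)


def _dot_bracket(n: int, pairs: Sequence[tuple[int, int]]) -> str:
    chars = ["."] * n
    for i, j in pairs:
        chars[i], chars[j] = "(", ")"
    return "".join(chars)


def fold_mfe(sequence: str) -> SecondaryStructure:
    """Maximum weighted-pairing structure of ``sequence`` by dynamic programming.

    Raises on bases outside {A, C, G, T/U} and on empty input.
    """
    seq = normalize(sequence)
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"invalid bases for folding: {sorted(bad)}")
    n = len(seq)
    # weight matrix W[i, j] for potential pairs
    idx = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.zeros((256, 256), dtype=np.int64)
    for (a, b), w in PAIR_WEIGHT.items():
        lut[ord(a), ord(b)] = w
    W = lut[idx[:, None], idx[None, :]]

    M = np.zeros((n, n), dtype=np.int64)
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = M[i + 1, j]  # i unpaired
            w = W[i, j]
            if w:
                best = max(best, w + (M[i + 1, j - 1] if j - i >= 2 else 0))
            if span >= 2:
                bif = int((M[i, i:j] + M[i + 1 : j + 1, j]).max())
                best = max(best, bif)
            M[i, j] = best

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or M[i, j] == 0:
            continue
        w = W[i, j]
        if M[i, j] == M[i + 1, j]:
            # leaving i unpaired when co-optimal avoids spurious enclosing
            # pairs that pure pairing-maximisation makes free
            stack.append((i + 1, j))
        elif w and j - i > MIN_LOOP and M[i, j] == w + M[i + 1, j - 1]:
            pairs.append((i, j))
            stack.append((i + 1, j - 1))
        else:
            for k in range(i, j):
                if M[i, k] + M[k + 1, j] == M[i, j]:
                    stack.append((i, k))
                    stack.append((k + 1, j))
                    break
    pairs.sort()
    total = sum(W[i, j] for i, j in pairs)
    assert total == M[0, n - 1], "traceback score mismatch"
    return SecondaryStructure(
        sequence=seq,
        pairs=tuple(pairs),
        dot_bracket=_dot_bracket(n, pairs),
        score=-float(total),
    )


def hairpin_loops(structure: SecondaryStructure) -> list[tuple[int, int]]:
    """Terminal (hairpin) loop intervals, inclusive, one per hairpin pair.

    A pair (i, j) closes a hairpin loop when every base strictly inside is
    unpaired; the loop interval is [i+1, j-1].
    """
    partner = structure.partner()
    loops = []
    for i, j in structure.pairs:
        if all(partner[k] is None for k in range(i + 1, j)):
            loops.append((i + 1, j - 1))
    return loops


#: extra width allowed for the dominant-arm partner window beyond the mature
#: length, accommodating asymmetric bulges in the stem
ARM_WINDOW_SLACK = 12


def classify_stem_loop(
    structure: SecondaryStructure,
    mature_offset: int,
    mature_length: int,
    min_paired_fraction: float = 0.60,
    arm_window_slack: int = ARM_WINDOW_SLACK,
) -> HairpinVerdict:
    """Decide whether the mature sits on one arm of a canonical stem-loop.

    The verdict is evaluated on the mature's *dominant arm*: the largest set
    of mature base pairs whose partners fall within one contiguous window of
    at most ``mature_length + arm_window_slack`` nt.  Conditions: no mature
    base pairs inside the mature span itself (a mature folded onto its own
    terminal loop fails here and is reported as crossing the loop); the
    dominant-arm partners lie entirely on one side of the mature; at least
    ``min_paired_fraction`` of mature bases pair into the dominant arm; and
    exactly one hairpin loop lies strictly between the mature and the arm.
    ``mature_crosses_loop`` is reported True when the mature folds back onto
    its own terminal loop (internal pairs) or pairs on both sides of itself.
    Stray pairs of a few mature-end bases into distant sequence, or an
    unpaired mature terminus dangling into the terminal loop, are tolerated,
    as a visual stem-loop screen would.

    The arm is 5p when the mature precedes its partners, 3p when it follows.
    """
    n = len(structure.sequence)
    if not (0 <= mature_offset and mature_offset + mature_length <= n):
        raise ValueError("mature span outside sequence")
    span = range(mature_offset, mature_offset + mature_length)
    in_span = set(span)
    partner = structure.partner()

    paired = [(k, partner[k]) for k in span if partner[k] is not None]
    paired_fraction = len(paired) / mature_length
    internal = [kp for kp in paired if kp[1] in in_span]
    external = [kp for kp in paired if kp[1] not in in_span]

    def fail(crosses: bool, n_loops: int = 0, arm_fraction: float = 0.0, arm: str = "none"):
        return HairpinVerdict(
            is_stem_loop=False,
            arm=arm,
            mature_paired_fraction=paired_fraction,
            arm_paired_fraction=arm_fraction,
            mature_crosses_loop=crosses,
            n_hairpin_loops=n_loops,
        )

    if internal:
        # the mature pairs with itself: it spans the turn of its own hairpin
        return fail(crosses=True)
    if not external:
        return fail(crosses=False)

    # dominant arm: largest pair subset with partners in one contiguous window
    by_partner = sorted(external, key=lambda kp: kp[1])
    window = mature_length + arm_window_slack
    best_lo, best_hi = 0, 0
    lo = 0
    for hi in range(len(by_partner)):
        while by_partner[hi][1] - by_partner[lo][1] >= window:
            lo += 1
        if hi - lo > best_hi - best_lo:
            best_lo, best_hi = lo, hi
    stem = by_partner[best_lo : best_hi + 1]
    arm_fraction = len(stem) / mature_length

    sides = {p >= span.stop for _, p in stem}
    if len(sides) != 1:
        return fail(crosses=True, arm_fraction=arm_fraction)
    arm = "5p" if sides.pop() else "3p"

    # the gap between the innermost stem pair holds the terminal loop
    if arm == "5p":
        gap_lo = max(k for k, _ in stem)
        gap_hi = min(p for _, p in stem)
    else:
        gap_lo = max(p for _, p in stem)
        gap_hi = min(k for k, _ in stem)
    gap_loops = [
        (llo, lhi) for llo, lhi in hairpin_loops(structure) if gap_lo < llo and lhi < gap_hi
    ]
    ok = arm_fraction >= min_paired_fraction and len(gap_loops) == 1
    return HairpinVerdict(
        is_stem_loop=ok,
        arm=arm,
        mature_paired_fraction=paired_fraction,
        arm_paired_fraction=arm_fraction,
        mature_crosses_loop=False,
        n_hairpin_loops=len(gap_loops),
    )


# ---------------------------------------------------------------------------
# Connect (ct) format


def write_ct(structure: SecondaryStructure, name: str = "structure") -> str:
    """Standard 6-column connect format; pairing column 0 for unpaired bases."""
    partner = structure.partner()
    n = len(structure.sequence)
    lines = [f"{n}\tdG = {structure.score:g}\t{name}"]
    for i in range(n):
        p = 0 if partner[i] is None else partner[i] + 1
        lines.append(
            f"{i + 1}\t{structure.sequence[i]}\t{i}\t"
            f"{(i + 2) if i + 1 < n else 0}\t{p}\t{i + 1}"
        )
    return "\n".join(lines) + "\n"


def read_ct(text: str) -> SecondaryStructure:
    """Inverse of :func:`write_ct`; raises ValueError with the offending line."""
    lines = [l for l in text.splitlines() if l.strip()]
    if not lines:
        raise ValueError("empty ct input")
    header = lines[0].split("\t")
    try:
        n = int(header[0])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"ct line 1: malformed header {lines[0]!r}") from exc
    score = 0.0
    for tok in header[1:]:
        if "dG" in tok:
            score = float(tok.split("=")[1])
    if len(lines) - 1 != n:
        raise ValueError(f"ct header declares {n} bases, found {len(lines) - 1} rows")
    bases: list[str] = []
    pairing: list[int] = []
    for lineno, line in enumerate(lines[1:], start=2):
        cols = line.split("\t")
        if len(cols) != 6:
            raise ValueError(f"ct line {lineno}: expected 6 columns, got {len(cols)}")
        try:
            idx, base, pair = int(cols[0]), cols[1], int(cols[4])
        except ValueError as exc:
            raise ValueError(f"ct line {lineno}: malformed fields") from exc
        if idx != lineno - 1:
            raise ValueError(f"ct line {lineno}: index {idx} out of order")
        bases.append(base)
        pairing.append(pair)
    pairs = tuple(
        sorted((i, p - 1) for i, p in enumerate(pairing) if p > 0 and i < p - 1)
    )
    seq = "".join(bases)
    return SecondaryStructure(
        sequence=seq,
        pairs=pairs,
        dot_bracket=_dot_bracket(n, pairs),
        score=score,
    )


def write_verdicts_tsv(path, rows: Sequence[tuple[str, SecondaryStructure, HairpinVerdict]]) -> None:
    with open(path, "w") as fh:
        fh.write(
            "candidate\tscore\tpaired_fraction\tarm_fraction\tarm\tcrosses_loop\t"
            "n_hairpin_loops\tis_stem_loop\n"
        )
        for name, s, v in rows:
            fh.write(
                f"{name}\t{s.score:g}\t{v.mature_paired_fraction:.4f}\t"
                f"{v.arm_paired_fraction:.4f}\t{v.arm}\t"
                f"{int(v.mature_crosses_loop)}\t{v.n_hairpin_loops}\t{int(v.is_stem_loop)}\n"
            )
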
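"""Pairing of opposite-orientation clipped reads and breakpoint arithmetic.

The core idea: a junction-spanning read of length L whose breakpoint offset x
lies in the 3' half is aligned as matched-then-clipped (``MS``); one with x in
the 5' half is aligned clipped-then-matched (``SM``).  An MS read anchors the
5' breakpoint a, an SM read the 3' breakpoint b.  Two such reads cover the
*same* junction exactly when they overlap in the polarized MS-left / SM-right
orientation and the overlap (the "common string") contains both soft-clipped
parts.  The breakpoints then follow directly from the positions and CIGAR
geometry; no realignment is needed.

Coordinate conventions (all 1-based inclusive):

* the variant allele is REF[..a] . REF[b..]; a < b is a deletion (bases
  a+1..b-1 lost), a >= b a tandem duplication (bases b..a doubled);
* when the junction sits in a short repeat (REF[a+1..a+h] == REF[b..b+h-1]),
  the pair (a, b) can slide jointly by up to h bases.  Aligners extend the
  matched run maximally toward the junction, so the raw arithmetic anchors
  the MS side at the *rightmost* equivalent a and the SM side at the
  *leftmost* equivalent b; :func:`refine_breakpoints` rebases and slides the
  pair against the reference, reporting the leftmost equivalent pair and the
  homology length dx.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .cigar import AlignedRead
from .reference import ReferenceBoundsError, ReferenceStore

__all__ = [
    "OverlapMatch",
    "CnvCall",
    "hamming",
    "find_overlap",
    "compute_breakpoints",
    "refine_breakpoints",
    "pair_reads",
]

log = logging.getLogger(__name__)


def hamming(s: str, t: str) -> int:
    """Position-wise mismatch count between equal-length strings."""
    if len(s) != len(t):
        raise ValueError(f"length mismatch: {len(s)} vs {len(t)}")
    return sum(a != b for a, b in zip(s, t))


@dataclass
class OverlapMatch:
    """An accepted MS-SM read pair with their polarized common string.

    ``common_string`` (CS) is assembled segment-wise: the first s2 bases come
    from the SM read's clip, the remainder (repeat + MS clip) from the MS
    read's suffix; disagreements inside the overlap are counted in
    ``mismatches`` but resolved toward the segment owner.
    """

    read_ms: AlignedRead
    read_sm: AlignedRead
    common_len: int
    mismatches: int
    common_string: str


@dataclass
class CnvCall:
    """A breakpoint pair (a, b) with uncertainty and supporting evidence.

    ``a`` is the last reference base of the left segment (5' breakpoint),
    ``b`` the first base of the right segment (3' breakpoint); both are the
    leftmost equivalent positions, and ``dx`` is the number of bases the pair
    can slide jointly without changing the variant sequence.
    """

    rname: str
    a: int
    b: int
    dx: int
    support: set = field(default_factory=set)  # {(ms_name, sm_name), ...}
    ed_merge_refab: int | None = None
    identifier: str | None = None
    match: OverlapMatch | None = None  # representative evidence pair

    @property
    def cnv_type(self) -> str:
        return "DEL" if self.a < self.b else "DUP"

    @property
    def cnv_length(self) -> int:
        """Deleted (b-a-1) or duplicated (a-b+1) bases."""
        return self.b - self.a - 1 if self.a < self.b else self.a - self.b + 1

    @property
    def n_support(self) -> int:
        return len(self.support)

    def key(self) -> tuple:
        return (self.rname, self.cnv_type, self.a, self.b, self.dx)


def find_overlap(
    read_ms: AlignedRead,
    read_sm: AlignedRead,
    min_overlap: int = 28,
    max_mismatch_frac: float = 0.08,
) -> OverlapMatch | None:
    """Best polarized overlap between an MS read's suffix and an SM read's prefix.

    Candidate overlap lengths CL run from max(min_overlap, s1+s2) -- the
    common string must contain both clips -- to min(L1, L2).  A candidate is
    admissible when its position-wise mismatch count is at most
    floor(max_mismatch_frac * CL); among admissible candidates the one with
    the fewest mismatches wins, ties broken toward the largest CL.  Returns
    ``None`` when no candidate qualifies (a normal outcome).
    """
    s1, s2 = read_ms.clip_len, read_sm.clip_len
    seq1, seq2 = read_ms.seq, read_sm.seq
    l1, l2 = len(seq1), len(seq2)
    lo = max(min_overlap, s1 + s2)
    hi = min(l1, l2)
    best: tuple[int, int] | None = None  # (mismatches, CL)
    for cl in range(lo, hi + 1):
        budget = math.floor(max_mismatch_frac * cl)
        tail = seq1[l1 - cl :]
        head = seq2[:cl]
        mm = 0
        for x, y in zip(tail, head):
            if x != y:
                mm += 1
                if mm > budget:
                    break
        if mm > budget:
            continue
        if best is None or mm < best[0] or (mm == best[0] and cl > best[1]):
            best = (mm, cl)
    if best is None:
        return None
    mm, cl = best
    cs = seq2[:s2] + seq1[l1 - cl + s2 :]
    return OverlapMatch(read_ms, read_sm, common_len=cl, mismatches=mm, common_string=cs)


def compute_breakpoints(match: OverlapMatch) -> tuple[int, int, int]:
    """Raw breakpoints (a, b) and repeat width dx from an accepted pair.

    a = POS_ms + ref_span_ms - 1 (last matched reference base of the MS
    read; equals p1 + (L - s1) - 1 for gapless alignments), b = POS_sm, and
    dx = CL - s1 - s2.  The raw a is the rightmost equivalent 5' breakpoint
    and the raw b the leftmost equivalent 3' breakpoint; use
    :func:`refine_breakpoints` to obtain a consistent leftmost pair.
    """
    a = match.read_ms.pos + match.read_ms.ref_span - 1
    b = match.read_sm.pos
    dx = match.common_len - match.read_ms.clip_len - match.read_sm.clip_len
    if dx < 0:
        raise ValueError(
            f"negative repeat width dx={dx}; overlap violates CL >= s1+s2"
        )
    return a, b, dx


def refine_breakpoints(
    a: int,
    b: int,
    dx: int,
    match: OverlapMatch,
    ref: ReferenceStore,
) -> tuple[int, int, int] | None:
    """Slide the breakpoint pair against the reference and report the leftmost.

    The raw pair from :func:`compute_breakpoints` admits the equivalent pairs
    (a - dx + i, b + i) for i in [0, dx].  For each shift i the junction
    sequence is rebuilt from the reference,

        CSREF(i) = REF[a0 - s2 + 1 .. a0 + i] . REF[b + i .. b + CL - s2 - 1],

    with a0 = a - dx, and compared base-by-base against the observed common
    string.  The shifts achieving the minimum mismatch count form the set
    {d}; the call is placed at (a0 + min{d}, b + min{d}) with uncertainty
    dx' = max{d} - min{d}.  With error-free reads every shift reconstructs
    the identical junction, so {d} = {0..dx} and the leftmost pair is
    reported with dx' = dx.

    Returns ``None`` when the reference windows fall outside the contig (the
    call is then discarded by the caller).
    """
    s2 = match.read_sm.clip_len
    cl = match.common_len
    cs = match.common_string
    rname = match.read_ms.rname
    a0 = a - dx
    scores: list[int] = []
    try:
        for i in range(dx + 1):
            csref = ref.fetch(rname, a0 - s2 + 1, a0 + i) + ref.fetch(
                rname, b + i, b + cl - s2 - 1
            )
            scores.append(hamming(cs, csref))
    except ReferenceBoundsError as exc:
        log.debug("discarding candidate at (%d, %d): %s", a, b, exc)
        return None
    best = min(scores)
    dset = [i for i, s in enumerate(scores) if s == best]
    if dset != list(range(dset[0], dset[-1] + 1)):
        log.debug(
            "non-contiguous shift set %s at (%d, %d); reporting min/max", dset, a, b
        )
    return a0 + dset[0], b + dset[0], dset[-1] - dset[0]


def pair_reads(
    ms_batch: list[AlignedRead],
    sm_batch: list[AlignedRead],
    search_window: int = 2_000_000,
    *,
    ref: ReferenceStore,
    min_overlap: int = 28,
    max_mismatch_frac: float = 0.08,
    stats: dict | None = None,
) -> list[CnvCall]:
    """Test every MS read against every SM read within ``search_window``.

    Both batches must be position-sorted and on one contig.  The window is
    symmetric in POS (an SM read may map left of the MS read -- the tandem
    duplication case).  Every qualifying pair yields one draft call via
    find_overlap -> compute_breakpoints -> refine_breakpoints; merging of
    drafts that describe the same CNV happens downstream (dedup_calls).
    """
    drafts: list[CnvCall] = []
    tested = 0
    discarded = 0
    j_lo = 0
    for ms in ms_batch:
        while j_lo < len(sm_batch) and sm_batch[j_lo].pos < ms.pos - search_window:
            j_lo += 1
        for j in range(j_lo, len(sm_batch)):
            sm = sm_batch[j]
            if sm.pos > ms.pos + search_window:
                break
            tested += 1
            match = find_overlap(ms, sm, min_overlap, max_mismatch_frac)
            if match is None:
                continue
            a_raw, b_raw, dx_raw = compute_breakpoints(match)
            refined = refine_breakpoints(a_raw, b_raw, dx_raw, match, ref)
            if refined is None:
                discarded += 1
                continue
            a, b, dx = refined
            drafts.append(
                CnvCall(
                    rname=ms.rname,
                    a=a,
                    b=b,
                    dx=dx,
                    support={(ms.name, sm.name)},
                    match=match,
                )
            )
    if stats is not None:
        stats["pairs_tested"] = stats.get("pairs_tested", 0) + tested
        stats["discarded_bounds"] = stats.get("discarded_bounds", 0) + discarded
    return drafts
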
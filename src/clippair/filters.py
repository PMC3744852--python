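"""False-positive filters, duplicate-call collapsing and depth validation.

A candidate junction is kept only if the merged evidence read (the two
paired reads fused at their common string) looks like a genuine piece of the
variant allele: it must *not* align well to the plain reference at either
read's location, and it *must* align well to the junction reconstruction
obtained by concatenating the reference at the breakpoints.  Calls that
survive are collapsed by a 50-base reference identifier around the
breakpoints and finally required to have more than one supporting read pair.

All string comparisons here are position-wise mismatch counts (Hamming):
every compared pair of strings is equal-length by construction, and for
substitution-only differences Hamming and edit distance coincide.  An edit
(Levenshtein) mode is left as an extension point for reads with internal
indels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .matcher import CnvCall, hamming
from .reference import ReferenceBoundsError, ReferenceStore

__all__ = [
    "FilterStrings",
    "build_filter_strings",
    "apply_reference_filters",
    "make_identifier",
    "dedup_calls",
    "enforce_min_support",
    "compute_read_depth_ratio",
]

log = logging.getLogger(__name__)

IDENT_FLANK = 25  # bases kept on each side of a breakpoint in the identifier


@dataclass
class FilterStrings:
    """The merged read and its three reference comparators.

    merge   -- READ1 . READ2[CL+1..], the fused junction read;
    ref_a   -- reference window of |merge| bases starting at READ1's POS;
    ref_b   -- reference window of |merge| bases ending at READ2's last
               matched base;
    ref_ab  -- junction reconstruction REF[p1..a] . REF[b..], |merge| bases.
    """

    merge: str
    ref_a: str
    ref_b: str
    ref_ab: str


def build_filter_strings(call: CnvCall, ref: ReferenceStore) -> FilterStrings:
    """Construct MERGE and its reference comparators for one draft call.

    Raises :class:`ReferenceBoundsError` when a window leaves the contig;
    such drafts are discarded by the pipeline.
    """
    match = call.match
    if match is None:
        raise ValueError("call carries no evidence pair")
    r1, r2 = match.read_ms, match.read_sm
    cl = match.common_len
    merge = r1.seq + r2.seq[cl:]
    n = len(merge)
    rname = call.rname

    ref_a = ref.fetch(rname, r1.pos, r1.pos + n - 1)
    end2 = r2.pos + r2.ref_span - 1
    ref_b = ref.fetch(rname, end2 - n + 1, end2)

    left = ref.fetch(rname, r1.pos, call.a)
    if len(left) > n:
        raise ReferenceBoundsError(
            f"junction left segment ({len(left)}) exceeds merged read ({n})"
        )
    ref_ab = left + ref.fetch(rname, call.b, call.b + (n - len(left)) - 1)
    return FilterStrings(merge=merge, ref_a=ref_a, ref_b=ref_b, ref_ab=ref_ab)


def apply_reference_filters(
    fs: FilterStrings, threshold_frac: float = 0.08
) -> str | None:
    """Reject a candidate whose merged read contradicts the junction model.

    With tau = threshold_frac * |MERGE|, the call is rejected when

    * dist(MERGE, REFa)  < tau  -- explainable by the plain reference at the
      MS read's location ("merge_matches_ref_a");
    * dist(MERGE, REFb)  < tau  -- likewise at the SM read's location
      ("merge_matches_ref_b");
    * dist(MERGE, REFab) > tau  -- does not match its own junction
      reconstruction ("merge_mismatches_junction").

    Inequalities are strict; equality at the threshold is accepted.  Returns
    ``None`` on acceptance, else the clause token.
    """
    tau = threshold_frac * len(fs.merge)
    if hamming(fs.merge, fs.ref_a) < tau:
        return "merge_matches_ref_a"
    if hamming(fs.merge, fs.ref_b) < tau:
        return "merge_matches_ref_b"
    if hamming(fs.merge, fs.ref_ab) > tau:
        return "merge_mismatches_junction"
    return None


def make_identifier(call: CnvCall, ref: ReferenceStore) -> str:
    """50-base reference fingerprint of a CNV: 25 bases ending at ``a`` plus
    25 bases starting at ``b``.  Windows truncated by contig edges are
    N-padded so near-telomeric calls remain comparable."""
    left = ref.fetch_padded(call.rname, call.a - IDENT_FLANK + 1, call.a)
    right = ref.fetch_padded(call.rname, call.b, call.b + IDENT_FLANK - 1)
    return left + right


def dedup_calls(calls: list[CnvCall]) -> list[CnvCall]:
    """Collapse calls that share a breakpoint identifier.

    Among calls with the same (contig, identifier) the one with the smallest
    dist(MERGE, REFab) is kept (ties toward smaller a, then smaller b) and
    the support sets are merged.  Idempotent.
    """
    groups: dict[tuple, list[CnvCall]] = {}
    for call in calls:
        if call.identifier is None:
            raise ValueError("identifier not computed before dedup")
        groups.setdefault((call.rname, call.identifier), []).append(call)
    kept: list[CnvCall] = []
    for group in groups.values():
        group.sort(
            key=lambda c: (
                c.ed_merge_refab if c.ed_merge_refab is not None else 0,
                c.a,
                c.b,
            )
        )
        winner = group[0]
        for other in group[1:]:
            winner.support |= other.support
        kept.append(winner)
    kept.sort(key=lambda c: (c.rname, c.a, c.b))
    return kept


def enforce_min_support(calls: list[CnvCall], min_pairs: int = 2) -> list[CnvCall]:
    """Keep calls supported by at least ``min_pairs`` distinct read pairs."""
    return [c for c in calls if len(c.support) >= min_pairs]


def compute_read_depth_ratio(
    call: CnvCall,
    alignments,
    flank: int = 1000,
) -> float | None:
    """Mean aligned depth inside the CNV over mean depth in its flanks.

    The inner window is [a, b] for deletions and [b, a] for duplications;
    the outer windows are the ``flank`` bases on each side, clipped at the
    contig edges.  Expected below one for deletions and above one for
    duplications.  Returns ``None`` when the flanks carry no coverage.

    ``alignments`` is a pysam ``AlignmentFile`` or a path to one; depth is
    accumulated from the aligned blocks of primary, non-duplicate records,
    streaming without requiring an index.
    """
    import numpy as np
    import pysam

    own = False
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments))
        own = True
    try:
        contig_len = None
        for sq in alignments.header.get("SQ", []):
            if sq["SN"] == call.rname:
                contig_len = sq["LN"]
        if contig_len is None:
            raise ValueError(f"contig {call.rname!r} absent from alignment header")
        lo, hi = min(call.a, call.b), max(call.a, call.b)
        win_start = max(1, lo - flank)
        win_end = min(contig_len, hi + flank)
        depth = np.zeros(win_end - win_start + 1, dtype=np.int64)
        for rec in alignments.fetch(until_eof=True):
            if (
                rec.is_unmapped
                or rec.is_secondary
                or rec.is_supplementary
                or rec.is_duplicate
                or rec.reference_name != call.rname
            ):
                continue
            for blk_start0, blk_end0 in rec.get_blocks():
                s = max(blk_start0 + 1, win_start)
                e = min(blk_end0, win_end)
                if e >= s:
                    depth[s - win_start : e - win_start + 1] += 1
        inner = depth[lo - win_start : hi - win_start + 1]
        outer = np.concatenate(
            [depth[: lo - win_start], depth[hi - win_start + 1 :]]
        )
        if outer.size == 0 or outer.mean() == 0:
            log.debug("no flank coverage for call at (%d, %d)", call.a, call.b)
            return None
        return float(inner.mean() / outer.mean())
    finally:
        if own:
            alignments.close()
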
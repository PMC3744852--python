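"""Exhaustive brute-force CNV caller used as an independent oracle.

Everything here is written the slow, obvious way on raw Python strings with
0-based slicing and pysam's numeric CIGAR tuples: every (MS, SM) read pair
is tried, every overlap length is scanned in full, and every breakpoint
shift is enumerated by rebuilding the junction from the reference.  It
shares no code with the package.
"""

from __future__ import annotations

import math

import pysam

S, H = 4, 5  # pysam numeric CIGAR codes
REF_CONSUMING = (0, 2, 3, 7, 8)  # M, D, N, =, X


def nmis(x: str, y: str) -> int:
    assert len(x) == len(y)
    return sum(1 for a, b in zip(x, y) if a != b)


def classify(rec, min_clip: int):
    if (
        rec.is_unmapped
        or rec.is_secondary
        or rec.is_supplementary
        or rec.is_duplicate
    ):
        return None
    ct = rec.cigartuples or []
    if not ct or any(op == H for op, _ in ct):
        return None
    lead = ct[0][1] if ct[0][0] == S else 0
    tail = ct[-1][1] if len(ct) > 1 and ct[-1][0] == S else 0
    if lead == tail or max(lead, tail) < min_clip:
        return None
    seq = rec.query_sequence.upper()
    if max(lead, tail) > len(seq) - lead - tail:
        return None
    span = sum(n for op, n in ct if op in REF_CONSUMING)
    common = dict(
        name=rec.query_name,
        rname=rec.reference_name,
        pos=rec.reference_start + 1,
        span=span,
    )
    if tail > lead:
        return dict(cls="MS", seq=seq[lead:], clip=tail, **common)
    return dict(
        cls="SM", seq=seq[: len(seq) - tail] if tail else seq, clip=lead, **common
    )


def best_overlap(seq1, seq2, s1, s2, min_overlap, frac):
    """Exhaustive scan over every admissible overlap length.

    Returns (CL, mismatches) with fewest mismatches, ties to the longest
    overlap, or None.
    """
    best = None
    for cl in range(max(min_overlap, s1 + s2), min(len(seq1), len(seq2)) + 1):
        mm = nmis(seq1[-cl:], seq2[:cl])
        if mm > math.floor(frac * cl):
            continue
        if best is None or (mm, -cl) < (best[1], -best[0]):
            best = (cl, mm)
    return best


def refine(cs, a_raw, b_raw, dx, s2, cl, contig):
    """Enumerate every breakpoint shift; return (a, b, dx') or None."""
    a0 = a_raw - dx
    if a0 - s2 < 0 or b_raw + cl - s2 - 1 > len(contig):
        return None
    scores = []
    for i in range(dx + 1):
        rebuilt = contig[a0 - s2 : a0 + i] + contig[b_raw + i - 1 : b_raw + cl - s2 - 1]
        scores.append(nmis(cs, rebuilt))
    lo = min(scores)
    dset = [i for i, v in enumerate(scores) if v == lo]
    return a0 + dset[0], b_raw + dset[0], dset[-1] - dset[0]


def _padded(contig, start0, end0):
    """contig[start0:end0] N-padded to the requested width at the edges."""
    left = "N" * max(0, -start0)
    right = "N" * max(0, end0 - len(contig))
    return left + contig[max(start0, 0) : min(end0, len(contig))] + right


def oracle_calls(
    sam_path,
    contigs: dict[str, str],
    min_clip: int = 11,
    min_overlap: int = 28,
    frac: float = 0.08,
    window: int = 2_000_000,
    min_support: int = 2,
) -> set[tuple]:
    """Final calls as a set of (rname, type, a, b, dx) tuples."""
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as af:
        reads = [classify(r, min_clip) for r in af.fetch(until_eof=True)]
    reads = [r for r in reads if r is not None]
    drafts = []
    for m in (r for r in reads if r["cls"] == "MS"):
        for s_read in (r for r in reads if r["cls"] == "SM"):
            if m["rname"] != s_read["rname"]:
                continue
            if abs(m["pos"] - s_read["pos"]) > window:
                continue
            ov = best_overlap(
                m["seq"], s_read["seq"], m["clip"], s_read["clip"], min_overlap, frac
            )
            if ov is None:
                continue
            cl, _ = ov
            contig = contigs[m["rname"]]
            s2 = s_read["clip"]
            cs = s_read["seq"][:s2] + m["seq"][len(m["seq"]) - cl + s2 :]
            a_raw = m["pos"] + m["span"] - 1
            b_raw = s_read["pos"]
            dx_raw = cl - m["clip"] - s2
            refined = refine(cs, a_raw, b_raw, dx_raw, s2, cl, contig)
            if refined is None:
                continue
            a, b, dx = refined

            merge = m["seq"] + s_read["seq"][cl:]
            n = len(merge)
            p1 = m["pos"]
            end2 = s_read["pos"] + s_read["span"] - 1
            refa = contig[p1 - 1 : p1 + n - 1]
            refb = contig[end2 - n : end2] if end2 - n >= 0 else ""
            left = contig[p1 - 1 : a]
            refab = left + contig[b - 1 : b - 1 + n - len(left)]
            if len(refa) != n or len(refb) != n or len(refab) != n:
                continue
            tau = frac * n
            if (
                nmis(merge, refa) < tau
                or nmis(merge, refb) < tau
                or nmis(merge, refab) > tau
            ):
                continue
            ident = _padded(contig, a - 25, a) + _padded(contig, b - 1, b + 24)
            drafts.append(
                dict(
                    rname=m["rname"],
                    a=a,
                    b=b,
                    dx=dx,
                    ed=nmis(merge, refab),
                    ident=ident,
                    pair=(m["name"], s_read["name"]),
                )
            )
    groups: dict[tuple, list[dict]] = {}
    for d in drafts:
        groups.setdefault((d["rname"], d["ident"]), []).append(d)
    out = set()
    for group in groups.values():
        group.sort(key=lambda d: (d["ed"], d["a"], d["b"]))
        pairs = {d["pair"] for d in group}
        if len(pairs) >= min_support:
            w = group[0]
            kind = "DEL" if w["a"] < w["b"] else "DUP"
            out.add((w["rname"], kind, w["a"], w["b"], w["dx"]))
    return out
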
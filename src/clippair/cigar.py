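"""CIGAR parsing and soft-clip classification of alignment records.

A read whose alignment carries a long soft clip (``S``) at one end is the
raw evidence for a CNV breakpoint: the matched part anchors one breakpoint
and the clipped part belongs on the other side of the junction.  This module
parses CIGAR strings, classifies reads by the orientation of their dominant
soft clip (``MS`` = clip at the 3' end, ``SM`` = clip at the 5' end) and
exposes the geometric quantities (clip length, matched query length,
reference span) the breakpoint arithmetic needs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "CigarOp",
    "AlignedRead",
    "Rejection",
    "CigarError",
    "parse_cigar",
    "cigar_to_string",
    "query_length",
    "ref_span",
    "classify_read",
]

VALID_OPS = frozenset("MIDNSHP=X")
QUERY_OPS = frozenset("MIS=X")  # operators that consume read bases
REF_OPS = frozenset("MDN=X")  # operators that consume reference bases

_CIGAR_TOKEN = re.compile(r"(\d+)([A-Za-z=])")


class CigarError(ValueError):
    """Malformed CIGAR string."""


@dataclass(frozen=True)
class CigarOp:
    """One CIGAR operation: a positive length and a SAM operator."""

    length: int
    op: str

    def __post_init__(self):
        if self.length < 1:
            raise CigarError(f"non-positive CIGAR length: {self.length}{self.op}")
        if self.op not in VALID_OPS:
            raise CigarError(f"unknown CIGAR operator: {self.length}{self.op}")

    def __str__(self) -> str:
        return f"{self.length}{self.op}"


def parse_cigar(cigar_string: str) -> tuple[CigarOp, ...]:
    """Parse a CIGAR string into an ordered tuple of :class:`CigarOp`.

    Raises :class:`CigarError` naming the offending token on malformed input.
    """
    if not cigar_string or cigar_string == "*":
        raise CigarError(f"empty or undefined CIGAR: {cigar_string!r}")
    ops: list[CigarOp] = []
    pos = 0
    for m in _CIGAR_TOKEN.finditer(cigar_string):
        if m.start() != pos:
            raise CigarError(
                f"malformed CIGAR token at {cigar_string[pos:]!r} in {cigar_string!r}"
            )
        ops.append(CigarOp(int(m.group(1)), m.group(2)))
        pos = m.end()
    if pos != len(cigar_string):
        raise CigarError(
            f"malformed CIGAR token at {cigar_string[pos:]!r} in {cigar_string!r}"
        )
    return tuple(ops)


def cigar_to_string(ops) -> str:
    return "".join(str(op) for op in ops)


def query_length(ops) -> int:
    """Read bases consumed by the CIGAR (M, I, S, =, X)."""
    return sum(op.length for op in ops if op.op in QUERY_OPS)


def ref_span(ops) -> int:
    """Reference bases consumed by the CIGAR (M, D, N, =, X)."""
    return sum(op.length for op in ops if op.op in REF_OPS)


@dataclass
class AlignedRead:
    """One mapped read reduced to the quantities the matcher uses.

    ``seq`` is the read sequence after minor-clip trimming: when a read is
    soft-clipped at both ends, the larger clip determines the orientation and
    the smaller one is removed from the sequence, so that downstream string
    arithmetic can treat the read as exactly (matched part + one clip).

    Attributes
    ----------
    pos
        1-based leftmost mapped reference position (SAM POS), i.e. the first
        reference base of the aligned (non-clipped) part.
    clip_class
        ``"MS"`` if the dominant soft clip is at the 3' end, ``"SM"`` if at
        the 5' end.
    clip_len, match_len
        Query bases in the dominant clip / in the aligned part.
    ref_span
        Reference bases consumed by the aligned part.
    """

    name: str
    rname: str
    pos: int
    cigar: tuple[CigarOp, ...]
    seq: str
    clip_class: str
    clip_len: int
    match_len: int
    ref_span: int

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def clip_seq(self) -> str:
        if self.clip_class == "MS":
            return self.seq[-self.clip_len :]
        return self.seq[: self.clip_len]


@dataclass(frozen=True)
class Rejection:
    """A read that does not qualify as breakpoint evidence, with the reason."""

    name: str
    reason: str


def _end_clips(ops: tuple[CigarOp, ...]) -> tuple[int, int, int, int]:
    """(soft_lead, soft_tail, hard_lead, hard_tail) clip lengths."""
    hard_lead = ops[0].length if ops[0].op == "H" else 0
    hard_tail = ops[-1].length if len(ops) > 1 and ops[-1].op == "H" else 0
    core = [op for op in ops if op.op != "H"]
    if not core:
        return 0, 0, hard_lead, hard_tail
    soft_lead = core[0].length if core[0].op == "S" else 0
    soft_tail = core[-1].length if len(core) > 1 and core[-1].op == "S" else 0
    return soft_lead, soft_tail, hard_lead, hard_tail


def classify_read(record, min_clip: int = 11, min_mapq: int = 0):
    """Classify a mapped record as MS/SM breakpoint evidence or reject it.

    ``record`` is duck-typed on the pysam ``AlignedSegment`` attributes
    (``is_unmapped``, ``cigarstring``, ``query_sequence``,
    ``reference_start``, ...), so any object with those fields works.

    Returns an :class:`AlignedRead` on acceptance, else a :class:`Rejection`
    whose ``reason`` is a short machine-readable token.  Rejected classes:

    * records that are unmapped / secondary / supplementary / duplicates;
    * no soft clip, or the dominant clip shorter than ``min_clip``;
    * equal-length clips at both ends (orientation ambiguous);
    * a dominant clip longer than the matched part -- the aligner chose to
      anchor the short side of a junction read, which cannot be validated
      and is a known source of misplacements;
    * hard-clipped dominant ends (the clipped sequence is absent);
    * missing sequence, or sequence inconsistent with the CIGAR.
    """
    name = getattr(record, "query_name", "?") or "?"
    if record.is_unmapped or record.reference_name is None:
        return Rejection(name, "unmapped")
    if record.is_secondary or record.is_supplementary:
        return Rejection(name, "not_primary")
    if record.is_duplicate:
        return Rejection(name, "duplicate")
    if record.mapping_quality < min_mapq:
        return Rejection(name, "mapq")
    if not record.cigarstring or record.cigarstring == "*":
        return Rejection(name, "no_cigar")
    ops = parse_cigar(record.cigarstring)

    seq = record.query_sequence
    if seq is None or seq == "*":
        return Rejection(name, "no_seq")
    seq = seq.upper()
    if len(seq) != query_length(ops):
        return Rejection(name, "seq_cigar_mismatch")

    soft_lead, soft_tail, hard_lead, hard_tail = _end_clips(ops)
    if max(hard_lead, hard_tail) > 0 and max(hard_lead, hard_tail) >= max(
        soft_lead, soft_tail
    ):
        return Rejection(name, "hard_clip")
    if soft_lead == 0 and soft_tail == 0:
        return Rejection(name, "no_clip")
    if soft_lead == soft_tail:
        return Rejection(name, "ambiguous_clips")

    clip_class = "MS" if soft_tail > soft_lead else "SM"
    clip_len = max(soft_lead, soft_tail)
    if clip_len < min_clip:
        return Rejection(name, "short_clip")

    match_len = len(seq) - soft_lead - soft_tail
    if match_len <= 0:
        return Rejection(name, "no_match")
    if clip_len > match_len:
        return Rejection(name, "clip_gt_match")

    # minor-clip trimming: drop the smaller clip from the sequence
    if clip_class == "MS":
        trimmed = seq[soft_lead:]
    else:
        trimmed = seq[: len(seq) - soft_tail] if soft_tail else seq

    return AlignedRead(
        name=name,
        rname=record.reference_name,
        pos=record.reference_start + 1,
        cigar=ops,
        seq=trimmed,
        clip_class=clip_class,
        clip_len=clip_len,
        match_len=match_len,
        ref_span=ref_span(ops),
    )
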
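"""Synthetic references, implanted CNVs and aligner-faithful junction reads.

The simulator builds a random reference, rewrites it locally so each
requested CNV has an *exact* engineered junction homology (including
homology 0: the implanted (a, b) is always the canonical leftmost pair), and
emits single-end SAM records the way a local aligner would align reads
sampled from the variant allele:

* a read whose breakpoint offset x (measured against the rightmost
  equivalent pair, which is where an aligner's maximal matched run ends)
  lies in the 3' half is emitted matched-then-clipped:
  ``POS = a_r - x + 1, CIGAR = xM(L-x)S``;
* one with x in the 5' half is emitted clipped-then-matched with the
  homology absorbed into the matched part:
  ``POS = b_r - h, CIGAR = (x-h)S(L-x+h)M``;
* reads falling entirely inside reference segments are fully matched
  (``LM``).

An optional fraction of deliberately misanchored records (short side
matched, long side clipped -- the pattern some paired-end aligners emit and
the caller must discard) can be mixed in for filter testing.

Coordinates are 1-based inclusive throughout; the variant allele for both
deletions (a < b) and tandem duplications (a >= b) is REF[1..a] . REF[b..N].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .reference import ReferenceStore, write_fasta

__all__ = [
    "SimCnv",
    "SimulatedDataset",
    "generate_reference",
    "engineer_homology",
    "verify_cnv_invariants",
    "implant_cnv",
    "variant_segments",
    "simulate_junction_reads",
    "simulate_background_reads",
    "simulate_variant_allele_reads",
    "simulate_dataset",
    "make_header",
    "write_sam",
]

BASES = "ACGT"
DEFAULT_RNAME = "sim1"


@dataclass(frozen=True)
class SimCnv:
    """An implanted CNV in leftmost breakpoint convention.

    ``homology_len`` bases of engineered repeat satisfy
    REF[a+1 .. a+h] == REF[b .. b+h-1], and the junction is canonical:
    REF[a] != REF[b-1] and REF[a+h+1] != REF[b+h].
    """

    rname: str
    a: int
    b: int
    cnv_type: str  # "DEL" | "DUP"
    homology_len: int = 0

    def __post_init__(self):
        if self.cnv_type not in ("DEL", "DUP"):
            raise ValueError(f"unknown cnv_type {self.cnv_type!r}")
        if self.cnv_type == "DEL" and not self.a < self.b:
            raise ValueError("DEL requires a < b")
        if self.cnv_type == "DUP" and not self.a >= self.b:
            raise ValueError("DUP requires a >= b")
        if self.homology_len < 0:
            raise ValueError("homology_len must be >= 0")
        h = self.homology_len
        if self.cnv_type == "DEL" and h + 1 >= self.b - self.a:
            raise ValueError("homology must be shorter than the deleted segment")
        if self.cnv_type == "DUP" and h > self.a - self.b:
            raise ValueError("homology must be shorter than the duplicated segment")

    @property
    def length(self) -> int:
        """Deleted (b-a-1) or duplicated (a-b+1) bases."""
        return self.b - self.a - 1 if self.cnv_type == "DEL" else self.a - self.b + 1


def generate_reference(
    length: int,
    seed: int,
    gc: float = 0.5,
    name: str = DEFAULT_RNAME,
) -> ReferenceStore:
    """Reproducible random reference with the requested GC fraction."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    seq = "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])
    return ReferenceStore({name: seq})


def _pick_base(forbidden: set[str]) -> str:
    for base in BASES:
        if base not in forbidden:
            return base
    raise ValueError("no admissible base")  # unreachable with |forbidden| < 4


def engineer_homology(store: ReferenceStore, cnv: SimCnv) -> ReferenceStore:
    """Rewrite ``cnv``'s contig so its junction invariants hold exactly.

    Copies REF[b..b+h-1] onto REF[a+1..a+h], then edits the two boundary
    bases so the homology is exactly h and (a, b) is the leftmost
    equivalent pair.  All edited positions are local to the junction and do
    not touch the homology block itself.
    """
    seq = list(store.sequence(cnv.rname))
    n = len(seq)
    a, b, h = cnv.a, cnv.b, cnv.homology_len
    if a < 1 or b < 2 or a + h + 1 > n or b + h > n:
        raise ValueError("CNV junction too close to the contig edge")

    for k in range(1, h + 1):
        seq[a + k - 1] = seq[b + k - 2]

    # leftmost canonicality: REF[a] != REF[b-1]
    if seq[a - 1] == seq[b - 2]:
        forbidden = {seq[a - 1]}
        if b - 1 == a + h + 1:  # the same base also bounds the homology
            forbidden.add(seq[b + h - 1])
        seq[b - 2] = _pick_base(forbidden)
    # exact homology: REF[a+h+1] != REF[b+h]
    if seq[a + h] == seq[b + h - 1]:
        forbidden = {seq[b + h - 1]}
        if a + h + 1 == b - 1:
            forbidden.add(seq[a - 1])
        seq[a + h] = _pick_base(forbidden)

    contigs = {name: store.sequence(name) for name in store.contigs()}
    contigs[cnv.rname] = "".join(seq)
    out = ReferenceStore(contigs)
    verify_cnv_invariants(out, cnv)
    return out


def verify_cnv_invariants(store: ReferenceStore, cnv: SimCnv) -> None:
    """Assert the engineered homology and leftmost canonicality by direct
    substring comparison; raises ``ValueError`` on violation."""
    a, b, h = cnv.a, cnv.b, cnv.homology_len
    r = store
    if h and r.fetch(cnv.rname, a + 1, a + h) != r.fetch(cnv.rname, b, b + h - 1):
        raise ValueError("engineered homology block mismatch")
    if r.fetch(cnv.rname, a, a) == r.fetch(cnv.rname, b - 1, b - 1):
        raise ValueError("junction not leftmost: REF[a] == REF[b-1]")
    if r.fetch(cnv.rname, a + h + 1, a + h + 1) == r.fetch(cnv.rname, b + h, b + h):
        raise ValueError("homology longer than requested")


def variant_segments(
    contig_len: int, cnvs: list[SimCnv]
) -> list[tuple[int, int]]:
    """Reference segments whose concatenation is the variant allele.

    For junctions (a_1, b_1) .. (a_k, b_k) sorted by a, the variant is
    REF[1..a_1] . REF[b_1..a_2] . ... . REF[b_k..N].  CNVs must not overlap:
    b_i <= a_{i+1} is required.
    """
    cnvs = sorted(cnvs, key=lambda c: c.a)
    for prev, nxt in zip(cnvs, cnvs[1:]):
        if prev.b > nxt.a or max(prev.a, prev.b) + prev.homology_len >= nxt.a:
            raise ValueError("overlapping CNV requests")
    segments = []
    start = 1
    for c in cnvs:
        if c.a < start:
            raise ValueError("overlapping CNV requests")
        segments.append((start, c.a))
        start = c.b
    if start > contig_len:
        raise ValueError("CNV junction beyond contig end")
    segments.append((start, contig_len))
    return segments


def implant_cnv(ref: ReferenceStore, cnv: SimCnv) -> str:
    """The variant contig sequence carrying ``cnv``.

    Deletions drop bases a+1..b-1; tandem duplications repeat bases b..a
    immediately after a.  Assumes the reference was prepared with
    :func:`engineer_homology` when homology is requested.
    """
    verify_cnv_invariants(ref, cnv)
    n = ref.length(cnv.rname)
    return ref.fetch(cnv.rname, 1, cnv.a) + ref.fetch(cnv.rname, cnv.b, n)


def make_header(store: ReferenceStore) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": name, "LN": store.length(name)} for name in store.contigs()
            ],
        }
    )


def make_record(
    header: pysam.AlignmentHeader,
    name: str,
    rname: str,
    pos1: int,
    cigar: str,
    seq: str,
) -> pysam.AlignedSegment:
    rec = pysam.AlignedSegment(header=header)
    rec.query_name = name
    rec.flag = 0
    rec.reference_id = header.references.index(rname)
    rec.reference_start = pos1 - 1
    rec.mapping_quality = 60
    rec.cigarstring = cigar
    rec.query_sequence = seq
    rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    return rec


def _inject_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0.0:
        return seq
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        out[i] = BASES[(BASES.index(out[i]) + rng.integers(1, 4)) % 4]
    return "".join(out)


def simulate_junction_reads(
    ref: ReferenceStore,
    cnv: SimCnv,
    read_length: int = 100,
    n: int = 10,
    error_rate: float = 0.0,
    seed: int = 0,
    x_values: list[int] | None = None,
    misassigned_frac: float = 0.0,
    header: pysam.AlignmentHeader | None = None,
    name_prefix: str | None = None,
) -> list[pysam.AlignedSegment]:
    """Emit ``n`` junction-spanning records for one CNV.

    The breakpoint offset x (bases of the read on the 5' side of the
    junction, measured against the rightmost equivalent pair) is drawn
    uniformly from 1..L-1, re-drawing the ambiguous midpoint x == L/2.
    Explicit ``x_values`` override the draw, fixing the MS/SM composition.
    ``misassigned_frac`` mixes in records anchored on the short side (long
    clip, short match) that downstream classification must discard.
    """
    if n < 1 and not x_values:
        return []
    rng = np.random.default_rng(seed)
    L = read_length
    h = cnv.homology_len
    a_r, b_r = cnv.a + h, cnv.b + h  # rightmost equivalent pair
    contig_len = ref.length(cnv.rname)
    if header is None:
        header = make_header(ref)
    prefix = name_prefix or f"jun_{cnv.rname}_{cnv.a}_{cnv.b}"

    def draw_x() -> int:
        for _ in range(10_000):
            x = int(rng.integers(1, L))
            if 2 * x == L:
                continue
            if a_r - x + 1 < 1 or b_r + L - x - 1 > contig_len:
                continue
            return x
        raise ValueError("cannot place junction read inside the contig")

    xs = list(x_values) if x_values is not None else [draw_x() for _ in range(n)]
    records = []
    for i, x in enumerate(xs):
        if not 1 <= x <= L - 1 or 2 * x == L:
            raise ValueError(f"invalid breakpoint offset x={x}")
        seq = ref.fetch(cnv.rname, a_r - x + 1, a_r) + ref.fetch(
            cnv.rname, b_r, b_r + L - x - 1
        )
        seq = _inject_errors(seq, rng, error_rate)
        misassign = misassigned_frac > 0.0 and rng.random() < misassigned_frac
        if misassign:
            if x > L // 2:
                pos, cigar = b_r, f"{x}S{L - x}M"
            else:
                pos, cigar = a_r - x + 1, f"{x}M{L - x}S"
        elif x > L // 2:
            pos, cigar = a_r - x + 1, f"{x}M{L - x}S"
        elif x - h >= 1:
            pos, cigar = b_r - h, f"{x - h}S{L - x + h}M"
        else:
            # the 5' stub lies entirely inside the homology: fully matched
            pos, cigar = b_r - x, f"{L}M"
        records.append(
            make_record(header, f"{prefix}_{i}", cnv.rname, pos, cigar, seq)
        )
    return records


def simulate_background_reads(
    ref: ReferenceStore,
    depth: float,
    read_length: int = 100,
    error_rate: float = 0.0,
    seed: int = 0,
    header: pysam.AlignmentHeader | None = None,
    name_prefix: str = "bg",
) -> list[pysam.AlignedSegment]:
    """Uniform fully-matched coverage of the reference allele.

    The read count per contig is Poisson with mean depth * length / L, so
    the expected per-base depth matches the request.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    L = read_length
    if header is None:
        header = make_header(ref)
    records = []
    for rname in ref.contigs():
        clen = ref.length(rname)
        if clen < L:
            continue
        n = int(rng.poisson(depth * clen / L))
        starts = rng.integers(1, clen - L + 2, size=n)
        for i, s in enumerate(sorted(map(int, starts))):
            seq = _inject_errors(ref.fetch(rname, s, s + L - 1), rng, error_rate)
            records.append(
                make_record(header, f"{name_prefix}_{rname}_{i}", rname, s, f"{L}M", seq)
            )
    return records


def simulate_variant_allele_reads(
    ref: ReferenceStore,
    cnvs: list[SimCnv],
    depth: float,
    read_length: int = 100,
    error_rate: float = 0.0,
    seed: int = 0,
    header: pysam.AlignmentHeader | None = None,
    name_prefix: str = "va",
) -> list[pysam.AlignedSegment]:
    """Uniform coverage of the variant allele, junction reads included.

    Read starts are uniform on the variant sequence; reads inside a
    reference segment are emitted fully matched at the lifted-over position,
    reads crossing exactly one junction are emitted with the aligner-style
    clipped CIGARs of :func:`simulate_junction_reads`.  Reads spanning two
    junctions (possible only for CNVs closer than a read length) are
    re-drawn.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    L = read_length
    if header is None:
        header = make_header(ref)
    by_contig: dict[str, list[SimCnv]] = {}
    for c in cnvs:
        by_contig.setdefault(c.rname, []).append(c)
    records = []
    for rname in ref.contigs():
        clen = ref.length(rname)
        contig_cnvs = sorted(by_contig.get(rname, []), key=lambda c: c.a)
        segments = variant_segments(clen, contig_cnvs)
        seg_lens = [e - s + 1 for s, e in segments]
        cum = np.cumsum(seg_lens)  # variant coordinate of each segment end
        nv = int(cum[-1])
        if nv < L:
            continue
        n = int(rng.poisson(depth * nv / L))
        emitted = 0
        attempts = 0
        out = []
        while emitted < n and attempts < 20 * n + 100:
            attempts += 1
            s = int(rng.integers(1, nv - L + 2))  # variant coord of first base
            e = s + L - 1
            seg_i = int(np.searchsorted(cum, s))
            if e <= cum[seg_i]:  # fully inside one reference segment
                offset = s - (cum[seg_i] - seg_lens[seg_i])  # 1-based in segment
                pos = segments[seg_i][0] + offset - 1
                seq = _inject_errors(ref.fetch(rname, pos, pos + L - 1), rng, error_rate)
                out.append(
                    make_record(header, f"{name_prefix}_{rname}_{emitted}", rname, pos, f"{L}M", seq)
                )
                emitted += 1
                continue
            if seg_i + 1 >= len(segments) or e > cum[seg_i + 1]:
                continue  # runs off the last segment or spans two junctions
            cnv = contig_cnvs[seg_i]
            h = cnv.homology_len
            x = int(cum[seg_i] - s + 1 + h)  # offset against the rightmost pair
            if 2 * x == L:
                continue
            if x >= L:  # the 3' stub lies inside the homology: fully matched
                start_ref = cnv.a + h - x + 1
                seq = _inject_errors(
                    ref.fetch(rname, start_ref, start_ref + L - 1), rng, error_rate
                )
                out.append(
                    make_record(header, f"{name_prefix}_{rname}_{emitted}", rname, start_ref, f"{L}M", seq)
                )
                emitted += 1
                continue
            recs = simulate_junction_reads(
                ref,
                cnv,
                read_length=L,
                n=1,
                error_rate=error_rate,
                seed=int(rng.integers(0, 2**31 - 1)),
                x_values=[x],
                header=header,
                name_prefix=f"{name_prefix}_{rname}_{emitted}",
            )
            out.extend(recs)
            emitted += 1
        records.extend(out)
    return records


@dataclass
class SimulatedDataset:
    """A simulation with its truth set, ready for round-trip testing."""

    reference: ReferenceStore
    cnvs: list[SimCnv]
    records: list[pysam.AlignedSegment]
    header: pysam.AlignmentHeader
    seed: int = 0
    read_length: int = 100
    paths: dict = field(default_factory=dict)

    def write(self, prefix: str | Path) -> dict:
        """Write <prefix>.fasta (+ .fai), <prefix>.sam and <prefix>.truth.tsv."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        fasta = write_fasta(self.reference, prefix.with_suffix(".fasta"))
        sam = write_sam(self.records, self.header, prefix.with_suffix(".sam"))
        truth = prefix.with_suffix(".truth.tsv")
        with open(truth, "w") as fh:
            fh.write("# coordinates are 1-based inclusive breakpoints (a, b)\n")
            fh.write("rname\ta\tb\ttype\thomology_len\n")
            for c in sorted(self.cnvs, key=lambda c: (c.rname, c.a)):
                fh.write(f"{c.rname}\t{c.a}\t{c.b}\t{c.cnv_type}\t{c.homology_len}\n")
        self.paths = {"fasta": fasta, "sam": sam, "truth": truth}
        return self.paths


def write_sam(
    records: list[pysam.AlignedSegment],
    header: pysam.AlignmentHeader,
    path: str | Path,
) -> Path:
    """Write records coordinate-sorted as a plain-text SAM file."""
    path = Path(path)
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for rec in sorted(records, key=lambda r: (r.reference_id, r.reference_start)):
            out.write(rec)
    return path


def simulate_dataset(
    ref_length: int = 50_000,
    cnvs: list[SimCnv] | None = None,
    coverage: float = 40.0,
    read_length: int = 100,
    error_rate: float = 0.0,
    seed: int = 0,
    zygosity: str = "hom",
    gc: float = 0.5,
    rname: str = DEFAULT_RNAME,
    n_junction_reads: int = 0,
    junction_x_values: list[int] | None = None,
) -> SimulatedDataset:
    """One-stop dataset builder: reference + engineered CNVs + reads.

    ``zygosity`` selects which alleles contribute coverage: ``"hom"`` draws
    all reads from the variant allele, ``"het"`` half from each allele,
    ``"ref"`` reference only (negative control).  ``n_junction_reads`` adds
    explicitly drawn junction-spanning reads per CNV on top of the coverage
    (``junction_x_values`` fixes their breakpoint offsets).
    """
    if zygosity not in ("hom", "het", "ref"):
        raise ValueError(f"unknown zygosity {zygosity!r}")
    cnvs = list(cnvs or [])
    store = generate_reference(ref_length, seed=seed, gc=gc, name=rname)
    for cnv in cnvs:
        store = engineer_homology(store, cnv)
    header = make_header(store)
    records: list[pysam.AlignedSegment] = []
    if coverage > 0:
        if zygosity == "ref":
            records += simulate_background_reads(
                store, coverage, read_length, error_rate, seed + 1, header=header
            )
        elif zygosity == "hom":
            records += simulate_variant_allele_reads(
                store, cnvs, coverage, read_length, error_rate, seed + 1, header=header
            )
        else:
            records += simulate_background_reads(
                store, coverage / 2, read_length, error_rate, seed + 1, header=header
            )
            records += simulate_variant_allele_reads(
                store, cnvs, coverage / 2, read_length, error_rate, seed + 2, header=header
            )
    for k, cnv in enumerate(cnvs):
        if n_junction_reads or junction_x_values:
            records += simulate_junction_reads(
                store,
                cnv,
                read_length=read_length,
                n=n_junction_reads,
                error_rate=error_rate,
                seed=seed + 10 + k,
                x_values=junction_x_values,
                header=header,
                name_prefix=f"jun{k}",
            )
    return SimulatedDataset(
        reference=store,
        cnvs=cnvs,
        records=records,
        header=header,
        seed=seed,
        read_length=read_length,
    )
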
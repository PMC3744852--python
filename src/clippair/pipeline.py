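"""End-to-end CNV calling from alignments + reference to filtered calls.

Stages (per contig, in position order): collect MS/SM clipped reads ->
polarized pairing and breakpoint arithmetic -> reference-based refinement ->
merged-read false-positive filters -> identifier-based duplicate collapsing
-> minimum-support rule.  The per-stage counts are recorded in a
:class:`CallReport` whose totals are self-consistent
(drafts = rejected + deduplicated-away + under-supported + final).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pysam

from .cigar import AlignedRead, Rejection, classify_read
from .filters import (
    apply_reference_filters,
    build_filter_strings,
    dedup_calls,
    enforce_min_support,
    make_identifier,
)
from .matcher import CnvCall, hamming, pair_reads
from .reference import ReferenceBoundsError, ReferenceStore

__all__ = ["CallerConfig", "CallReport", "run_caller", "call_from_records",
           "write_calls_tsv", "write_calls_vcf"]

log = logging.getLogger(__name__)

TSV_COLUMNS = [
    "chrom", "type", "a", "b", "dx", "length",
    "n_support", "ed_merge_refab", "identifier",
]


@dataclass(frozen=True)
class CallerConfig:
    """Tunable thresholds of the caller.

    min_clip
        Shortest soft clip collected as breakpoint evidence (bases); clips
        of 10 and below are treated as alignment noise.
    min_overlap
        Shortest admissible common string between a read pair (bases); the
        common string merges the two reads, so this behaves like an
        aligner's seed length.
    max_mismatch_frac
        Mismatch tolerance inside the common string and in the merged-read
        reference filters, as a fraction of the compared length.
    search_window
        Largest POS distance across which reads are paired (bases); bounds
        the detectable CNV span.  ~20 kb is plenty for exome data.
    min_support
        Least number of distinct supporting read pairs per call.
    flank
        Flank width for the read-depth-ratio validation statistic (bases).
    min_mapq
        Mapping-quality floor for collected reads (0 = no filter).
    regions
        Optional list of (rname, start, end) 1-based inclusive intervals
        restricting read collection.
    """

    min_clip: int = 11
    min_overlap: int = 28
    max_mismatch_frac: float = 0.08
    search_window: int = 2_000_000
    min_support: int = 2
    flank: int = 1000
    min_mapq: int = 0
    regions: tuple | None = None

    def __post_init__(self):
        if min(self.min_clip, self.min_overlap, self.search_window,
               self.min_support, self.flank) <= 0:
            raise ValueError("thresholds must be positive")
        if not 0.0 < self.max_mismatch_frac < 1.0:
            raise ValueError("max_mismatch_frac must be in (0, 1)")
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")


@dataclass
class CallReport:
    """Per-stage counters of one caller run."""

    n_records: int = 0
    n_ms: int = 0
    n_sm: int = 0
    rejected_reads: Counter = field(default_factory=Counter)
    pairs_tested: int = 0
    n_refine_discarded: int = 0
    n_drafts: int = 0
    discarded_bounds: int = 0
    rejected_by_clause: Counter = field(default_factory=Counter)
    n_after_filter: int = 0
    n_dedup_removed: int = 0
    n_under_support: int = 0
    n_final: int = 0

    def consistent(self) -> bool:
        return (
            self.n_drafts
            == sum(self.rejected_by_clause.values())
            + self.discarded_bounds
            + self.n_after_filter
        ) and (
            self.n_after_filter
            == self.n_dedup_removed + self.n_under_support + self.n_final
        )

    def summary(self) -> str:
        return (
            f"records={self.n_records} MS={self.n_ms} SM={self.n_sm} "
            f"pairs_tested={self.pairs_tested} drafts={self.n_drafts} "
            f"rejected={dict(self.rejected_by_clause)} "
            f"deduped={self.n_dedup_removed} "
            f"under_support={self.n_under_support} final={self.n_final}"
        )


def _in_regions(rname: str, pos: int, end: int, regions) -> bool:
    for r_name, r_start, r_end in regions:
        if r_name == rname and pos <= r_end and end >= r_start:
            return True
    return False


def call_from_records(
    records,
    ref: ReferenceStore,
    cfg: CallerConfig | None = None,
) -> tuple[list[CnvCall], CallReport]:
    """Run the full caller over an iterable of alignment records.

    ``records`` must be coordinate-grouped by contig (coordinate-sorted
    input satisfies this); sorted order within a contig is verified.
    """
    cfg = cfg or CallerConfig()
    report = CallReport()
    calls: list[CnvCall] = []

    ms_batch: list[AlignedRead] = []
    sm_batch: list[AlignedRead] = []
    current: str | None = None
    seen_contigs: set[str] = set()
    last_pos = 0

    def flush():
        if current is None:
            return
        stats: dict = {}
        drafts = pair_reads(
            sorted(ms_batch, key=lambda r: r.pos),
            sorted(sm_batch, key=lambda r: r.pos),
            cfg.search_window,
            ref=ref,
            min_overlap=cfg.min_overlap,
            max_mismatch_frac=cfg.max_mismatch_frac,
            stats=stats,
        )
        report.pairs_tested += stats.get("pairs_tested", 0)
        report.n_refine_discarded += stats.get("discarded_bounds", 0)
        report.n_drafts += len(drafts)
        survivors = []
        for draft in drafts:
            try:
                fs = build_filter_strings(draft, ref)
            except ReferenceBoundsError as exc:
                log.debug("draft at (%d, %d) discarded: %s", draft.a, draft.b, exc)
                report.discarded_bounds += 1
                continue
            reason = apply_reference_filters(fs, cfg.max_mismatch_frac)
            if reason is not None:
                report.rejected_by_clause[reason] += 1
                continue
            draft.ed_merge_refab = hamming(fs.merge, fs.ref_ab)
            draft.identifier = make_identifier(draft, ref)
            survivors.append(draft)
        report.n_after_filter += len(survivors)
        deduped = dedup_calls(survivors)
        report.n_dedup_removed += len(survivors) - len(deduped)
        supported = enforce_min_support(deduped, cfg.min_support)
        report.n_under_support += len(deduped) - len(supported)
        calls.extend(supported)

    for rec in records:
        report.n_records += 1
        result = classify_read(rec, cfg.min_clip, cfg.min_mapq)
        if isinstance(result, Rejection):
            report.rejected_reads[result.reason] += 1
            continue
        if cfg.regions is not None and not _in_regions(
            result.rname, result.pos, result.pos + result.ref_span - 1, cfg.regions
        ):
            report.rejected_reads["outside_regions"] += 1
            continue
        if result.rname != current:
            if result.rname in seen_contigs:
                raise ValueError(
                    f"input not coordinate-sorted: contig {result.rname!r} revisited"
                )
            flush()
            if current is not None:
                seen_contigs.add(current)
            current = result.rname
            ms_batch, sm_batch = [], []
            last_pos = 0
            if result.rname not in ref:
                raise ValueError(
                    f"contig {result.rname!r} in alignments but not in the reference"
                )
        if result.pos < last_pos:
            raise ValueError("input not coordinate-sorted: POS decreased")
        last_pos = result.pos
        if result.clip_class == "MS":
            ms_batch.append(result)
            report.n_ms += 1
        else:
            sm_batch.append(result)
            report.n_sm += 1
    flush()

    report.n_final = len(calls)
    calls.sort(key=lambda c: (c.rname, c.a, c.b))
    log.info("%s", report.summary())
    return calls, report


def run_caller(
    bam: str | Path,
    fasta: str | Path,
    cfg: CallerConfig | None = None,
) -> tuple[list[CnvCall], CallReport]:
    """Call CNV breakpoints from a coordinate-sorted SAM/BAM and its FASTA.

    Contig names declared in the alignment header must all be present in the
    reference; a mismatch is fatal, as is unsorted input.
    """
    ref = ReferenceStore.from_fasta(fasta)
    with pysam.AlignmentFile(str(bam), check_sq=False) as af:
        missing = [sq["SN"] for sq in af.header.get("SQ", []) if sq["SN"] not in ref]
        if missing:
            raise ValueError(
                f"contigs {missing} present in {bam} but absent from {fasta}"
            )
        return call_from_records(af.fetch(until_eof=True), ref, cfg)


def write_calls_tsv(calls: list[CnvCall], path: str | Path) -> Path:
    """Tab-separated call table; breakpoints are 1-based inclusive."""
    import pandas as pd

    path = Path(path)
    rows = [
        {
            "chrom": c.rname,
            "type": c.cnv_type,
            "a": c.a,
            "b": c.b,
            "dx": c.dx,
            "length": c.cnv_length,
            "n_support": c.n_support,
            "ed_merge_refab": c.ed_merge_refab,
            "identifier": c.identifier,
        }
        for c in calls
    ]
    frame = pd.DataFrame(rows, columns=TSV_COLUMNS)
    with open(path, "w") as fh:
        fh.write("# breakpoints a, b are 1-based inclusive; "
                 "length = b-a-1 (DEL) or a-b+1 (DUP)\n")
        frame.to_csv(fh, sep="\t", index=False)
    return path


def write_calls_vcf(
    calls: list[CnvCall], ref: ReferenceStore, path: str | Path
) -> Path:
    """Symbolic VCF 4.2 output (<DEL> / <DUP:TANDEM>).

    Mapping from the internal 1-based inclusive pair (a, b): a deletion of
    bases a+1..b-1 is anchored at POS=a with END=b-1 and SVLEN=-(b-a-1); a
    tandem duplication of bases b..a is anchored at POS=b-1 with END=a and
    SVLEN=a-b+1.  HOMLEN carries the breakpoint slide range dx.
    """
    path = Path(path)
    lines = [
        "##fileformat=VCFv4.2",
        '##ALT=<ID=DEL,Description="Deletion">',
        '##ALT=<ID=DUP:TANDEM,Description="Tandem duplication">',
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End of the variant">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Signed SV length">',
        '##INFO=<ID=HOMLEN,Number=1,Type=Integer,Description="Breakpoint homology length">',
        '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting read pairs">',
    ]
    for name in ref.contigs():
        lines.append(f"##contig=<ID={name},length={ref.length(name)}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for i, c in enumerate(sorted(calls, key=lambda c: (c.rname, min(c.a, c.b)))):
        if c.cnv_type == "DEL":
            pos, end, svlen, alt = c.a, c.b - 1, -(c.b - c.a - 1), "<DEL>"
            svtype = "DEL"
        else:
            pos, end, svlen, alt = c.b - 1, c.a, c.a - c.b + 1, "<DUP:TANDEM>"
            svtype = "DUP"
        if pos < 1 or pos > ref.length(c.rname):
            log.warning("skipping call with out-of-bounds VCF anchor at %s:%d",
                        c.rname, pos)
            continue
        refbase = ref.fetch(c.rname, pos, pos)
        info = (
            f"SVTYPE={svtype};END={end};SVLEN={svlen};HOMLEN={c.dx};"
            f"SUPPORT={c.n_support}"
        )
        lines.append(
            f"{c.rname}\t{pos}\tcall{i + 1}\t{refbase}\t{alt}\t.\tPASS\t{info}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path
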
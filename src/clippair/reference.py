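"""Random-access reference sequence store with 1-based inclusive coordinates.

Every coordinate in this package is 1-based and inclusive, matching the SAM
POS convention: ``fetch(rname, i, j)`` returns the bases at positions
``i, i+1, ..., j``.  A dedicated store (rather than raw ``pyfaidx`` objects)
keeps the coordinate convention in one place and lets small in-memory
references be used interchangeably with indexed FASTA files.
"""

from __future__ import annotations

from collections.abc import Mapping
from pathlib import Path


class ReferenceBoundsError(ValueError):
    """Requested window falls outside a contig."""


class ReferenceStore:
    """1-based inclusive substring access to a set of contigs.

    Parameters
    ----------
    contigs
        Mapping of contig name to its full sequence (upper-cased on entry).
    """

    def __init__(self, contigs: Mapping[str, str]):
        self._contigs = {name: str(seq).upper() for name, seq in contigs.items()}

    @classmethod
    def from_dict(cls, contigs: Mapping[str, str]) -> "ReferenceStore":
        return cls(contigs)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceStore":
        """Load (and index, if needed) a FASTA file via pyfaidx."""
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def contigs(self) -> list[str]:
        return list(self._contigs)

    def __contains__(self, rname: str) -> bool:
        return rname in self._contigs

    def length(self, rname: str) -> int:
        try:
            return len(self._contigs[rname])
        except KeyError:
            raise ReferenceBoundsError(f"unknown contig {rname!r}") from None

    def sequence(self, rname: str) -> str:
        """The full contig sequence."""
        if rname not in self._contigs:
            raise ReferenceBoundsError(f"unknown contig {rname!r}")
        return self._contigs[rname]

    def fetch(self, rname: str, start: int, end: int) -> str:
        """Bases at 1-based positions ``start..end`` inclusive.

        ``end < start`` yields the empty string (an empty window is legal,
        e.g. degenerate segments in junction reconstructions).  Windows that
        reach outside the contig raise :class:`ReferenceBoundsError`.
        """
        seq = self.sequence(rname)
        if end < start:
            return ""
        if start < 1 or end > len(seq):
            raise ReferenceBoundsError(
                f"window [{start}, {end}] out of bounds for {rname!r} "
                f"(length {len(seq)})"
            )
        return seq[start - 1 : end]

    def fetch_padded(self, rname: str, start: int, end: int, pad: str = "N") -> str:
        """Like :meth:`fetch` but N-pads the part of the window beyond the contig.

        Used for breakpoint identifiers near contig edges, so near-telomeric
        calls stay comparable instead of being dropped.
        """
        seq = self.sequence(rname)
        if end < start:
            return ""
        n = len(seq)
        left_pad = max(0, 1 - start)
        right_pad = max(0, end - n)
        core = seq[max(start, 1) - 1 : min(end, n)]
        return pad * left_pad + core + pad * right_pad


def write_fasta(store: ReferenceStore, path: str | Path, width: int = 60) -> Path:
    """Write all contigs to ``path`` as FASTA and build a .fai index."""
    import pyfaidx

    path = Path(path)
    with open(path, "w") as fh:
        for name in store.contigs():
            seq = store.sequence(name)
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    pyfaidx.Faidx(str(path))  # side effect: writes <path>.fai
    return path
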
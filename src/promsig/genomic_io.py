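"""Coordinate model, standard-format I/O, and strand-aware promoter windows.

All internal coordinates are 0-based half-open.  The field's "+1 = TSS"
display convention (no position 0; -1 abuts +1) is applied only when
formatting TSS-relative positions for reports, via :func:`to_display_position`.

A promoter window of ``upstream=150, downstream=50`` covers TSS-relative
offsets -150..+49 (0 = the TSS base itself), i.e. display positions
-150..-1 and +1..+50 — 200 bp in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GenomicInterval",
    "PromoterCatalog",
    "PromoterWindow",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_tss_catalog",
    "write_tss_catalog",
    "extract_promoter_windows",
    "window_sequence",
    "to_display_position",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving IUPAC ambiguity codes."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_display_position(offset: int) -> int:
    """Map a 0-based TSS-relative offset to the +1-convention display position.

    Offset 0 (the TSS base) displays as +1; there is no position 0.
    """
    return offset + 1 if offset >= 0 else offset


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    contig: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Integer midpoint (floor)."""
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class PromoterWindow:
    """A promoter's fixed-length window around its TSS.

    ``clipped`` marks windows truncated at a contig boundary.
    """

    promoter_id: str
    interval: GenomicInterval
    clipped: bool = False


@dataclass
class PromoterCatalog:
    """TSS records: (promoter_id, gene_id, contig, tss_position, strand).

    ``tss_position`` is the 0-based genomic coordinate of the TSS base.
    The catalog is the universe for all enrichment tests.
    """

    records: list[tuple[str, str, str, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for pid, _gid, _contig, _tss, strand in self.records:
            if pid in seen:
                raise ValueError(f"duplicate promoter_id {pid!r}")
            seen.add(pid)
            if strand not in {"+", "-"}:
                raise ValueError(f"promoter {pid!r}: strand must be + or -")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def promoter_ids(self) -> list[str]:
        return [r[0] for r in self.records]

    def gene_of(self, promoter_id: str) -> str:
        for pid, gid, *_ in self.records:
            if pid == promoter_id:
                return gid
        raise KeyError(promoter_id)


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into ``{identifier: uppercased sequence}``.

    The identifier is the first whitespace-delimited token of the header.
    Ambiguity codes are preserved (uppercased).
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate sequence identifier {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    if not sequences:
        raise ValueError(f"no FASTA records in {path}")
    return sequences


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3–BED6 into intervals in file order (0-based half-open).

    Strand comes from column 6 when present, else ".".  Malformed
    coordinates raise with the offending line number.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 columns")
            contig = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = fields[3] if len(fields) > 3 else None
            score: float | None = None
            if len(fields) > 4 and fields[4] not in {".", ""}:
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 else "."
            intervals.append(
                GenomicInterval(contig, start, end, strand, name=name, score=score)
            )
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    """Write BED6 (deterministic column order; round-trips read_bed output)."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            score = "0" if iv.score is None else format(iv.score, "g")
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def read_tss_catalog(path) -> PromoterCatalog:
    """Read a tab-delimited TSS catalog with header
    (promoter_id, gene_id, contig, tss, strand)."""
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["promoter_id", "gene_id", "contig", "tss", "strand"]
        if header[:5] != expected:
            raise ValueError(f"unexpected TSS catalog header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            pid, gid, contig, tss, strand = line.split("\t")[:5]
            try:
                tss_i = int(tss)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer TSS") from exc
            records.append((pid, gid, contig, tss_i, strand))
    return PromoterCatalog(records)


def write_tss_catalog(catalog: PromoterCatalog, path) -> None:
    with open(path, "w") as fh:
        fh.write("promoter_id\tgene_id\tcontig\ttss\tstrand\n")
        for pid, gid, contig, tss, strand in catalog:
            fh.write(f"{pid}\t{gid}\t{contig}\t{tss}\t{strand}\n")


def extract_promoter_windows(
    catalog: PromoterCatalog,
    upstream: int = 150,
    downstream: int = 50,
    contig_lengths: Mapping[str, int] | None = None,
) -> dict[str, PromoterWindow]:
    """Extract fixed-length promoter windows around each TSS.

    For a + strand TSS at t the window is [t-upstream, t+downstream);
    for a - strand TSS it is [t-downstream+1, t+upstream+1), so both cover
    TSS-relative offsets -upstream..+downstream-1 in gene orientation.
    Windows overlapping a contig edge are clipped and flagged (known
    contig lengths are required to clip at the right edge).
    """
    if upstream < 0 or downstream < 0 or upstream + downstream <= 0:
        raise ValueError("require upstream, downstream >= 0 and upstream+downstream > 0")
    windows: dict[str, PromoterWindow] = {}
    for pid, _gid, contig, tss, strand in catalog:
        if contig_lengths is not None and contig not in contig_lengths:
            raise KeyError(f"promoter {pid!r}: unknown contig {contig!r}")
        if strand == "+":
            start, end = tss - upstream, tss + downstream
        else:
            start, end = tss - downstream + 1, tss + upstream + 1
        clipped = False
        if start < 0:
            start, clipped = 0, True
        if contig_lengths is not None and end > contig_lengths[contig]:
            end, clipped = contig_lengths[contig], True
        windows[pid] = PromoterWindow(
            pid, GenomicInterval(contig, start, end, strand), clipped=clipped
        )
    return windows


def window_sequence(
    windows: Mapping[str, PromoterWindow], genome: Mapping[str, str]
) -> dict[str, str]:
    """Extract window sequences in gene orientation.

    Minus-strand windows are reverse-complemented so that string index 0 is
    the most upstream (TSS-relative -upstream) base.
    """
    out: dict[str, str] = {}
    for pid, win in windows.items():
        iv = win.interval
        try:
            contig_seq = genome[iv.contig]
        except KeyError as exc:
            raise KeyError(f"window {pid!r}: contig {iv.contig!r} not in genome") from exc
        seq = contig_seq[iv.start : iv.end]
        if iv.strand == "-":
            seq = reverse_complement(seq)
        out[pid] = seq
    return out
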
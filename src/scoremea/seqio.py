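"""Scored sequence I/O.

Reads and writes the scored FASTA convention used by AME-style score-based
enrichment tools (header = ``>name score``, any further header tokens
ignored), and extracts scored sequence windows from BED intervals plus a
genome FASTA using bedtools-getfasta semantics (0-based half-open
coordinates, minus-strand intervals reverse-complemented, BED columns 4-5
supplying name and score).
"""
from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, TextIO

from Bio import SeqIO

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass
class ScoredSequence:
    """A named DNA sequence with one numeric activity score."""

    name: str
    sequence: str
    score: float


@dataclass
class GenomicInterval:
    """A BED-style interval: 0-based half-open, with name, score and strand."""

    chrom: str
    start: int
    end: int
    name: str
    score: float
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"interval {self.name!r}: start {self.start} < 0")
        if self.end <= self.start:
            raise ValueError(
                f"interval {self.name!r}: end {self.end} <= start {self.start}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"interval {self.name!r}: bad strand {self.strand!r}")


def reverse_complement_seq(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _as_handle(source: str | Path | TextIO) -> TextIO:
    if isinstance(source, (str, Path)):
        return open(source)
    return source


def read_scored_fasta(source: str | Path | TextIO) -> list[ScoredSequence]:
    """Read scored FASTA: each header is ``>name score[ ignored...]``.

    Sequence case is preserved on read (scanning uppercases later).
    Duplicate names and unparseable scores are errors naming the record.
    """
    handle = _as_handle(source)
    records: list[ScoredSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(handle, "fasta"):
        tokens = rec.description.split()
        name = tokens[0]
        if len(tokens) < 2:
            raise ValueError(f"record {name!r}: header has no score field")
        try:
            score = float(tokens[1])
        except ValueError as exc:
            raise ValueError(
                f"record {name!r}: unparseable score {tokens[1]!r}"
            ) from exc
        if name in seen:
            raise ValueError(f"duplicate sequence name {name!r}")
        seen.add(name)
        records.append(ScoredSequence(name, str(rec.seq), score))
    return records


def write_scored_fasta(
    records: Iterable[ScoredSequence], destination: str | Path | TextIO | None = None
) -> str:
    """Write scored FASTA (sequences uppercased, scores at full precision).

    Returns the text; also writes it to ``destination`` when given.
    ``read_scored_fasta(write_scored_fasta(x))`` round-trips exactly.
    """
    buf = io.StringIO()
    for rec in records:
        buf.write(f">{rec.name} {rec.score!r}\n{rec.sequence.upper()}\n")
    text = buf.getvalue()
    if destination is not None:
        if isinstance(destination, (str, Path)):
            Path(destination).write_text(text)
        else:
            destination.write(text)
    return text


def resize_to_center_window(iv: GenomicInterval, half_width: int) -> GenomicInterval:
    """Window of +/- ``half_width`` around the interval center.

    Center is ``floor((start + end) / 2)``; the window is clipped at 0 here
    and at the chromosome end during extraction.  Unclipped windows all have
    length ``2 * half_width``.
    """
    if half_width <= 0:
        raise ValueError("half_width must be > 0")
    center = (iv.start + iv.end) // 2
    start = max(0, center - half_width)
    end = center + half_width
    if start != center - half_width:
        logger.warning(
            "interval %r clipped at contig start (center %d, half_width %d)",
            iv.name, center, half_width,
        )
    return GenomicInterval(iv.chrom, start, end, iv.name, iv.score, iv.strand)


def read_bed(source: str | Path | TextIO) -> list[GenomicInterval]:
    """Read BED5/BED6 intervals (chrom, start, end, name, score[, strand])."""
    handle = _as_handle(source)
    intervals: list[GenomicInterval] = []
    for lineno, raw in enumerate(handle, start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 5:
            raise ValueError(f"BED line {lineno}: need >= 5 columns, got {len(fields)}")
        try:
            score = float(fields[4])
        except ValueError as exc:
            raise ValueError(
                f"BED line {lineno} ({fields[3]!r}): non-numeric score {fields[4]!r}"
            ) from exc
        strand = fields[5] if len(fields) >= 6 else "."
        intervals.append(
            GenomicInterval(fields[0], int(fields[1]), int(fields[2]), fields[3], score, strand)
        )
    return intervals


def extract_bed_sequences(
    bed: str | Path | TextIO | list[GenomicInterval],
    genome_fasta: str | Path,
    half_width: int | None = None,
) -> list[ScoredSequence]:
    """Extract scored sequences for BED intervals from a genome FASTA.

    Coordinates are 0-based half-open; minus-strand intervals are
    reverse-complemented; name and score come from BED columns 4-5.  With
    ``half_width`` each interval is first resized to a center window.
    Intervals extending past a contig are clipped (with a logged warning)
    rather than dropped.
    """
    from pyfaidx import Fasta

    intervals = bed if isinstance(bed, list) else read_bed(bed)
    genome = Fasta(str(genome_fasta))
    out: list[ScoredSequence] = []
    for iv in intervals:
        if half_width is not None:
            iv = resize_to_center_window(iv, half_width)
        if iv.chrom not in genome:
            raise KeyError(f"chromosome {iv.chrom!r} missing from {genome_fasta}")
        contig_len = len(genome[iv.chrom])
        end = min(iv.end, contig_len)
        if end != iv.end:
            logger.warning(
                "interval %r clipped at end of %s (%d -> %d)",
                iv.name, iv.chrom, iv.end, end,
            )
        seq = genome[iv.chrom][iv.start : end].seq
        if iv.strand == "-":
            seq = reverse_complement_seq(seq)
        out.append(ScoredSequence(iv.name, seq, iv.score))
    return out
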
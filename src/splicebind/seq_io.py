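"""Sequence and interval I/O.

All coordinates are BED-style 0-based half-open. DNA input is converted to the
RNA alphabet ``{A, C, G, U}`` once at ingest; every downstream module assumes
that alphabet.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from splicebind.errors import (
    AlphabetError,
    CoordinateError,
    FormatError,
    LookupError_,
)

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


@dataclass(frozen=True)
class SequenceRecord:
    """A named RNA sequence over {A, C, G, U}.

    ``truncated`` marks sequences produced by clipping an out-of-bounds region;
    it is never set silently (see :func:`extract_region_sequence`).
    """

    id: str
    residues: str
    truncated: bool = False

    def __post_init__(self):
        if not self.id:
            raise FormatError("sequence record id must be non-empty")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval with strand."""

    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"{self.chrom}:{self.start}-{self.end}: require 0 <= start < end"
            )
        if self.strand not in {"+", "-"}:
            raise CoordinateError(f"strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def normalize_residues(raw: str, record_id: str = "?") -> str:
    """Upper-case, map T to U and reject anything outside the RNA alphabet."""
    seq = raw.upper().replace("T", "U")
    for i, ch in enumerate(seq):
        if ch not in RNA_ALPHABET:
            raise AlphabetError(record_id, i + 1, raw[i])
    return seq


def reverse_complement(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file into normalized :class:`SequenceRecord`s.

    T is mapped to U and case is folded to upper. A residue outside the
    alphabet raises :class:`AlphabetError` naming the record and position.
    """
    path = Path(path)
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # pragma: no cover - biopython internal
        raise FormatError(f"{path}: {exc}") from exc
    if not parsed:
        raise FormatError(f"{path}: no FASTA records found")
    records = []
    for rec in parsed:
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        records.append(SequenceRecord(rec.id, normalize_residues(str(rec.seq), rec.id)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals; a missing strand column defaults to '+'."""
    intervals: list[GenomicInterval] = []
    defaulted = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 else "."
            if len(fields) > 5 and fields[5] in {"+", "-"}:
                strand = fields[5]
            else:
                strand = "+"
                defaulted += 1
            if start >= end:
                raise CoordinateError(f"{path}:{lineno}: start {start} >= end {end}")
            intervals.append(GenomicInterval(chrom, start, end, name, strand))
    if defaulted:
        logger.warning("%s: %d interval(s) without strand, defaulted to '+'", path, defaulted)
    return intervals


def extract_region_sequence(
    genome: Mapping[str, SequenceRecord], region: GenomicInterval
) -> SequenceRecord:
    """Strand-aware slice of a chromosome; '-' returns the reverse complement.

    Regions exceeding chromosome bounds are truncated with ``truncated=True``
    rather than rejected, because fixed-width flanking windows routinely run
    off contig edges.
    """
    if region.chrom not in genome:
        raise LookupError_(f"chromosome {region.chrom!r} not in genome")
    chrom_seq = genome[region.chrom].residues
    start = max(0, region.start)
    end = min(len(chrom_seq), region.end)
    truncated = (start != region.start) or (end != region.end)
    if start >= end:
        raise CoordinateError(
            f"region {region.chrom}:{region.start}-{region.end} entirely outside "
            f"chromosome of length {len(chrom_seq)}"
        )
    seq = chrom_seq[start:end]
    if region.strand == "-":
        seq = reverse_complement(seq)
    return SequenceRecord(region.name if region.name != "." else region.chrom, seq, truncated)


def write_bedgraph_track(
    records: Sequence[tuple[GenomicInterval, float]],
    path: str | Path,
    track_name: str = "splicebind",
) -> None:
    """Write (interval, score) pairs as a bedGraph track with 4-decimal values."""
    for iv, score in records:
        if not math.isfinite(score):
            raise ValueError(f"non-finite score for {iv.chrom}:{iv.start}-{iv.end}")
    _warn_overlaps(records)
    with open(path, "w") as fh:
        fh.write(f"track type=bedGraph name={track_name}\n")
        for iv, score in records:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{score:.4f}\n")


def _warn_overlaps(records: Sequence[tuple[GenomicInterval, float]]) -> None:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv, _ in records:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for chrom, spans in by_chrom.items():
        spans.sort()
        for (s0, e0), (s1, _) in zip(spans, spans[1:]):
            if s1 < e0:
                logger.warning("overlapping bedGraph intervals on %s near %d", chrom, s1)
                break


def read_genome_fasta(path: str | Path) -> dict[str, SequenceRecord]:
    """Load a genome FASTA as a chrom -> record mapping."""
    return {rec.id: rec for rec in read_fasta(path)}
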
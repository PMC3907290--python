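"""Splice-site strength scoring and the per-exon feature vector x1..x4.

Splice-site strength is a min-max-scaled position-weight-matrix score:
100 * (S - S_min) / (S_max - S_min) with S the sum of per-position observed
base frequencies, so the consensus scores 100 and the worst sequence 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from splicebind.errors import CoordinateError, DegenerateInputError, LookupError_
from splicebind.seq_io import (
    GenomicInterval,
    SequenceRecord,
    extract_region_sequence,
)
from splicebind.score_norm import LengthBinStats
from splicebind.triplet_hmm import BASE_INDEX, BASES, HmmParameters, log_odds_score

UPSTREAM_SPAN = 250
DOWNSTREAM_SPAN = 100

#: default scoring windows: 3'ss = last 14 intronic + first exonic base;
#: 5'ss = last 3 exonic + first 6 intronic bases
THREE_PRIME_INTRON = 14
THREE_PRIME_EXON = 1
FIVE_PRIME_EXON = 3
FIVE_PRIME_INTRON = 6

_PSEUDOCOUNT = 1e-3


@dataclass(frozen=True)
class SpliceSiteMatrix:
    """Per-position base frequencies around a splice junction."""

    site_kind: str  # "5ss" or "3ss"
    offsets: tuple[int, ...]  # relative to the junction, informational
    frequencies: np.ndarray  # (n_positions, 4) rows over A,C,G,U

    def __post_init__(self):
        if self.site_kind not in ("5ss", "3ss"):
            raise ValueError("site_kind must be '5ss' or '3ss'")
        freqs = np.asarray(self.frequencies, dtype=float)
        if freqs.ndim != 2 or freqs.shape[1] != 4 or freqs.shape[0] != len(self.offsets):
            raise ValueError("frequencies must be (n_positions, 4)")
        # rows are accepted as counts or frequencies: normalize first, then a
        # pseudocount so every frequency is strictly positive
        sums = freqs.sum(axis=1, keepdims=True)
        if (sums <= 0).any():
            raise ValueError("every matrix position needs positive total weight")
        freqs = freqs / sums
        freqs = (freqs + _PSEUDOCOUNT) / (1.0 + 4 * _PSEUDOCOUNT)
        object.__setattr__(self, "frequencies", freqs)

    @property
    def n_positions(self) -> int:
        return self.frequencies.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("position\tA\tC\tG\tU\n")
            for off, row in zip(self.offsets, self.frequencies):
                fh.write(f"{off}\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, site_kind: str) -> "SpliceSiteMatrix":
        offsets, rows = [], []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("position"):
                raise ValueError(f"{path}: expected 'position\\tA\\tC\\tG\\tU' header")
            for line in fh:
                fields = line.split("\t")
                offsets.append(int(fields[0]))
                rows.append([float(v) for v in fields[1:5]])
        return cls(site_kind=site_kind, offsets=tuple(offsets), frequencies=np.array(rows))

    @classmethod
    def from_junction_sequences(
        cls,
        seqs: Sequence[SequenceRecord | str],
        site_kind: str,
        offsets: tuple[int, ...] | None = None,
    ) -> "SpliceSiteMatrix":
        """Build a matrix from aligned junction sequences (all equal length)."""
        strings = [s.residues if isinstance(s, SequenceRecord) else s for s in seqs]
        if not strings:
            raise DegenerateInputError("no junction sequences")
        L = len(strings[0])
        if any(len(s) != L for s in strings):
            raise ValueError("junction sequences must share one length")
        counts = np.zeros((L, 4))
        for s in strings:
            for i, b in enumerate(s):
                counts[i, BASE_INDEX[b]] += 1
        if offsets is None:
            offsets = tuple(range(L))
        return cls(site_kind=site_kind, offsets=offsets, frequencies=counts / len(strings))


def score_splice_site(seq: SequenceRecord | str, matrix: SpliceSiteMatrix) -> float:
    """Min-max-scaled PWM strength in [0, 100]; consensus 100, worst 0."""
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    if len(residues) != matrix.n_positions:
        raise ValueError(
            f"sequence of {len(residues)} nt does not cover the "
            f"{matrix.n_positions}-position matrix"
        )
    idx = np.fromiter((BASE_INDEX[b] for b in residues), dtype=np.int64)
    s = float(matrix.frequencies[np.arange(len(idx)), idx].sum())
    s_max = float(matrix.frequencies.max(axis=1).sum())
    s_min = float(matrix.frequencies.min(axis=1).sum())
    return 100.0 * (s - s_min) / (s_max - s_min)


@dataclass(frozen=True)
class RegulatoryRegions:
    """The three scored regions flanking an exon, transcribed-strand oriented."""

    upstream_intron: GenomicInterval
    exon: GenomicInterval
    downstream_intron: GenomicInterval
    upstream_truncated: bool = False
    downstream_truncated: bool = False


def define_regulatory_regions(
    exon: GenomicInterval,
    chrom_length: int,
    upstream_span: int = UPSTREAM_SPAN,
    downstream_span: int = DOWNSTREAM_SPAN,
) -> RegulatoryRegions:
    """Upstream-250/exon/downstream-100 regions, strand-aware and clipped.

    On the minus strand the transcribed upstream intron lies at higher genomic
    coordinates. Regions clipped at chromosome edges carry truncation flags.
    """
    if exon.start >= chrom_length or exon.end > chrom_length:
        raise CoordinateError(
            f"exon {exon.chrom}:{exon.start}-{exon.end} outside chromosome "
            f"of length {chrom_length}"
        )
    if exon.strand == "+":
        up_start, up_end = exon.start - upstream_span, exon.start
        down_start, down_end = exon.end, exon.end + downstream_span
    else:
        up_start, up_end = exon.end, exon.end + upstream_span
        down_start, down_end = exon.start - downstream_span, exon.start
    up_trunc = up_start < 0 or up_end > chrom_length
    down_trunc = down_start < 0 or down_end > chrom_length
    up = GenomicInterval(
        exon.chrom,
        max(0, up_start),
        min(chrom_length, up_end),
        f"{exon.name}|upstream",
        exon.strand,
    )
    down = GenomicInterval(
        exon.chrom,
        max(0, down_start),
        min(chrom_length, down_end),
        f"{exon.name}|downstream",
        exon.strand,
    )
    return RegulatoryRegions(
        upstream_intron=up,
        exon=exon,
        downstream_intron=down,
        upstream_truncated=up_trunc,
        downstream_truncated=down_trunc,
    )


@dataclass(frozen=True)
class FeatureStandardizer:
    """Per-feature reference mean/sd (from a reference internal-exon set)."""

    means: np.ndarray  # (4,) for x1..x4
    sds: np.ndarray

    def __post_init__(self):
        if np.any(np.asarray(self.sds) <= 0):
            raise DegenerateInputError("reference sds must be > 0")

    @classmethod
    def from_table(cls, raw_features: np.ndarray) -> "FeatureStandardizer":
        X = np.asarray(raw_features, dtype=float)
        return cls(means=X.mean(axis=0), sds=X.std(axis=0, ddof=1))

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.means) / self.sds


@dataclass(frozen=True)
class ExonFeatureVector:
    """x1 = 3'ss strength; x2..x4 = upstream/exon/downstream binding z-scores."""

    exon_id: str
    x1: float
    x2: float
    x3: float
    x4: float
    standardized: bool = False
    truncation_flags: tuple[bool, bool] = (False, False)

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.x2, self.x3, self.x4])

    def standardize(self, ref: FeatureStandardizer) -> "ExonFeatureVector":
        if self.standardized:
            raise ValueError("feature vector already standardized")
        vals = ref.transform(self.as_array())
        return replace(
            self, x1=vals[0], x2=vals[1], x3=vals[2], x4=vals[3], standardized=True
        )


def three_prime_site_interval(
    exon: GenomicInterval,
    intron_span: int = THREE_PRIME_INTRON,
    exon_span: int = THREE_PRIME_EXON,
) -> GenomicInterval:
    """Genomic interval of the 3' splice-site scoring window, strand-aware."""
    if exon.strand == "+":
        return GenomicInterval(
            exon.chrom, exon.start - intron_span, exon.start + exon_span,
            f"{exon.name}|3ss", "+",
        )
    return GenomicInterval(
        exon.chrom, exon.end - exon_span, exon.end + intron_span,
        f"{exon.name}|3ss", "-",
    )


def five_prime_site_interval(
    exon: GenomicInterval,
    exon_span: int = FIVE_PRIME_EXON,
    intron_span: int = FIVE_PRIME_INTRON,
) -> GenomicInterval:
    if exon.strand == "+":
        return GenomicInterval(
            exon.chrom, exon.end - exon_span, exon.end + intron_span,
            f"{exon.name}|5ss", "+",
        )
    return GenomicInterval(
        exon.chrom, exon.start - intron_span, exon.start + exon_span,
        f"{exon.name}|5ss", "-",
    )


def compute_exon_features(
    exon: GenomicInterval,
    genome: Mapping[str, SequenceRecord],
    hmm: HmmParameters,
    bins: Mapping[str, LengthBinStats],
    ss_matrix: SpliceSiteMatrix,
    ref_stats: FeatureStandardizer | None = None,
) -> ExonFeatureVector:
    """Assemble (x1, x2, x3, x4) for one exon.

    x1 scores the 3' splice site against ``ss_matrix``; x2..x4 are the
    length-bin z-scores of the upstream-250, exon and downstream-100 region
    log-odds under the binding HMM. Truncated flanking regions are scored on
    the truncated sequence with the flag propagated.
    """
    if exon.chrom not in genome:
        raise LookupError_(f"chromosome {exon.chrom!r} not in genome")
    chrom_len = len(genome[exon.chrom])
    regions = define_regulatory_regions(exon, chrom_len)

    ss_seq = extract_region_sequence(genome, three_prime_site_interval(exon))
    x1 = score_splice_site(ss_seq, ss_matrix)

    zs = []
    for region, cls in (
        (regions.upstream_intron, "upstream_intron"),
        (regions.exon, "exon"),
        (regions.downstream_intron, "downstream_intron"),
    ):
        seq = extract_region_sequence(genome, region)
        raw = log_odds_score(hmm, seq)
        zs.append(bins[cls].z_for(len(seq), raw).z)

    vec = ExonFeatureVector(
        exon_id=exon.name,
        x1=x1,
        x2=zs[0],
        x3=zs[1],
        x4=zs[2],
        truncation_flags=(regions.upstream_truncated, regions.downstream_truncated),
    )
    return vec.standardize(ref_stats) if ref_stats is not None else vec
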
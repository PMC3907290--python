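"""Score normalisation: random-sequence nulls, z-scores, empirical p-values,
genome-scale length-bin statistics, background models and affinity correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from splicebind.errors import DegenerateInputError, TooShortError
from splicebind.seq_io import SequenceRecord
from splicebind.triplet_hmm import (
    BASES,
    HmmParameters,
    encode_triplets,
    forward_loglik,
    log_odds_scores_batch,
    tokens_from_base_indices,
)

logger = logging.getLogger(__name__)

#: probe geometry: 4 hexanucleotide RRM elements separated by 3 gaps of 15 nt
N_RRM_ELEMENTS = 4
RRM_ELEMENT_LENGTH = 6
RRM_GAP_LENGTH = 15


def probe_span(
    n_elements: int = N_RRM_ELEMENTS,
    element_length: int = RRM_ELEMENT_LENGTH,
    gap_length: int = RRM_GAP_LENGTH,
) -> int:
    """Total probe length accommodating ``n_elements`` bound elements with
    fixed inter-element gaps. The default geometry spans 69 nt."""
    if n_elements < 1 or element_length < 1 or gap_length < 0:
        raise ValueError("invalid probe geometry")
    return n_elements * element_length + (n_elements - 1) * gap_length


DEFAULT_NULL_LENGTH = probe_span()  # 69 nt
DEFAULT_NULL_SIZE = 100_000


@dataclass(frozen=True)
class NullDistribution:
    """Raw log-odds scores of random sequences of one fixed length."""

    scores: np.ndarray
    length: int
    seed: int
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        if scores.size < 2:
            raise DegenerateInputError("null distribution needs >= 2 scores")
        if float(scores.std(ddof=1)) <= 0:
            raise DegenerateInputError("degenerate null: all scores identical")
        object.__setattr__(self, "scores", scores)

    @property
    def n(self) -> int:
        return int(self.scores.size)

    @property
    def mean(self) -> float:
        return float(self.scores.mean())

    @property
    def sd(self) -> float:
        return float(self.scores.std(ddof=1))

    def summary(self) -> dict:
        return {
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "length": self.length,
            "seed": self.seed,
            "base_freqs": list(self.base_freqs),
        }


@dataclass(frozen=True)
class BindingScore:
    """A raw log-odds score with the z-score its null/bin assigns it."""

    raw: float
    z: float
    source: str


@dataclass(frozen=True)
class ProbeAffinityRecord:
    """Normalised binding score paired with an externally measured Kd (nM)."""

    probe_id: str
    z: float
    kd: float

    def __post_init__(self):
        if self.kd <= 0:
            raise ValueError(f"probe {self.probe_id}: kd must be > 0")


class BackgroundModel:
    """Background sequence model for log-odds denominators.

    kinds:
      - ``uniform``: every triplet has probability 1/64 (the default and the
        most accurate choice in held-out comparisons).
      - ``mono_shuffle`` / ``di_shuffle``: the query's own composition; the
        log-probability is the mean HMM forward log-likelihood over seeded
        shuffles of the query that preserve the mono-/di-nucleotide multiset.
      - ``gene_matched``: triplet frequencies estimated from a user-supplied
        pool of background sequences.
    """

    KINDS = ("uniform", "mono_shuffle", "di_shuffle", "gene_matched")

    def __init__(
        self,
        kind: str = "uniform",
        params: HmmParameters | None = None,
        pool: Sequence[SequenceRecord] | None = None,
        n_shuffles: int = 10,
        seed: int = 0,
    ):
        if kind not in self.KINDS:
            raise ValueError(f"unknown background kind {kind!r}")
        if kind in ("mono_shuffle", "di_shuffle") and params is None:
            raise ValueError(f"{kind} background needs the HMM parameters")
        if kind == "gene_matched":
            if not pool:
                raise ValueError("gene_matched background needs a sequence pool")
            counts = np.full(64, 1e-6)
            for rec in pool:
                tok = encode_triplets(rec).tokens
                np.add.at(counts, tok, 1.0)
            self._log_freqs = np.log(counts / counts.sum())
        self.kind = kind
        self.params = params
        self.n_shuffles = n_shuffles
        self.seed = seed
        self._query: SequenceRecord | None = None

    def bind_query(self, seq: SequenceRecord) -> "BackgroundModel":
        """Attach the query sequence (needed by per-query shuffle backgrounds)."""
        self._query = seq
        return self

    def log_prob(self, tokens: np.ndarray) -> float:
        tokens = np.asarray(tokens)
        if self.kind == "uniform":
            return -tokens.size * np.log(64.0)
        if self.kind == "gene_matched":
            return float(self._log_freqs[tokens].sum())
        if self._query is None:
            raise ValueError("shuffle background: call bind_query(seq) first")
        order = "mono" if self.kind == "mono_shuffle" else "di"
        lls = []
        for k in range(self.n_shuffles):
            shuf = shuffle_sequence(self._query, order=order, seed=self.seed + k)
            lls.append(forward_loglik(self.params, encode_triplets(shuf)))
        return float(np.mean(lls))


# ---------------------------------------------------------------------------
# nulls and z-scores
# ---------------------------------------------------------------------------

def build_null_distribution(
    params: HmmParameters,
    length: int = DEFAULT_NULL_LENGTH,
    n: int = DEFAULT_NULL_SIZE,
    seed: int = 0,
    base_freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> NullDistribution:
    """Score ``n`` i.i.d. random sequences of ``length`` nt under the uniform
    background; reproducible for a fixed seed."""
    if length < 3:
        raise TooShortError("null sequence length must be >= 3")
    if n < 2:
        raise DegenerateInputError("null needs n >= 2 sequences")
    freqs = np.asarray(base_freqs, dtype=float)
    if freqs.shape != (4,) or not np.isclose(freqs.sum(), 1.0, atol=1e-9):
        raise ValueError("base_freqs must be 4 probabilities summing to 1")
    rng = np.random.default_rng(seed)
    base_idx = rng.choice(4, size=(n, length), p=freqs)
    tokens = tokens_from_base_indices(base_idx)
    scores = log_odds_scores_batch(params, tokens)
    return NullDistribution(
        scores=scores, length=length, seed=seed, base_freqs=tuple(freqs)
    )


def z_score(raw: float, null: NullDistribution, source: str = "null") -> BindingScore:
    """Express a raw score in standard deviations of the null (mean maps to 0)."""
    return BindingScore(raw=float(raw), z=(float(raw) - null.mean) / null.sd, source=source)


def empirical_p_value(raw: float, null: NullDistribution, pseudocount: bool = False) -> float:
    """Exceedance probability: the fraction of null scores >= ``raw``.

    The default has no pseudocount (500 of 100,000 at-or-above gives exactly
    0.005); ``pseudocount=True`` switches to (k+1)/(n+1) for multiple-testing
    pipelines that cannot tolerate p = 0.
    """
    k = int(np.count_nonzero(null.scores >= raw))
    if pseudocount:
        return (k + 1) / (null.n + 1)
    return k / null.n


# ---------------------------------------------------------------------------
# genome-scale length binning
# ---------------------------------------------------------------------------

REGION_CLASSES = ("upstream_intron", "exon", "downstream_intron")


@dataclass(frozen=True)
class LengthBinStats:
    """Per-length-bin raw-score mean/sd for one region class.

    ``boundaries[i]`` is the (min_length, max_length) span of bin i; bins were
    built from 1,000 sequences each (a final partial bin of < 500 sequences is
    merged into its predecessor).
    """

    region_class: str
    boundaries: tuple[tuple[int, int], ...]
    means: np.ndarray
    sds: np.ndarray

    def bin_for_length(self, length: int) -> int:
        for i, (lo, hi) in enumerate(self.boundaries):
            if lo <= length <= hi:
                return i
        # outside observed range: clamp to nearest bin
        return 0 if length < self.boundaries[0][0] else len(self.boundaries) - 1

    def z_for(self, length: int, raw: float) -> BindingScore:
        i = self.bin_for_length(length)
        return BindingScore(
            raw=float(raw),
            z=(float(raw) - float(self.means[i])) / float(self.sds[i]),
            source=f"{self.region_class}:bin{i}",
        )


def length_bin_normalize(
    scored_regions: Sequence[tuple[str, int, float]],
    bin_size: int = 1000,
    min_final_bin: int = 500,
) -> tuple[list[BindingScore], dict[str, LengthBinStats]]:
    """Within each region class, sort by length into bins of ``bin_size`` and
    z-score every sequence against its own bin's mean/sd.

    A final partial bin smaller than ``min_final_bin`` is merged into its
    predecessor. Length ties keep input order (stable sort). Returns one
    :class:`BindingScore` per input, in input order, plus per-class stats.
    """
    scores_out: list[BindingScore | None] = [None] * len(scored_regions)
    stats_out: dict[str, LengthBinStats] = {}
    by_class: dict[str, list[int]] = {}
    for idx, (region_class, _length, _raw) in enumerate(scored_regions):
        by_class.setdefault(region_class, []).append(idx)
    for region_class, indices in by_class.items():
        if len(indices) < 2:
            raise DegenerateInputError(
                f"region class {region_class!r} needs >= 2 sequences"
            )
        order = sorted(indices, key=lambda i: scored_regions[i][1])  # stable
        bins: list[list[int]] = [
            order[i : i + bin_size] for i in range(0, len(order), bin_size)
        ]
        if len(bins) > 1 and len(bins[-1]) < min_final_bin:
            tail = bins.pop()
            bins[-1].extend(tail)
        boundaries, means, sds = [], [], []
        for b, members in enumerate(bins):
            raws = np.array([scored_regions[i][2] for i in members], dtype=float)
            lengths = [scored_regions[i][1] for i in members]
            mean, sd = float(raws.mean()), float(raws.std(ddof=1)) if raws.size > 1 else 0.0
            if sd <= 0:
                raise DegenerateInputError(
                    f"{region_class} bin {b} (lengths {min(lengths)}-{max(lengths)}) "
                    "has zero score variance"
                )
            boundaries.append((min(lengths), max(lengths)))
            means.append(mean)
            sds.append(sd)
            for i in members:
                scores_out[i] = BindingScore(
                    raw=float(scored_regions[i][2]),
                    z=(scored_regions[i][2] - mean) / sd,
                    source=f"{region_class}:bin{b}",
                )
        stats_out[region_class] = LengthBinStats(
            region_class=region_class,
            boundaries=tuple(boundaries),
            means=np.array(means),
            sds=np.array(sds),
        )
    assert all(s is not None for s in scores_out)
    return scores_out, stats_out  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# shuffles
# ---------------------------------------------------------------------------

def shuffle_sequence(
    seq: SequenceRecord, order: str = "mono", seed: int = 0
) -> SequenceRecord:
    """Composition-preserving shuffle.

    ``mono`` permutes residues (exact nucleotide multiset preserved); ``di``
    performs an Euler-path shuffle of the dinucleotide graph
    (Altschul–Erickson), preserving the exact dinucleotide multiset. If a
    di-shuffle is impossible (degenerate short input) the input is returned
    unchanged with a warning.
    """
    rng = np.random.default_rng(seed)
    s = seq.residues
    if order == "mono":
        if len(s) < 2:
            raise TooShortError("mono-shuffle needs length >= 2")
        perm = rng.permutation(len(s))
        return SequenceRecord(seq.id, "".join(s[i] for i in perm))
    if order != "di":
        raise ValueError("order must be 'mono' or 'di'")
    if len(s) < 3:
        raise TooShortError("di-shuffle needs length >= 3")
    shuffled = _euler_dishuffle(s, rng)
    if shuffled is None:
        logger.warning("di-shuffle impossible for %r; returning input", seq.id)
        return seq
    return SequenceRecord(seq.id, shuffled)


def _euler_dishuffle(s: str, rng: np.random.Generator, max_tries: int = 100) -> str | None:
    """Altschul–Erickson dinucleotide shuffle via random last-edge trees."""
    first, last = s[0], s[-1]
    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    vertices = sorted(edges.keys() | {last})
    if len(vertices) == 1:
        return s  # homopolymer: the only arrangement
    for _ in range(max_tries):
        # pick a random terminal edge for every non-terminal vertex, then
        # check the terminal edges form a tree into the last vertex
        terminal: dict[str, str] = {}
        for v in vertices:
            if v == last:
                continue
            if not edges.get(v):
                return None
            terminal[v] = edges[v][rng.integers(len(edges[v]))]
        if not _reaches_last(terminal, vertices, last):
            continue
        out_lists: dict[str, list[str]] = {}
        for v in vertices:
            pool = list(edges.get(v, []))
            if v != last:
                pool.remove(terminal[v])
            rng.shuffle(pool)
            if v != last:
                pool.append(terminal[v])
            out_lists[v] = pool
        walk = [first]
        ptr = {v: 0 for v in vertices}
        cur = first
        for _ in range(len(s) - 1):
            nxt = out_lists[cur][ptr[cur]]
            ptr[cur] += 1
            walk.append(nxt)
            cur = nxt
        result = "".join(walk)
        return result
    return None


def _reaches_last(terminal: dict[str, str], vertices: list[str], last: str) -> bool:
    for v in vertices:
        if v == last:
            continue
        seen = {v}
        cur = v
        while cur != last:
            cur = terminal.get(cur)
            if cur is None or cur in seen:
                return False
            seen.add(cur)
    return True


# ---------------------------------------------------------------------------
# affinity correlation
# ---------------------------------------------------------------------------

def correlate_score_affinity(
    records: Sequence[ProbeAffinityRecord], log_kd: bool = False
) -> float:
    """Pearson correlation between binding z-scores and measured Kd values."""
    if len(records) < 3:
        raise DegenerateInputError("need >= 3 probe records")
    z = np.array([r.z for r in records], dtype=float)
    kd = np.array([r.kd for r in records], dtype=float)
    if log_kd:
        kd = np.log(kd)
    if np.ptp(z) == 0 or np.ptp(kd) == 0:
        raise DegenerateInputError("correlation undefined for a constant vector")
    return float(stats.pearsonr(z, kd).statistic)
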
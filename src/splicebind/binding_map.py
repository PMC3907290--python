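"""Binding-site maps: per-base state tracks, sliding-window densities,
group-averaged RNA maps, per-exon heatmap matrices and anchored profiles.

Intron coordinates in maps are measured from the splice sites; exons
contribute boundary-anchored windows from each end rather than being
length-scaled. Only full windows are emitted, and every averaged value
carries its denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage

from splicebind.errors import DegenerateInputError
from splicebind.triplet_hmm import StatePath

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 24
DEFAULT_OVERLAP = 8


@dataclass(frozen=True)
class StateLabelTrack:
    """Per-nucleotide binding marks for one sequence."""

    labels: np.ndarray  # bool, True = binding, length = sequence length

    def __post_init__(self):
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=bool))

    def __len__(self) -> int:
        return int(self.labels.size)


@dataclass(frozen=True)
class DensityProfile:
    """Window-start positions and binding-base fractions at a fixed step."""

    window_starts: np.ndarray
    densities: np.ndarray
    window: int
    step: int

    def __post_init__(self):
        d = np.asarray(self.densities, dtype=float)
        if d.size and (d.min() < 0 or d.max() > 1):
            raise ValueError("densities must lie in [0, 1]")


@dataclass(frozen=True)
class RegionHeatmap:
    """Per-exon score matrix with a hierarchical-clustering row order."""

    exon_ids: tuple[str, ...]
    matrix: np.ndarray  # (n_exons, n_cells), original input order
    row_order: np.ndarray  # permutation of rows after clustering


def per_base_state_labels(path: StatePath, seq_length: int) -> StateLabelTrack:
    """Project triplet-token states onto bases.

    Base i (0 <= i <= L-3) takes the state of the triplet starting at i; the
    final two bases inherit the last token's state.
    """
    if len(path) != seq_length - 2:
        raise ValueError(
            f"path of {len(path)} tokens does not match sequence length {seq_length}"
        )
    binding = path.binding
    labels = np.empty(seq_length, dtype=bool)
    labels[: seq_length - 2] = binding
    labels[seq_length - 2 :] = binding[-1]
    return StateLabelTrack(labels)


def window_density(
    track: StateLabelTrack,
    window: int = DEFAULT_WINDOW,
    overlap: int = DEFAULT_OVERLAP,
) -> DensityProfile:
    """Binding fraction in sliding windows; step = window - overlap.

    Only full windows are emitted; a track shorter than one window yields an
    empty profile with a warning.
    """
    if not 0 <= overlap < window:
        raise ValueError("need 0 <= overlap < window")
    step = window - overlap
    L = len(track)
    if L < window:
        logger.warning("track of %d nt shorter than window %d; empty profile", L, window)
        return DensityProfile(np.array([], dtype=int), np.array([]), window, step)
    starts = np.arange(0, L - window + 1, step)
    csum = np.concatenate([[0], np.cumsum(track.labels)])
    densities = (csum[starts + window] - csum[starts]) / window
    return DensityProfile(starts, densities, window, step)


def group_average_map(
    exon_tracks: Sequence[tuple[StateLabelTrack, StateLabelTrack, StateLabelTrack]],
    span: int = 250,
    window: int = DEFAULT_WINDOW,
    overlap: int = DEFAULT_OVERLAP,
    exon_windows_per_side: int = 2,
) -> dict[str, list[tuple[int, float, int]]]:
    """Average window densities across exons, anchored at the splice sites.

    ``exon_tracks`` holds (upstream intron, exon, downstream intron) per-base
    tracks per exon. Upstream windows are anchored at the 3' splice site
    (rightmost ``span`` nt, positions negative toward the intron), downstream
    windows at the 5' splice site (leftmost ``span`` nt, positions positive),
    and the exon contributes ``exon_windows_per_side`` boundary-anchored
    windows from each end. Windows a shorter sequence cannot fill are excluded
    from that window's denominator. Returns, per segment, a list of
    (position, mean density, n) tuples.
    """
    if not exon_tracks:
        raise DegenerateInputError("empty exon group")
    step = window - overlap

    def accumulate(profiles: list[tuple[np.ndarray, np.ndarray]]):
        sums: dict[int, float] = {}
        counts: dict[int, int] = {}
        for starts, dens in profiles:
            for s, d in zip(starts, dens):
                sums[s] = sums.get(s, 0.0) + float(d)
                counts[s] = counts.get(s, 0) + 1
        return [(s, sums[s] / counts[s], counts[s]) for s in sorted(sums)]

    def right_anchored(labels: np.ndarray, max_span: int | None = None):
        """Windows anchored at the RIGHT edge; position = window start offset
        from that edge (negative)."""
        L = labels.size
        usable = min(L, max_span) if max_span else L
        if usable < window:
            return np.array([], dtype=int), np.array([])
        csum = np.concatenate([[0], np.cumsum(labels)])
        anchors = np.arange(0, usable - window + 1, step)  # distance of window end from edge
        starts = L - window - anchors
        dens = (csum[starts + window] - csum[starts]) / window
        return -(anchors + window), dens

    up_profiles, down_profiles, ex_start_profiles, ex_end_profiles = [], [], [], []
    for up, ex, down in exon_tracks:
        up_profiles.append(right_anchored(up.labels, span))

        down_clip = StateLabelTrack(down.labels[:span]) if len(down) > span else down
        prof = window_density(down_clip, window, overlap)
        down_profiles.append((prof.window_starts + 1, prof.densities))

        prof = window_density(ex, window, overlap)
        k = min(exon_windows_per_side, prof.window_starts.size)
        ex_start_profiles.append((prof.window_starts[:k], prof.densities[:k]))
        # end-anchored: positions negative from the exon 3' end
        tail_pos, tail_dens = right_anchored(ex.labels)
        ex_end_profiles.append((tail_pos[:k], tail_dens[:k]))

    return {
        "upstream_intron": accumulate(up_profiles),
        "exon_start": accumulate(ex_start_profiles),
        "exon_end": accumulate(ex_end_profiles),
        "downstream_intron": accumulate(down_profiles),
    }


def region_heatmap(
    exons: Sequence[tuple[str, Sequence[float]]],
    method: str = "average",
    metric: str = "euclidean",
) -> RegionHeatmap:
    """Cluster exons by their per-region score profiles (rows reordered by
    hierarchical clustering; Euclidean distance, average linkage by default)."""
    if len(exons) < 2:
        raise DegenerateInputError("need >= 2 exons to cluster")
    ids = tuple(e[0] for e in exons)
    matrix = np.array([e[1] for e in exons], dtype=float)
    if not np.isfinite(matrix).all():
        raise ValueError("heatmap matrix contains non-finite cells")
    Z = linkage(matrix, method=method, metric=metric)
    order = np.asarray(leaves_list(Z))
    return RegionHeatmap(exon_ids=ids, matrix=matrix, row_order=order)


def anchor_state_frequency(
    tracks: Sequence[StateLabelTrack],
    anchors: Sequence[Sequence[int]],
    half_width: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binding-state frequency at offsets [-half_width, +half_width] around
    per-track anchor positions.

    Offsets that fall outside a track are excluded from that offset's
    denominator. Returns (offsets, frequencies, denominators).
    """
    if len(tracks) != len(anchors):
        raise ValueError("one anchor list per track required")
    offsets = np.arange(-half_width, half_width + 1)
    hits = np.zeros(offsets.size)
    denom = np.zeros(offsets.size, dtype=int)
    n_anchors = 0
    for track, track_anchors in zip(tracks, anchors):
        L = len(track)
        for a in track_anchors:
            if not 0 <= a < L:
                raise ValueError(f"anchor {a} outside track of length {L}")
            n_anchors += 1
            pos = a + offsets
            valid = (pos >= 0) & (pos < L)
            denom[valid] += 1
            hits[valid] += track.labels[pos[valid]]
    if n_anchors == 0:
        raise DegenerateInputError("no anchors provided")
    freqs = np.divide(hits, denom, out=np.zeros_like(hits), where=denom > 0)
    return offsets, freqs, denom
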
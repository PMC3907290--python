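"""Seeded generators for every pipeline input, with recorded ground truth.

Two cluster generators exist on purpose: overlapping-triplet observations
cannot be produced consistently from independent per-step token emissions, so
token-space clusters (:func:`gen_hmm_observation_clusters`) serve estimation
oracles that match the HMM's generative law exactly, while nucleotide-space
tract sequences (:func:`gen_planted_tract_sequences`) serve end-to-end tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from splicebind.errors import DegenerateInputError
from splicebind.seq_io import SequenceRecord
from splicebind.triplet_hmm import BASES, HmmParameters, TripletObservations

_BASE_ARR = np.array(list(BASES))


@dataclass(frozen=True)
class PlantedHmmSpec:
    """Ground-truth HMM plus the cluster geometry to sample from it."""

    params: HmmParameters
    n_clusters: int
    length: int | tuple[int, int]  # fixed, or inclusive (lo, hi) range
    seed: int = 0


@dataclass(frozen=True)
class PlantedLogitSpec:
    """Ground-truth multinomial-logit coefficients and feature distribution.

    ``beta_repressed``/``beta_enhanced`` are (intercept, *feature coefs).
    In ``generative`` mode features are drawn from a shared Gaussian and labels
    sampled from the planted class probabilities; in ``class_conditional`` mode
    labels are fixed per class and features drawn from per-class means.
    """

    beta_repressed: tuple[float, ...]
    beta_enhanced: tuple[float, ...]
    n_per_class: tuple[int, int, int] = (68, 37, 69)  # repressed, enhanced, non-regulated
    mode: str = "generative"
    n_total: int = 200  # generative mode sample size
    class_means: dict = field(default_factory=dict)
    feature_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("generative", "class_conditional"):
            raise ValueError("mode must be 'generative' or 'class_conditional'")
        if self.mode == "class_conditional" and min(self.n_per_class) < 1:
            raise ValueError("need >= 1 exon per class")
        if len(self.beta_repressed) != len(self.beta_enhanced):
            raise ValueError("beta vectors must have equal length")


def gen_random_sequences(
    n: int,
    length: int,
    base_freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
    prefix: str = "rand",
) -> list[SequenceRecord]:
    """i.i.d. random RNA sequences with the given base composition."""
    freqs = np.asarray(base_freqs, dtype=float)
    if freqs.shape != (4,) or not np.isclose(freqs.sum(), 1.0, atol=1e-9):
        raise ValueError("base_freqs must be 4 probabilities summing to 1")
    rng = np.random.default_rng(seed)
    idx = rng.choice(4, size=(n, length), p=freqs)
    return [
        SequenceRecord(f"{prefix}{i}", "".join(_BASE_ARR[row])) for i, row in enumerate(idx)
    ]


def gen_hmm_observation_clusters(spec: PlantedHmmSpec) -> list[TripletObservations]:
    """Token-space clusters drawn exactly from the planted HMM law.

    Each cluster samples a state path from initial/transition probabilities and
    one triplet token per step from that state's emission row.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.params
    lengths = _cluster_lengths(spec, rng)
    clusters = []
    for L in lengths:
        T = L - 2 if L >= 3 else L  # interpret length as nt when >= 3
        states = np.empty(T, dtype=np.int64)
        states[0] = rng.choice(2, p=p.initial)
        for t in range(1, T):
            states[t] = rng.choice(2, p=p.transition[states[t - 1]])
        tokens = np.array(
            [rng.choice(64, p=p.emission[s]) for s in states], dtype=np.int64
        )
        clusters.append(TripletObservations(tokens))
    return clusters


def _cluster_lengths(spec: PlantedHmmSpec, rng: np.random.Generator) -> np.ndarray:
    if isinstance(spec.length, tuple):
        lo, hi = spec.length
        return rng.integers(lo, hi + 1, size=spec.n_clusters)
    return np.full(spec.n_clusters, spec.length, dtype=np.int64)


def gen_planted_tract_sequences(
    n: int,
    length: int,
    tract_length: int,
    tract_composition: Sequence[float] = (0.0, 0.45, 0.10, 0.45),  # CU-rich, some G
    background_freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
    prefix: str = "tract",
) -> tuple[list[SequenceRecord], list[tuple[int, int]]]:
    """Background sequences each carrying one planted composition tract.

    Returns the sequences and the true (start, end) coordinates of every
    tract (0-based half-open). The default tract composition is
    pyrimidine-rich with interspersed G.
    """
    if tract_length > length:
        raise ValueError("tract_length exceeds sequence length")
    tfreqs = np.asarray(tract_composition, dtype=float)
    bfreqs = np.asarray(background_freqs, dtype=float)
    for f in (tfreqs, bfreqs):
        if f.shape != (4,) or not np.isclose(f.sum(), 1.0, atol=1e-9):
            raise ValueError("compositions must be 4 probabilities summing to 1")
    rng = np.random.default_rng(seed)
    records, coords = [], []
    for i in range(n):
        body = rng.choice(4, size=length, p=bfreqs)
        start = int(rng.integers(0, length - tract_length + 1))
        body[start : start + tract_length] = rng.choice(4, size=tract_length, p=tfreqs)
        records.append(SequenceRecord(f"{prefix}{i}", "".join(_BASE_ARR[body])))
        coords.append((start, start + tract_length))
    return records, coords


def gen_alternating_cu_tract_sequences(
    n: int, length: int, tract_length: int, seed: int = 0, prefix: str = "cu"
) -> tuple[list[SequenceRecord], list[tuple[int, int]]]:
    """Planted tracts that are exactly (CU)* repeats, for anchor-profile tests."""
    rng = np.random.default_rng(seed)
    records, coords = [], []
    for i in range(n):
        body = rng.choice(4, size=length)
        start = int(rng.integers(0, length - tract_length + 1))
        tract = ("CU" * tract_length)[:tract_length]
        s = "".join(_BASE_ARR[body])
        s = s[:start] + tract + s[start + tract_length :]
        records.append(SequenceRecord(f"{prefix}{i}", s))
        coords.append((start, start + tract_length))
    return records, coords


def logit_class_probabilities(
    beta_repressed: np.ndarray, beta_enhanced: np.ndarray, X: np.ndarray
) -> np.ndarray:
    """Planted-model class probabilities, columns (repressed, enhanced, non_regulated)."""
    X1 = np.column_stack([np.ones(len(X)), X])
    g_r = X1 @ np.asarray(beta_repressed)
    g_e = X1 @ np.asarray(beta_enhanced)
    denom = 1.0 + np.exp(g_r) + np.exp(g_e)
    return np.column_stack([np.exp(g_r) / denom, np.exp(g_e) / denom, 1.0 / denom])


CLASS_NAMES = ("repressed", "enhanced", "non_regulated")


def gen_exon_dataset(spec: PlantedLogitSpec) -> tuple[np.ndarray, np.ndarray, dict]:
    """Labelled feature table from the planted logit model.

    Returns (X, labels, truth) where X is (n, k) features, labels is an array
    of class-name strings and truth records the generating parameters and, in
    generative mode, the per-exon planted probabilities.
    """
    rng = np.random.default_rng(spec.seed)
    k = len(spec.beta_repressed) - 1
    truth: dict = {
        "beta_repressed": list(spec.beta_repressed),
        "beta_enhanced": list(spec.beta_enhanced),
        "mode": spec.mode,
        "seed": spec.seed,
    }
    if spec.mode == "generative":
        X = rng.normal(0.0, spec.feature_sd, size=(spec.n_total, k))
        probs = logit_class_probabilities(
            np.asarray(spec.beta_repressed), np.asarray(spec.beta_enhanced), X
        )
        draws = rng.random(spec.n_total)
        cum = np.cumsum(probs, axis=1)
        label_idx = (draws[:, None] > cum).sum(axis=1)
        labels = np.array([CLASS_NAMES[i] for i in label_idx])
        truth["probabilities"] = probs
        return X, labels, truth
    # class-conditional mode
    default_means = {
        "repressed": np.r_[np.full(k, 1.5)],
        "enhanced": np.r_[np.full(k, -1.5)],
        "non_regulated": np.zeros(k),
    }
    rows, labels_list = [], []
    for cls, n_cls in zip(CLASS_NAMES, spec.n_per_class):
        mu = np.asarray(spec.class_means.get(cls, default_means[cls]), dtype=float)
        cov = np.eye(k) * spec.feature_sd**2
        if np.linalg.matrix_rank(cov) < k:
            raise DegenerateInputError("singular feature covariance")
        rows.append(rng.multivariate_normal(mu, cov, size=n_cls))
        labels_list.extend([cls] * n_cls)
    X = np.vstack(rows)
    truth["class_means"] = {c: list(np.atleast_1d(spec.class_means.get(c, default_means[c]))) for c in CLASS_NAMES}
    return X, np.array(labels_list), truth


def gen_psi_table(
    n_per_class: tuple[int, int, int],
    delta_means: tuple[float, float] = (40.0, 40.0),  # repressed +, enhanced -
    noise_sd: float = 2.0,
    control_psi_ranges: dict | None = None,
    seed: int = 0,
) -> tuple[list[tuple[str, float, float]], np.ndarray]:
    """PSI tables with planted per-class delta-PSI plus Gaussian noise.

    Control PSI is drawn per class (repressed exons sit low in control and rise
    on knockdown; enhanced exons the mirror image). Returns rows
    (exon_id, psi_control, psi_knockdown) and the true labels. Values are
    clipped to [0, 100] after noise; clipping is logged.
    """
    import logging

    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    ranges = {
        "repressed": (10.0, 50.0),
        "enhanced": (50.0, 90.0),
        "non_regulated": (10.0, 90.0),
    }
    if control_psi_ranges:
        ranges.update(control_psi_ranges)
    rng = np.random.default_rng(seed)
    mu_r, mu_e = delta_means
    rows, labels = [], []
    n_clipped = 0
    idx = 0
    for cls, n_cls, delta in zip(
        CLASS_NAMES, n_per_class, (mu_r, -mu_e, 0.0)
    ):
        for _ in range(n_cls):
            ctrl = rng.uniform(*ranges[cls])
            kd = ctrl + delta + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            clipped = min(100.0, max(0.0, kd))
            if clipped != kd:
                n_clipped += 1
            rows.append((f"exon{idx}", float(ctrl), float(clipped)))
            labels.append(cls)
            idx += 1
    if n_clipped:
        logging.getLogger(__name__).info("clipped %d PSI value(s) to [0,100]", n_clipped)
    return rows, np.array(labels)
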
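"""Two-state triplet-emission hidden Markov model.

Sequences are tokenised as OVERLAPPING 3-mers (one token per position, L-2
tokens for a length-L sequence), which yields per-nucleotide state paths.
All recursions run in log space with log-sum-exp; Baum–Welch emission updates
carry a small pseudocount so no triplet probability collapses to exactly zero.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from splicebind.errors import NumericalError, TooShortError
from splicebind.seq_io import SequenceRecord

logger = logging.getLogger(__name__)

N_STATES = 2
BASES = "ACGU"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: all 64 triplets in lexicographic order over A < C < G < U (AAA=0 ... UUU=63)
TRIPLETS = ["".join(t) for t in product(BASES, repeat=3)]
TRIPLET_INDEX = {t: i for i, t in enumerate(TRIPLETS)}

#: the 8 pyrimidine-only triplets {C,U}^3, used to label the binding state
PYRIMIDINE_TRIPLETS = tuple(
    TRIPLET_INDEX["".join(t)] for t in product("CU", repeat=3)
)

_EMISSION_PSEUDOCOUNT = 1e-6


@dataclass(frozen=True)
class TripletObservations:
    """Token sequence of overlapping-triplet indices in [0, 63]."""

    tokens: np.ndarray  # int array, shape (T,)

    def __post_init__(self):
        tokens = np.asarray(self.tokens, dtype=np.int64)
        if tokens.ndim != 1 or tokens.size < 1:
            raise TooShortError("observations need at least one token")
        if tokens.min() < 0 or tokens.max() > 63:
            raise ValueError("triplet tokens must lie in [0, 63]")
        object.__setattr__(self, "tokens", tokens)

    def __len__(self) -> int:
        return int(self.tokens.size)


@dataclass(frozen=True)
class StatePath:
    """Per-token decoded states; ``binding`` flags which are the binding state."""

    states: np.ndarray  # int array over {0, 1}, shape (T,)
    binding_state: int

    @property
    def binding(self) -> np.ndarray:
        """Boolean mask, True where the token is in the binding state."""
        return self.states == self.binding_state

    def __len__(self) -> int:
        return int(self.states.size)


@dataclass(frozen=True)
class HmmParameters:
    """Initial, transition and 64-triplet emission probabilities for 2 states."""

    initial: np.ndarray  # (2,)
    transition: np.ndarray  # (2, 2) row-stochastic
    emission: np.ndarray  # (2, 64) row-stochastic
    binding_state: int = 0
    log_base: float = 2.0
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        initial = np.asarray(self.initial, dtype=float)
        transition = np.asarray(self.transition, dtype=float)
        emission = np.asarray(self.emission, dtype=float)
        if initial.shape != (N_STATES,) or transition.shape != (N_STATES, N_STATES):
            raise ValueError("initial must be (2,), transition (2,2)")
        if emission.shape != (N_STATES, 64):
            raise ValueError("emission must be (2, 64)")
        for name, arr, axis in (
            ("initial", initial, 0),
            ("transition", transition, 1),
            ("emission", emission, 1),
        ):
            if (arr < 0).any():
                raise ValueError(f"{name} has negative entries")
            sums = arr.sum(axis=axis)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError(f"{name} rows must sum to 1 (got {sums})")
        if self.binding_state not in (0, 1):
            raise ValueError("binding_state must be 0 or 1")
        object.__setattr__(self, "initial", initial)
        object.__setattr__(self, "transition", transition)
        object.__setattr__(self, "emission", emission)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "alphabet": TRIPLETS,
            "initial": self.initial.tolist(),
            "transition": self.transition.tolist(),
            "emission": self.emission.tolist(),
            "binding_state": self.binding_state,
            "log_base": self.log_base,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HmmParameters":
        if "alphabet" in d and list(d["alphabet"]) != TRIPLETS:
            raise ValueError("model alphabet order does not match AAA..UUU")
        return cls(
            initial=np.array(d["initial"], dtype=float),
            transition=np.array(d["transition"], dtype=float),
            emission=np.array(d["emission"], dtype=float),
            binding_state=int(d.get("binding_state", 0)),
            log_base=float(d.get("log_base", 2.0)),
            metadata=dict(d.get("metadata", {})),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "HmmParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class TrainingConfig:
    n_restarts: int = 10
    seed: int = 0
    tol: float = 1e-6
    max_iter: int = 500

    def __post_init__(self):
        if self.n_restarts < 1 or self.max_iter < 1 or self.tol <= 0:
            raise ValueError("need n_restarts >= 1, max_iter >= 1, tol > 0")


@dataclass(frozen=True)
class TrainingResult:
    params: HmmParameters
    log_likelihood_trace: np.ndarray  # best restart, one value per iteration
    restart_final_logliks: np.ndarray
    best_restart: int
    n_dropped_clusters: int


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

def encode_triplets(seq: SequenceRecord | str) -> TripletObservations:
    """Overlapping 3-mer tokens: residues i..i+2 become token i (L-2 tokens)."""
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    if len(residues) < 3:
        raise TooShortError(f"sequence of length {len(residues)} has no triplets")
    base_idx = np.fromiter((BASE_INDEX[b] for b in residues), dtype=np.int64)
    return TripletObservations(tokens_from_base_indices(base_idx[None, :])[0])


def tokens_from_base_indices(base_idx: np.ndarray) -> np.ndarray:
    """Vectorised overlapping-triplet encoding of a (n, L) base-index matrix."""
    return base_idx[..., :-2] * 16 + base_idx[..., 1:-1] * 4 + base_idx[..., 2:]


def _as_tokens(obs: TripletObservations | np.ndarray) -> np.ndarray:
    return obs.tokens if isinstance(obs, TripletObservations) else np.asarray(obs)


# ---------------------------------------------------------------------------
# likelihoods
# ---------------------------------------------------------------------------

def forward_loglik(params: HmmParameters, obs: TripletObservations) -> float:
    """Natural-log P(obs | params) via the scaled/log-space forward recursion."""
    tokens = _as_tokens(obs)
    if tokens.size == 0:
        raise TooShortError("empty observation sequence")
    return float(forward_loglik_batch(params, tokens[None, :])[0])


def forward_loglik_batch(params: HmmParameters, token_matrix: np.ndarray) -> np.ndarray:
    """Forward log-likelihoods for an (n, T) matrix of equal-length token rows."""
    O = np.asarray(token_matrix, dtype=np.int64)
    if O.ndim != 2 or O.shape[1] < 1:
        raise TooShortError("token matrix must be (n, T) with T >= 1")
    with np.errstate(divide="ignore"):
        log_pi = np.log(params.initial)
        log_A = np.log(params.transition)
        log_E = np.log(params.emission)
    la = log_pi[None, :] + log_E[:, O[:, 0]].T  # (n, 2)
    for t in range(1, O.shape[1]):
        trans = np.logaddexp(
            la[:, 0, None] + log_A[0][None, :],
            la[:, 1, None] + log_A[1][None, :],
        )
        la = trans + log_E[:, O[:, t]].T
    return np.logaddexp(la[:, 0], la[:, 1])


def _forward_backward(params: HmmParameters, O: np.ndarray):
    """Full log alpha/beta for an (n, T) token matrix; returns (la, lb, loglik)."""
    n, T = O.shape
    with np.errstate(divide="ignore"):
        log_pi = np.log(params.initial)
        log_A = np.log(params.transition)
        log_E = np.log(params.emission)
    la = np.empty((n, T, N_STATES))
    la[:, 0, :] = log_pi[None, :] + log_E[:, O[:, 0]].T
    for t in range(1, T):
        prev = la[:, t - 1, :]
        la[:, t, :] = (
            np.logaddexp(
                prev[:, 0, None] + log_A[0][None, :],
                prev[:, 1, None] + log_A[1][None, :],
            )
            + log_E[:, O[:, t]].T
        )
    lb = np.zeros((n, T, N_STATES))
    for t in range(T - 2, -1, -1):
        nxt = lb[:, t + 1, :] + log_E[:, O[:, t + 1]].T  # (n, 2)
        lb[:, t, :] = np.logaddexp(
            nxt[:, 0, None] + log_A[:, 0][None, :],
            nxt[:, 1, None] + log_A[:, 1][None, :],
        )
    loglik = np.logaddexp(la[:, -1, 0], la[:, -1, 1])
    return la, lb, loglik


def posterior_state_probs(params: HmmParameters, obs: TripletObservations) -> np.ndarray:
    """Per-position posterior P(state | obs), shape (T, 2); rows sum to 1."""
    tokens = _as_tokens(obs)
    la, lb, loglik = _forward_backward(params, tokens[None, :])
    return np.exp(la[0] + lb[0] - loglik[0])


# ---------------------------------------------------------------------------
# Baum-Welch
# ---------------------------------------------------------------------------

def _group_by_length(
    token_rows: Sequence[np.ndarray],
) -> list[np.ndarray]:
    groups: dict[int, list[np.ndarray]] = {}
    for row in token_rows:
        groups.setdefault(row.size, []).append(row)
    return [np.stack(rows) for _, rows in sorted(groups.items())]


def _em_step(params: HmmParameters, matrices: list[np.ndarray]):
    """One Baum-Welch iteration over grouped token matrices.

    Returns (updated params, total log-likelihood under the INPUT params).
    """
    pi_counts = np.zeros(N_STATES)
    trans_counts = np.zeros((N_STATES, N_STATES))
    emit_counts = np.zeros((N_STATES, 64))
    total_ll = 0.0
    with np.errstate(divide="ignore"):
        log_A = np.log(params.transition)
        log_E = np.log(params.emission)
    for O in matrices:
        la, lb, loglik = _forward_backward(params, O)
        total_ll += float(loglik.sum())
        gamma = np.exp(la + lb - loglik[:, None, None])  # (n, T, 2)
        pi_counts += gamma[:, 0, :].sum(axis=0)
        for s in range(N_STATES):
            np.add.at(emit_counts[s], O.ravel(), gamma[:, :, s].ravel())
        if O.shape[1] > 1:
            for i in range(N_STATES):
                for j in range(N_STATES):
                    log_xi = (
                        la[:, :-1, i]
                        + log_A[i, j]
                        + log_E[j, O[:, 1:]]
                        + lb[:, 1:, j]
                        - loglik[:, None]
                    )
                    trans_counts[i, j] += float(np.exp(log_xi).sum())
    if not np.isfinite(total_ll):
        raise NumericalError("non-finite log-likelihood during EM")
    new_pi = pi_counts / pi_counts.sum()
    row_sums = trans_counts.sum(axis=1, keepdims=True)
    # a state never left (all mass self-transitions possible at T=1 corpora)
    safe = np.where(row_sums > 0, row_sums, 1.0)
    new_A = np.where(row_sums > 0, trans_counts / safe, params.transition)
    emit_counts += _EMISSION_PSEUDOCOUNT
    new_E = emit_counts / emit_counts.sum(axis=1, keepdims=True)
    updated = replace(params, initial=new_pi, transition=new_A, emission=new_E)
    return updated, total_ll


def _random_params(rng: np.random.Generator) -> HmmParameters:
    return HmmParameters(
        initial=rng.dirichlet(np.ones(N_STATES)),
        transition=np.stack([rng.dirichlet(np.ones(N_STATES)) for _ in range(N_STATES)]),
        emission=np.stack([rng.dirichlet(np.ones(64)) for _ in range(N_STATES)]),
    )


def baum_welch_train(
    clusters: Iterable[SequenceRecord | TripletObservations],
    config: TrainingConfig = TrainingConfig(),
) -> TrainingResult:
    """Best-of-restarts Baum-Welch fit on cluster sequences (or pre-encoded tokens).

    Clusters shorter than 3 nt are dropped with a logged count. Within each
    restart the log-likelihood trace is monotone non-decreasing (EM guarantee,
    up to numerical slack); the restart with the highest final likelihood wins
    and its binding state is labelled via :func:`label_binding_state`.
    """
    token_rows: list[np.ndarray] = []
    n_dropped = 0
    for item in clusters:
        if isinstance(item, TripletObservations):
            token_rows.append(item.tokens)
        else:
            if len(item.residues) < 3:
                n_dropped += 1
                continue
            token_rows.append(encode_triplets(item).tokens)
    if n_dropped:
        logger.info("dropped %d cluster(s) shorter than 3 nt", n_dropped)
    if not token_rows:
        raise TooShortError("no trainable clusters (all shorter than 3 nt)")
    matrices = _group_by_length(token_rows)

    rng = np.random.default_rng(config.seed)
    best: tuple[float, HmmParameters, list[float]] | None = None
    finals = []
    for restart in range(config.n_restarts):
        params = _random_params(rng)
        trace: list[float] = []
        prev_ll = -np.inf
        try:
            for _ in range(config.max_iter):
                params, ll = _em_step(params, matrices)
                trace.append(ll)
                if np.isfinite(prev_ll):
                    rel = abs(ll - prev_ll) / max(abs(prev_ll), 1.0)
                    if rel < config.tol:
                        break
                prev_ll = ll
        except NumericalError as exc:
            raise NumericalError(f"restart {restart}: {exc}") from exc
        final_ll = trace[-1]
        finals.append(final_ll)
        if best is None or final_ll > best[0]:
            best = (final_ll, params, trace)

    assert best is not None
    _, params, trace = best
    params = replace(
        params,
        metadata={
            "n_clusters": len(token_rows),
            "n_dropped": n_dropped,
            "seed": config.seed,
            "n_restarts": config.n_restarts,
            "tol": config.tol,
            "max_iter": config.max_iter,
        },
    )
    params = label_binding_state(params)
    return TrainingResult(
        params=params,
        log_likelihood_trace=np.array(trace),
        restart_final_logliks=np.array(finals),
        best_restart=int(np.argmax(finals)),
        n_dropped_clusters=n_dropped,
    )


def label_binding_state(params: HmmParameters) -> HmmParameters:
    """Label as binding the state with more emission mass on {C,U}^3 triplets.

    Relabelling only changes the ``binding_state`` index, never any probability,
    so all likelihoods and scores are invariant. An exact tie picks state 0.
    """
    pyr = list(PYRIMIDINE_TRIPLETS)
    mass = params.emission[:, pyr].sum(axis=1)
    if mass[0] == mass[1]:
        logger.warning("pyrimidine emission mass tied between states; labelling state 0")
        binding = 0
    else:
        binding = int(np.argmax(mass))
    return replace(params, binding_state=binding)


# ---------------------------------------------------------------------------
# decoding and scoring
# ---------------------------------------------------------------------------

def viterbi_path(params: HmmParameters, obs: TripletObservations) -> StatePath:
    """Maximum-probability state path; ties resolved toward the binding state."""
    tokens = _as_tokens(obs)
    if tokens.size == 0:
        raise TooShortError("empty observation sequence")
    T = tokens.size
    b = params.binding_state
    with np.errstate(divide="ignore"):
        log_pi = np.log(params.initial)
        log_A = np.log(params.transition)
        log_E = np.log(params.emission)
    delta = np.empty((T, N_STATES))
    psi = np.zeros((T, N_STATES), dtype=np.int64)
    delta[0] = log_pi + log_E[:, tokens[0]]
    for t in range(1, T):
        for j in range(N_STATES):
            cand = delta[t - 1] + log_A[:, j]
            # tie toward the binding state, deterministically
            best_i = b if cand[b] >= cand[1 - b] else 1 - b
            psi[t, j] = best_i
            delta[t, j] = cand[best_i] + log_E[j, tokens[t]]
    states = np.empty(T, dtype=np.int64)
    states[-1] = b if delta[-1, b] >= delta[-1, 1 - b] else 1 - b
    for t in range(T - 2, -1, -1):
        states[t] = psi[t + 1, states[t + 1]]
    return StatePath(states=states, binding_state=b)


def log_odds_score(
    params: HmmParameters,
    seq: SequenceRecord | str,
    background=None,
) -> float:
    """Log-odds of the sequence under the HMM vs a background model.

    ``background`` is any object with a ``log_prob(tokens) -> float`` method
    returning a natural-log probability; ``None`` means the default uniform
    background (every triplet 1/64). The result is expressed in
    ``params.log_base`` units (base 2 by default).
    """
    obs = encode_triplets(seq)
    ll = forward_loglik(params, obs)
    if background is None:
        bg = -len(obs) * np.log(64.0)
    else:
        bg = background.log_prob(obs.tokens)
    return (ll - bg) / np.log(params.log_base)


def log_odds_scores_batch(
    params: HmmParameters, token_matrix: np.ndarray
) -> np.ndarray:
    """Uniform-background log-odds for equal-length token rows (model units)."""
    ll = forward_loglik_batch(params, token_matrix)
    bg = -token_matrix.shape[1] * np.log(64.0)
    return (ll - bg) / np.log(params.log_base)
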
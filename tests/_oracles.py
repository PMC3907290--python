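"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's recursion code paths: probabilities are
accumulated by explicit enumeration over all 2^T state paths.
"""

from itertools import product

import numpy as np


def enumerate_forward_loglik(params, tokens) -> float:
    """log P(tokens) by summing the joint probability of every state path."""
    tokens = list(tokens)
    total = 0.0
    for path in product(range(2), repeat=len(tokens)):
        pr = params.initial[path[0]] * params.emission[path[0], tokens[0]]
        for t in range(1, len(tokens)):
            pr *= params.transition[path[t - 1], path[t]]
            pr *= params.emission[path[t], tokens[t]]
        total += pr
    return float(np.log(total))


def enumerate_best_path_logprob(params, tokens) -> float:
    """log of the maximum joint probability over all state paths."""
    tokens = list(tokens)
    best = -np.inf
    for path in product(range(2), repeat=len(tokens)):
        pr = params.initial[path[0]] * params.emission[path[0], tokens[0]]
        for t in range(1, len(tokens)):
            pr *= params.transition[path[t - 1], path[t]]
            pr *= params.emission[path[t], tokens[t]]
        best = max(best, pr)
    return float(np.log(best))


def path_joint_logprob(params, tokens, states) -> float:
    """log joint probability of one specific state path."""
    tokens = list(tokens)
    lp = np.log(params.initial[states[0]]) + np.log(params.emission[states[0], tokens[0]])
    for t in range(1, len(tokens)):
        lp += np.log(params.transition[states[t - 1], states[t]])
        lp += np.log(params.emission[states[t], tokens[t]])
    return float(lp)


def auc_by_pair_counting(scores, positive) -> float:
    """AUC as the concordant-pair fraction (ties count one half)."""
    pos = [s for s, y in zip(scores, positive) if y]
    neg = [s for s, y in zip(scores, positive) if not y]
    total = len(pos) * len(neg)
    conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return conc / total
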
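import numpy as np
import pytest

from splicebind import synthetic_data as synth
from splicebind import triplet_hmm as th


def _uniform_params(binding_state: int = 0) -> th.HmmParameters:
    return th.HmmParameters(
        initial=np.array([0.5, 0.5]),
        transition=np.full((2, 2), 0.5),
        emission=np.full((2, 64), 1 / 64),
        binding_state=binding_state,
    )


def make_cu_params(sticky: float = 0.9) -> th.HmmParameters:
    """Handcrafted two-state model: state 0 strongly favours pyrimidine triplets."""
    emission = np.full((2, 64), 1e-3)
    pyr = list(th.PYRIMIDINE_TRIPLETS)
    emission[0, pyr] = 1.0
    other = [i for i in range(64) if i not in pyr]
    emission[1, other] = 1.0
    emission /= emission.sum(axis=1, keepdims=True)
    return th.label_binding_state(
        th.HmmParameters(
            initial=np.array([0.5, 0.5]),
            transition=np.array([[sticky, 1 - sticky], [1 - sticky, sticky]]),
            emission=emission,
        )
    )


@pytest.fixture
def uniform_params() -> th.HmmParameters:
    return _uniform_params()


@pytest.fixture(scope="session")
def cu_params() -> th.HmmParameters:
    return make_cu_params()


@pytest.fixture
def toy_params() -> th.HmmParameters:
    """Small fully-specified model for oracle comparisons."""
    rng = np.random.default_rng(42)
    return th.HmmParameters(
        initial=np.array([0.6, 0.4]),
        transition=np.array([[0.7, 0.3], [0.2, 0.8]]),
        emission=np.stack([rng.dirichlet(np.ones(64)) for _ in range(2)]),
    )


def make_planted_hmm_params() -> th.HmmParameters:
    """Planted truth for parameter-recovery simulations."""
    emission = np.full((2, 64), 1.0)
    pyr = list(th.PYRIMIDINE_TRIPLETS)
    emission[0, pyr] = 40.0
    a_triplets = [i for i in range(64) if th.TRIPLETS[i].count("A") >= 2]
    emission[1, a_triplets] = 25.0
    emission /= emission.sum(axis=1, keepdims=True)
    return th.HmmParameters(
        initial=np.array([0.5, 0.5]),
        transition=np.array([[0.9, 0.1], [0.2, 0.8]]),
        emission=emission,
    )


@pytest.fixture(scope="session")
def planted_hmm_params() -> th.HmmParameters:
    return make_planted_hmm_params()


@pytest.fixture(scope="session")
def tract_trained() -> th.TrainingResult:
    """HMM trained on nucleotide sequences with planted CU-rich (G-tolerant)
    tracts; shared by the qualitative emission and end-to-end tests."""
    seqs, _ = synth.gen_planted_tract_sequences(
        n=1200, length=40, tract_length=15, seed=11
    )
    return th.baum_welch_train(
        seqs, th.TrainingConfig(n_restarts=3, seed=7, tol=1e-6, max_iter=120)
    )
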
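import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import settings

from langtraits import corpus as cp
from langtraits import synthetic_data as sd

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def utm_from_standardized(x: np.ndarray) -> cp.UserTermMatrix:
    """Wrap a dense matrix as a UserTermMatrix whose ``standardized`` slot
    holds the column z-scores of ``x`` (for tests that feed the factor model
    directly, bypassing the corpus layer)."""
    x = np.asarray(x, dtype=float)
    n, v = x.shape
    means = x.mean(axis=0)
    sds = x.std(axis=0)
    sds = np.where(sds == 0, 1.0, sds)
    std = (x - means) / sds
    pos = np.abs(x) + 1e-9
    rel = sp.csr_matrix(pos / pos.sum(axis=1, keepdims=True))
    vocab = cp.Vocabulary([f"t{j:03d}" for j in range(v)])
    return cp.UserTermMatrix(
        row_users=[f"u{i:04d}" for i in range(n)],
        vocabulary=vocab,
        raw_counts=sp.csr_matrix(np.ones((n, v), dtype=np.int64)),
        rel_freq=rel,
        standardized=std,
        column_means=means,
        column_sds=sds,
    )


@pytest.fixture(scope="session")
def small_config() -> sd.SyntheticConfig:
    return sd.SyntheticConfig(n_users=300, vocab_size=200, n_factors=3, seed=5)


@pytest.fixture(scope="session")
def small_study(small_config):
    """One small synthetic study shared across tests: population, corpus,
    outcomes, likes, plus the fitted user-term matrix."""
    pop, corpus, outcomes, likes = sd.generate_all(small_config)
    filtered = cp.filter_users(corpus)
    vocab = cp.build_vocabulary(filtered, top_k=small_config.vocab_size)
    utm = cp.build_user_term_matrix(filtered, vocab)
    return {
        "config": small_config,
        "pop": pop,
        "corpus": corpus,
        "outcomes": outcomes,
        "likes": likes,
        "vocab": vocab,
        "utm": utm,
    }
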
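import numpy as np
import pytest
from hypothesis import settings

from scentnlp.synthetic_corpus import CorpusConfig, generate_corpus

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_corpus():
    """600-document synthetic corpus shared across tests (seed-fixed)."""
    return generate_corpus(
        CorpusConfig(n_documents=600, class_proportions=(0.6, 0.3, 0.1), seed=11)
    )


@pytest.fixture(scope="session")
def corpus_texts(small_corpus):
    return [d.full_text() for d in small_corpus]


def finite_difference(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite-difference gradient of a scalar function of an array."""
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g


def relative_error(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.max(np.abs(a - b) / (np.abs(a) + np.abs(b) + 1e-8)))
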
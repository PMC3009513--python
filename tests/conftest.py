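import numpy as np
import pytest

from hmmball import HMM, random_hmm, toy_topology_hmm


@pytest.fixture
def two_state_hmm():
    """Hand-specified two-state, two-symbol model with printed parameters."""
    return HMM(
        transitions=np.array([[0.7, 0.3], [0.4, 0.6]]),
        emissions=np.array([[0.9, 0.1], [0.2, 0.8]]),
        alphabet=("a", "b"),
        start_state=0,
        labels=("A", "B"),
    )


@pytest.fixture
def one_state_emitter():
    """Deterministic single-state model emitting 'a' with probability 1."""
    return HMM(
        transitions=np.array([[1.0]]),
        emissions=np.array([[1.0, 0.0]]),
        alphabet=("a", "b"),
        start_state=0,
        labels=("A",),
    )


@pytest.fixture
def make_random_instance():
    """Factory for seeded (hmm, sequence) enumeration-scale instances."""

    def _make(seed, m=3, n=6, alphabet_size=2, num_labels=2):
        hmm = random_hmm(m, alphabet_size, num_labels, seed=seed)
        rng = np.random.default_rng(seed + 10_000)
        y = "".join(rng.choice(list(hmm.alphabet), size=n))
        return hmm, y

    return _make


@pytest.fixture(scope="session")
def toy_hmm():
    return toy_topology_hmm()
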
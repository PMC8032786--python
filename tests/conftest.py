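import numpy as np
import pytest

from gazesim.config import GeneratorConfig, StudyConfig
from gazesim.synth import generate_dataset


@pytest.fixture(scope="session")
def study_config():
    return StudyConfig()


@pytest.fixture(scope="session")
def small_dataset():
    """Six-participant synthetic study shared across tests."""
    return generate_dataset(GeneratorConfig(n_participants=6, seed=7))


def brute_force_align(a, b, sub, gap=0.0):
    """Exhaustive enumeration over all global alignments (oracle).

    Recursively tries substitution / gap-in-A / gap-in-B at every
    position and returns the best total score.  Exponential; only for
    very short sequences.
    """
    def rec(i, j):
        if i == len(a) and j == len(b):
            return 0.0
        best = -np.inf
        if i < len(a) and j < len(b):
            best = max(best, sub[a[i], b[j]] + rec(i + 1, j + 1))
        if i < len(a):
            best = max(best, gap + rec(i + 1, j))
        if j < len(b):
            best = max(best, gap + rec(i, j + 1))
        return best

    return rec(0, 0)
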
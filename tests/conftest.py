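import numpy as np
import pytest

from pathrank import GeneScores


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def uniform_scores(rng):
    """A 2000-gene universe with iid Uniform(0,1) p-values (global null)."""
    return GeneScores.from_pvalues(rng.random(2000))


@pytest.fixture
def named_scores():
    """Tiny named universe for id-based plumbing tests."""
    p = np.array([0.001, 0.2, 0.8, 0.05, 0.6])
    ids = np.array(["gA", "gB", "gC", "gD", "gE"])
    return GeneScores.from_pvalues(p, ids)
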
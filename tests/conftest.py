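import numpy as np
import pytest

from hipposim.attractor import AttractorConfig, build_mask, store_patterns
from hipposim.patterns import PatternSet, make_sparse_binary


@pytest.fixture(scope="session")
def small_attractor():
    """A small trained autoassociator shared across recall tests:
    N=1000, C=200, a=0.05, ten stored binary patterns (seed 0)."""
    rng = np.random.default_rng(0)
    N, C, a, p = 1000, 200, 0.05, 10
    mask = build_mask(N, C, rng)
    R = np.vstack([make_sparse_binary(N, a, seed=rng) for _ in range(p)])
    stored = PatternSet(R)
    J = store_patterns(mask, stored)
    return {"mask": mask, "patterns": stored, "weights": J,
            "config": AttractorConfig(a=a), "rng_seed": 0}
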
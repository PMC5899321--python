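import numpy as np
import pytest

from chronoforge import simulate as sim


@pytest.fixture(scope="session")
def tiny_case():
    """One shared tiny benchmark (8 taxa, 5 genes x 200 sites, LN clock)."""
    return sim.make_benchmark("tiny", seed=11)


@pytest.fixture(scope="session")
def paper_shape_case():
    """The 63-taxon, 20-gene benchmark with the 13-calibration fixture."""
    return sim.make_benchmark("paper-shape", seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
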
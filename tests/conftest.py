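import numpy as np
import pytest

from lnckit.fixtures import FixtureSpec, generate


@pytest.fixture(scope="session")
def small_spec() -> FixtureSpec:
    """A compact study: fast to generate, all planted signals present."""
    return FixtureSpec(seed=11, n_genes=300, n_mrna_genes=8, chrom_len=60_000)


@pytest.fixture(scope="session")
def small_bundle(small_spec):
    return generate(small_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
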
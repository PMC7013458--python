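import numpy as np
import pytest

from methyledit import synth


@pytest.fixture(scope="session")
def isg15_like_amplicon():
    """292 bp amplicon, 19 CpGs, sites 16-19 blocked, 1-15 analyzed."""
    return synth.make_amplicon(seed=0)


@pytest.fixture(scope="session")
def small_amplicon():
    """Short amplicon (80 bp, 5 CpGs) for fast read-level tests."""
    return synth.make_amplicon(
        name="mini", length=80, n_cpgs=5, blocked_indices=(), analysis_indices=(1, 2, 3, 4, 5), seed=7
    )


@pytest.fixture(scope="session")
def small_genome():
    """100-CGI single-chromosome genome with a planted sgRNA site."""
    return synth.make_genome(n_cgis=100, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
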
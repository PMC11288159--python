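import numpy as np
import pytest

from nanoml5mou import ModEffect, PoreModel, simulate_kmer_dataset, simulate_reads


@pytest.fixture(scope="session")
def strong_dataset():
    """500/class single-kmer dataset under the strong modification effect."""
    return simulate_kmer_dataset("AGTCC", 500, ModEffect.strong(), seed=101)


@pytest.fixture(scope="session")
def small_strong_dataset():
    """200/class single-kmer dataset, enough to train quickly in unit tests."""
    return simulate_kmer_dataset("AGTCC", 200, ModEffect.strong(), seed=202)


@pytest.fixture(scope="session")
def null_dataset():
    """500/class dataset where modified and unmodified are the same law."""
    return simulate_kmer_dataset("AGTCC", 500, ModEffect.null(), seed=303)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def pore():
    return PoreModel(seed=7)


@pytest.fixture(scope="session")
def template_reads(pore):
    """Labelled full-length reads over a 60-nt template, strong effect."""
    from nanoml5mou import make_template

    template = make_template(60, seed=5, u_density=0.25)
    mod = simulate_reads(pore, template, 40, modified=1, effect=ModEffect.strong(), seed=11)
    unmod = simulate_reads(pore, template, 40, modified=0, effect=ModEffect.strong(), seed=12)
    return template, mod, unmod
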
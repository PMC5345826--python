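import numpy as np
import pandas as pd
import pytest

from phylofactor import CompositionTable, Phylogeny, close_to_composition


def make_composition(rng, taxa, n_samples, mu=8.0, sigma=0.5):
    """Lognormal absolute abundances closed to a composition."""
    N = np.exp(rng.normal(mu, sigma, size=(len(taxa), n_samples)))
    df = pd.DataFrame(N, index=list(taxa), columns=[f"s{j}" for j in range(n_samples)])
    return close_to_composition(df)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_tree():
    """5 taxa, one polytomy at the (unrooted) root; 7 edges."""
    return Phylogeny.from_newick("((A,B),(C,D),E);")


@pytest.fixture
def binary_tree4():
    return Phylogeny.from_newick("((A,B),(C,D));")


@pytest.fixture
def toy_comp(rng):
    return make_composition(rng, "ABCDE", 12)


@pytest.fixture
def binary_env():
    """Balanced two-level covariate over 12 samples s0..s11."""
    return pd.DataFrame(
        {"site": ["gut"] * 6 + ["tongue"] * 6}, index=[f"s{j}" for j in range(12)]
    )


@pytest.fixture
def effect_comp(rng, binary_env):
    """Composition where clade {A,B} is 4x up in the tongue samples."""
    N = np.exp(rng.normal(8, 0.5, size=(5, 12)))
    df = pd.DataFrame(N, index=list("ABCDE"), columns=binary_env.index)
    df.loc[["A", "B"], binary_env["site"] == "tongue"] *= 4.0
    return close_to_composition(df)
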
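import numpy as np
import pytest
from hypothesis import settings

from mitorder.genome_model import PCGS, RRNAS, TRNAS, arrangement_from_tokens
from mitorder.order_io import load_ancestral_arrangement, load_bi1_tree

settings.register_profile("fixed", deadline=None, derandomize=True)
settings.load_profile("fixed")

# a pool of distinct gene names for small random arrangements
GENE_POOL = list(PCGS) + list(RRNAS) + list(TRNAS)


@pytest.fixture(scope="session")
def ancestor():
    return load_ancestral_arrangement()


@pytest.fixture()
def bi1_tree():
    return load_bi1_tree()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)


def random_arrangement_tokens(rng, n_genes=None, with_cr=False):
    """Random circular arrangement tokens over distinct genes incl. cox1."""
    if n_genes is None:
        n_genes = int(rng.integers(4, 11))
    names = ["cox1"] + list(
        rng.choice([g for g in GENE_POOL if g != "cox1"], size=n_genes - 1, replace=False)
    )
    rng.shuffle(names)
    tokens = [("-" if rng.random() < 0.4 else "") + g for g in names]
    if with_cr and rng.random() < 0.5:
        tokens.insert(int(rng.integers(0, len(tokens) + 1)), "CR")
    return tokens


def make_arrangement(taxon, tokens, topology="circular"):
    return arrangement_from_tokens(taxon, tokens, topology)
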
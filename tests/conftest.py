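import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose oracles.py

from rnacoevo import GtrGammaModel, RnaAlignment, parse_tree_string  # noqa: E402
from rnacoevo.seqdata import parse_tree_string as _pts  # noqa: E402,F401


@pytest.fixture
def jc():
    return GtrGammaModel.jukes_cantor()


@pytest.fixture
def jc4():
    return GtrGammaModel.jukes_cantor(alpha=0.8, n_categories=4)


@pytest.fixture
def default_model():
    return GtrGammaModel()


@pytest.fixture
def two_leaf_tree():
    return parse_tree_string("(A:0.1,B:0.1);")


@pytest.fixture
def four_leaf_tree():
    return parse_tree_string("((A:0.13,B:0.21):0.09,(C:0.17,D:0.05):0.12);")


def random_model(rng: np.random.Generator) -> GtrGammaModel:
    ex = rng.uniform(0.3, 3.0, size=6)
    fr = rng.dirichlet(np.full(4, 5.0))
    return GtrGammaModel(ex, fr, alpha=float(rng.uniform(0.3, 2.0)),
                         n_categories=int(rng.integers(1, 5)))


def random_four_leaf_tree(rng: np.random.Generator):
    b = rng.uniform(0.02, 0.6, size=6)
    return parse_tree_string(
        f"((A:{b[0]},B:{b[1]}):{b[2]},(C:{b[3]},D:{b[4]}):{b[5]});")


def alignment_from_columns(cols: list[str],
                           names: list[str] | None = None) -> RnaAlignment:
    """Build an alignment from per-site strings (cols[k][t] = taxon t, site k)."""
    n = len(cols[0])
    if names is None:
        names = [f"t{k + 1}" for k in range(n)]
    seqs = ["".join(c[t] for c in cols) for t in range(n)]
    return RnaAlignment.from_sequences(names, seqs)
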
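import numpy as np
import pytest

from enamelgmm.phylo import Phylogeny, phylogeny_from_newick_string
from enamelgmm.scheme import SemiLandmarkScheme
from enamelgmm.synthetic import DEFAULT_TREE_NEWICK, fixture_dataset


@pytest.fixture(scope="session")
def scheme() -> SemiLandmarkScheme:
    return SemiLandmarkScheme()


@pytest.fixture(scope="session")
def default_tree() -> Phylogeny:
    return phylogeny_from_newick_string(DEFAULT_TREE_NEWICK)


@pytest.fixture(scope="session")
def fixture_files(tmp_path_factory):
    """Tiny 12-specimen synthetic study on disk (TPS + metadata + newick)."""
    d = tmp_path_factory.mktemp("fixture")
    return fixture_dataset(d, seed=7)


def random_binary_tree(labels: list[str], rng: np.random.Generator) -> str:
    """Random rooted binary newick with positive branch lengths."""
    nodes = [f"{l}:{rng.uniform(0.2, 2.0):.6f}" for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        if len(nodes) == 0:
            nodes.append(f"({a},{b})")
        else:
            nodes.append(f"({a},{b}):{rng.uniform(0.2, 2.0):.6f}")
    return nodes[0] + ";"


def univariate_blomberg_k(y: np.ndarray, C: np.ndarray) -> float:
    """Direct univariate Blomberg-K formula (independent oracle path)."""
    n = len(y)
    Ci = np.linalg.pinv(C)
    one = np.ones(n)
    ahat = (one @ Ci @ y) / (one @ Ci @ one)
    num = ((y - ahat) @ (y - ahat)) / ((y - ahat) @ Ci @ (y - ahat))
    den = (np.trace(C) - n / (one @ Ci @ one)) / (n - 1)
    return num / den


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
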
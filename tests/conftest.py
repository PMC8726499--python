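import numpy as np
import pytest

import phylorates as pr
from phylorates.data import INTERCEPT, AnalysisDataset


@pytest.fixture(scope="session")
def three_tip_tree() -> pr.Phylogeny:
    return pr.Phylogeny.from_newick("(A:1,(B:0.5,C:0.5):0.5);")


@pytest.fixture(scope="session")
def small_dataset():
    """The 50-tip 'small' preset with its ground truth."""
    return pr.make_dataset("small", 1)


@pytest.fixture(scope="session")
def small_constant_rate_fit(small_dataset):
    """Constant-rate fit (scalars disallowed, lambda fixed at 1) of the
    small preset; shared across tests that only need a fitted posterior."""
    dataset, _ = small_dataset
    settings = pr.ChainSettings(
        n_iter=20_000, burnin=3_000, thin=5, seed=42, rj=False, fix_lambda=1.0
    )
    return pr.run_chain(dataset, pr.PriorSpec(), settings)


def random_dataset(n_tips: int, seed: int, p: int = 1) -> AnalysisDataset:
    """Small ad-hoc dataset for engine-level tests."""
    tree = pr.simulate_tree(n_tips, "yule", seed)
    rng = np.random.default_rng(seed)
    X = np.column_stack(
        [np.ones(n_tips)] + [rng.normal(size=n_tips) for _ in range(p)]
    )
    y = X @ np.concatenate([[0.2], rng.normal(size=p)]) + 0.2 * rng.normal(size=n_tips)
    return AnalysisDataset(
        tree=tree,
        response="y",
        y=y,
        X=X,
        names=[INTERCEPT, *[f"x{j}" for j in range(1, p + 1)]],
    )
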
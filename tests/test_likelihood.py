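import numpy as np
import pytest
import statsmodels.api as sm
from scipy.stats import multivariate_normal, norm

import phylorates as pr
from phylorates import (
    ModelState,
    Placement,
    Phylogeny,
    ScalarConfiguration,
    apply_scalars,
    phylo_covariance,
    regression_loglik,
)
from phylorates.data import INTERCEPT, AnalysisDataset
from phylorates.likelihood import gls_fit


def brute_force_covariance(tree, config, lam):
    """Dense oracle: shared path lengths found by walking parent pointers."""
    # per-branch effective rate by explicit ancestor enumeration
    placements = dict(config.items())
    eff = np.ones(tree.n_nodes)
    for u in range(tree.n_nodes):
        if u == tree.root:
            continue
        r = placements.get(Placement(u, "branch"), 1.0)
        anc = u
        while anc != -1:
            r *= placements.get(Placement(anc, "clade"), 1.0)
            anc = int(tree.parent[anc])
        eff[u] = r
    w = tree.edge_length * eff

    def path(i):
        out = []
        v = i
        while v != tree.root:
            out.append(v)
            v = int(tree.parent[v])
        return set(out)

    paths = [path(i) for i in range(tree.n_tips)]
    n = tree.n_tips
    V = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            V[i, j] = sum(w[b] for b in paths[i] & paths[j])
    d = np.diag(V).copy()
    V = lam * V
    np.fill_diagonal(V, d)
    return V


def random_state_and_dataset(seed, n_tips=5):
    rng = np.random.default_rng(seed)
    tree = pr.simulate_tree(n_tips, "yule", seed)
    X = np.column_stack([np.ones(n_tips), rng.normal(size=n_tips)])
    y = rng.normal(size=n_tips)
    ds = AnalysisDataset(tree=tree, response="y", y=y, X=X, names=[INTERCEPT, "x"])
    placements = {}
    candidates = [v for v in range(tree.n_nodes) if v != tree.root]
    for v in rng.choice(candidates, size=2, replace=False):
        kind = "branch" if (v < tree.n_tips or rng.random() < 0.5) else "clade"
        placements[Placement(int(v), kind)] = float(rng.gamma(2.0, 1.0) + 0.05)
    state = ModelState(
        beta=rng.normal(size=2),
        sigma2=float(rng.gamma(2.0, 0.5) + 0.05),
        lam=float(rng.uniform()),
        config=ScalarConfiguration(placements),
    )
    return ds, state


class TestCovariance:
    def test_lambda_one_equals_shared_paths(self, three_tip_tree):
        tt = apply_scalars(three_tip_tree, ScalarConfiguration())
        V = phylo_covariance(tt, 1.0)
        oracle = brute_force_covariance(three_tip_tree, ScalarConfiguration(), 1.0)
        assert np.allclose(V, oracle)

    def test_lambda_zero_is_diagonal_of_depths(self, three_tip_tree):
        tt = apply_scalars(three_tip_tree, ScalarConfiguration())
        V = phylo_covariance(tt, 0.0)
        assert np.allclose(V, np.diag(three_tip_tree.tip_depths()))

    def test_two_tips_no_shared_path(self):
        tree = Phylogeny.from_newick("(A:1,B:1);")
        V = phylo_covariance(apply_scalars(tree, ScalarConfiguration()), 0.5)
        assert np.allclose(V, np.eye(2))

    def test_lambda_out_of_range_rejected(self, three_tip_tree):
        tt = apply_scalars(three_tip_tree, ScalarConfiguration())
        with pytest.raises(ValueError, match="lambda"):
            phylo_covariance(tt, 1.5)


class TestLoglik:
    @pytest.mark.parametrize("seed", range(25))
    def test_matches_dense_mvn_oracle(self, seed):
        ds, state = random_state_and_dataset(seed)
        V = brute_force_covariance(ds.tree, state.config, state.lam)
        oracle = multivariate_normal(
            mean=ds.X @ state.beta, cov=state.sigma2 * V
        ).logpdf(ds.y)
        assert regression_loglik(ds, state) == pytest.approx(oracle, abs=1e-8)

    def test_one_tip_is_ordinary_normal(self):
        # a cherry with lambda=0 makes each tip an independent normal
        tree = Phylogeny.from_newick("(A:2,B:2);")
        ds = AnalysisDataset(
            tree=tree, response="y", y=np.array([0.7, -0.1]),
            X=np.ones((2, 1)), names=[INTERCEPT],
        )
        state = ModelState(beta=[0.2], sigma2=0.3, lam=0.0)
        expect = norm(0.2, np.sqrt(0.3 * 2.0)).logpdf(ds.y).sum()
        assert regression_loglik(ds, state) == pytest.approx(expect, abs=1e-10)

    def test_scale_identifiability_invariant(self):
        """Multiplying all effective lengths by c and dividing sigma2 by c
        leaves the likelihood unchanged."""
        ds, state = random_state_and_dataset(101, n_tips=8)
        c = 3.7
        scaled_tree = Phylogeny(
            ds.tree.parent, ds.tree.edge_length * c, ds.tree.tip_labels
        )
        ds2 = AnalysisDataset(
            tree=scaled_tree, response="y", y=ds.y, X=ds.X, names=ds.names
        )
        state2 = ModelState(
            beta=state.beta, sigma2=state.sigma2 / c, lam=state.lam,
            config=state.config,
        )
        assert regression_loglik(ds, state) == pytest.approx(
            regression_loglik(ds2, state2), abs=1e-10
        )

    def test_lambda_zero_ultrametric_equals_iid_regression(self):
        ds, _ = random_state_and_dataset(7, n_tips=12)
        depth = ds.tree.tip_depths()[0]
        state = ModelState(beta=[0.1, 0.4], sigma2=0.2, lam=0.0)
        iid = norm(ds.X @ state.beta, np.sqrt(state.sigma2 * depth)).logpdf(ds.y).sum()
        assert regression_loglik(ds, state) == pytest.approx(iid, abs=1e-8)

    def test_tip_reordering_invariance(self):
        a = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
        b = Phylogeny.from_newick("(C:2,(B:1,A:1):1);")
        y = {"A": 0.3, "B": -0.2, "C": 0.9}
        x = {"A": 1.0, "B": 0.0, "C": 1.0}
        lls = []
        for tree in (a, b):
            ds = AnalysisDataset(
                tree=tree,
                response="y",
                y=np.array([y[s] for s in tree.tip_labels]),
                X=np.column_stack(
                    [np.ones(3), [x[s] for s in tree.tip_labels]]
                ),
                names=[INTERCEPT, "x"],
            )
            lls.append(
                regression_loglik(ds, ModelState(beta=[0.1, 0.2], sigma2=0.4, lam=0.8))
            )
        assert lls[0] == pytest.approx(lls[1], abs=1e-10)


class TestGLS:
    def test_gls_fit_matches_statsmodels(self):
        ds, _ = random_state_and_dataset(13, n_tips=20)
        V = phylo_covariance(apply_scalars(ds.tree, ScalarConfiguration()), 1.0)
        beta, cov_unit, sigma2_ml = gls_fit(ds.X, ds.y, V)
        ref = sm.GLS(ds.y, ds.X, sigma=V).fit()
        assert np.allclose(beta, ref.params, atol=1e-10)
        # statsmodels scales by the unbiased residual variance estimate
        n, p = ds.X.shape
        assert np.allclose(
            cov_unit * sigma2_ml * n / (n - p), ref.cov_params(), rtol=1e-8
        )
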
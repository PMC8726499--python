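import numpy as np
import pandas as pd
import pytest

import phylorates as pr
from phylorates import (
    GroundTruth,
    Placement,
    ScalarConfiguration,
    make_dataset,
    simulate_binary_traits,
    simulate_continuous_traits,
    simulate_tree,
    write_dataset,
)
from phylorates.data import INTERCEPT
from phylorates.simulate import PAPER_SHAPE_PREVALENCE, _pick_shift_clade


class TestTrees:
    def test_minimal_tree(self):
        t = simulate_tree(3, "yule", 0)
        assert t.n_tips == 3
        assert t.n_nodes == 5  # strictly bifurcating

    def test_same_seed_identical(self):
        assert simulate_tree(20, "yule", 7).to_newick() == simulate_tree(
            20, "yule", 7
        ).to_newick()

    def test_unit_depth_after_scaling(self):
        t = simulate_tree(300, "yule", 1)
        depths = t.tip_depths()
        assert np.mean(depths) == pytest.approx(1.0, abs=1e-12)
        # pure-birth trees are ultrametric
        assert np.ptp(depths) < 1e-9

    def test_birth_death_model(self):
        t = simulate_tree(30, "birth-death", 2)
        assert t.n_tips == 30

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_tree(2, "yule", 0)
        with pytest.raises(ValueError, match="model"):
            simulate_tree(10, "exponential-growth", 0)


class TestBinaryTraits:
    def test_min_present_contract(self):
        tree = simulate_tree(40, "yule", 3)
        cols = simulate_binary_traits(
            tree, gain_rate=0.8, loss_rate=0.4, min_present=5, seed=1, n_traits=10
        )
        assert cols.shape == (40, 10)
        assert (cols.sum(axis=0) >= 6).all()
        assert set(np.unique(cols)) <= {0, 1}

    def test_stationary_frequency_with_symmetric_rates(self):
        """gain = loss on long branches: tip frequency averages 1/2."""
        base = simulate_tree(30, "yule", 4)
        long_tree = pr.Phylogeny(base.parent, base.edge_length * 5.0, base.tip_labels)
        rng = np.random.default_rng(5)
        freqs = [
            simulate_binary_traits(
                long_tree, gain_rate=2.0, loss_rate=2.0, min_present=0, rng=rng
            )[:, 0].mean()
            for _ in range(200)
        ]
        assert np.mean(freqs) == pytest.approx(0.5, abs=0.05)

    def test_retry_budget_exhaustion(self):
        tree = simulate_tree(10, "yule", 6)
        with pytest.raises(RuntimeError, match="could not generate"):
            simulate_binary_traits(
                tree, gain_rate=1e-6, loss_rate=1e-6, min_present=9,
                seed=2, max_tries=10,
            )


def plain_truth(beta, sigma2=0.02, lam=1.0, config=None):
    return GroundTruth(
        beta=beta,
        sigma2=sigma2,
        lam=lam,
        config=config or ScalarConfiguration(),
        predictor_rates={},
        seed=0,
    )


class TestContinuousTraits:
    def test_constant_rate_bm_sigma_recovered(self):
        """beta = 0, lambda = 1, no scalars: the ML residual rate of the
        fitted constant-rate model lands within 20% of truth at 200 tips."""
        from phylorates.likelihood import gls_fit, phylo_covariance
        from phylorates.scalars import apply_scalars

        tree = simulate_tree(200, "yule", 8)
        preds = pd.DataFrame(index=tree.tip_labels)
        truth = plain_truth({INTERCEPT: 0.0}, sigma2=0.02)
        tab = simulate_continuous_traits(
            tree, preds, truth, rng=np.random.default_rng(9), response="y"
        )
        V = phylo_covariance(apply_scalars(tree, ScalarConfiguration()), 1.0)
        _, _, sigma2_ml = gls_fit(
            np.ones((200, 1)), tab["y"].to_numpy(), V
        )
        assert sigma2_ml == pytest.approx(0.02, rel=0.2)

    def test_planted_clade_scalar_inflates_cherry_contrasts(self):
        """With a whole-clade scalar r = 8, the variance of sister-tip
        differences inside the clade is about 8x the prediction for
        unscaled branches (checked from raw branch lengths, not through
        the covariance code)."""
        tree = simulate_tree(60, "yule", 10)
        node = _pick_shift_clade(tree)
        config = ScalarConfiguration({Placement(node, "clade"): 8.0})
        truth = plain_truth({INTERCEPT: 0.0}, config=config)
        rng = np.random.default_rng(11)
        in_clade = tree.tips_below[node]

        # cherries: tip pairs that are mutual sisters
        cherries = []
        for v in range(tree.n_tips, tree.n_nodes):
            kids = tree.children[v]
            if all(k < tree.n_tips for k in kids):
                cherries.append(tuple(kids))
        ratios_in, ratios_out = [], []
        preds = pd.DataFrame(index=tree.tip_labels)
        for _ in range(150):
            tab = simulate_continuous_traits(tree, preds, truth, rng=rng, response="y")
            y = tab["y"].to_numpy()
            for i, j in cherries:
                base = truth.sigma2 * (tree.edge_length[i] + tree.edge_length[j])
                z2 = (y[i] - y[j]) ** 2 / base
                (ratios_in if in_clade[i] else ratios_out).append(z2)
        assert np.mean(ratios_in) == pytest.approx(8.0, rel=0.2)
        assert np.mean(ratios_out) == pytest.approx(1.0, rel=0.2)

    def test_lambda_zero_residuals_uncorrelated(self):
        tree = simulate_tree(25, "yule", 12)
        truth = plain_truth({INTERCEPT: 0.0}, lam=0.0)
        rng = np.random.default_rng(13)
        preds = pd.DataFrame(index=tree.tip_labels)
        draws = np.stack(
            [
                simulate_continuous_traits(tree, preds, truth, rng=rng, response="y")[
                    "y"
                ].to_numpy()
                for _ in range(400)
            ]
        )
        corr = np.corrcoef(draws.T)
        off = corr[~np.eye(corr.shape[0], dtype=bool)]
        assert abs(off.mean()) < 0.02

    def test_loglik_peaks_at_true_parameters(self):
        """Generative/likelihood consistency: across replicates the mean
        log-likelihood at the truth beats a 3-prior-sd coefficient shift."""
        from phylorates.likelihood import ModelState, regression_loglik
        from phylorates.data import AnalysisDataset

        tree = simulate_tree(25, "yule", 14)
        rng = np.random.default_rng(15)
        x = rng.normal(size=25)
        preds = pd.DataFrame({"x": x}, index=tree.tip_labels)
        truth = plain_truth({INTERCEPT: 0.1, "x": 0.4}, lam=0.9)
        shift = 3.0 * (200.0 / np.sqrt(12.0))  # 3 sd of the uniform prior
        diffs = []
        for _ in range(50):
            tab = simulate_continuous_traits(tree, preds, truth, rng=rng, response="y")
            ds = AnalysisDataset(
                tree=tree, response="y", y=tab["y"].to_numpy(),
                X=np.column_stack([np.ones(25), x]), names=[INTERCEPT, "x"],
            )
            at_truth = regression_loglik(
                ds, ModelState(beta=[0.1, 0.4], sigma2=truth.sigma2, lam=truth.lam)
            )
            perturbed = regression_loglik(
                ds,
                ModelState(
                    beta=[0.1, 0.4 + shift], sigma2=truth.sigma2, lam=truth.lam
                ),
            )
            diffs.append(at_truth - perturbed)
        assert np.mean(diffs) > 0


class TestPresets:
    def test_recovery_has_one_null_effect(self):
        _, truth = make_dataset("recovery", 0)
        zeros = [k for k, v in truth.beta.items() if k != INTERCEPT and v == 0.0]
        assert zeros == ["pred_2"]

    def test_shift_preset_plants_8x_on_predictor_clade(self):
        ds, truth = make_dataset("shift-attribution", 0)
        [(loc, r)] = list(truth.config)
        assert r == 8.0
        assert set(ds.tree.clade_tips(loc.node)) == set(truth.shift_clade_tips)
        care = ds.X[:, ds.names.index("care")]
        clade = {t: i for i, t in enumerate(ds.tree.tip_labels)}
        present = {t for t in clade if care[clade[t]] == 1}
        assert present == set(truth.shift_clade_tips)

    def test_paper_shape_dimensions_and_prevalence(self):
        ds, truth = make_dataset("paper-shape", 0)
        assert ds.tree.n_tips == 805
        # response + 15 predictors = 16 variables
        assert 1 + len(ds.names) - 1 == 16
        for name, target in PAPER_SHAPE_PREVALENCE.items():
            count = int(ds.X[:, ds.names.index(name)].sum())
            assert abs(count - target) <= 0.2 * target, (name, count, target)
            assert count > 5

    def test_same_seed_byte_identical_files(self, tmp_path):
        for sub in ("a", "b"):
            ds, truth = make_dataset("small", 5)
            write_dataset(ds, truth, tmp_path / sub)
        for name in ("tree.nwk", "traits.tsv", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_unknown_preset(self):
        with pytest.raises(KeyError, match="unknown preset"):
            make_dataset("enormous", 0)

    def test_ground_truth_json_roundtrip(self):
        _, truth = make_dataset("shift-attribution", 1)
        again = GroundTruth.from_json(truth.to_json())
        assert again.beta == truth.beta
        assert again.config == truth.config
        assert again.shift_clade_tips == truth.shift_clade_tips
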
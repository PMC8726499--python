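"""Scikit-learn style front end to the variable-rates regression.

:class:`VariableRatesRegression` wraps the reversible-jump sampler as an
estimator: the tree is a constructor parameter (it plays the role of a
kernel), ``X`` is the design matrix without intercept whose rows follow
the tree's tip order, and ``fit`` populates posterior summaries as fitted
attributes. The estimator composes with scikit-learn tooling
(``get_params`` / ``set_params`` / ``clone``); ``predict`` returns the
posterior-median linear predictor.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .data import INTERCEPT, AnalysisDataset
from .mcmc import ChainSettings, compute_ess, run_chain
from .priors import PriorSpec
from .tree import Phylogeny

__all__ = ["VariableRatesRegression"]


class VariableRatesRegression(RegressorMixin, BaseEstimator):
    """Phylogenetic regression with branch-specific evolutionary rates.

    The residual of ``y = X beta + e`` is multivariate normal with
    covariance ``sigma_b^2 * V(lambda, r)`` built from the tree, where a
    variable-dimension set of branch/clade rate scalars ``r`` is explored
    by reversible-jump MCMC together with the coefficients, the background
    rate ``sigma_b^2`` and Pagel's ``lambda``.

    Parameters
    ----------
    tree
        Rooted bifurcating :class:`~phylorates.tree.Phylogeny`; rows of
        ``X`` and ``y`` must follow its tip order.
    n_iter, burnin, thin
        Chain dimensions; ``(n_iter - burnin) // thin`` samples are kept.
    rj
        Allow rate scalars. ``False`` gives a constant-rate PGLS.
    lam, sigma2
        Fix Pagel's lambda / the background rate instead of sampling them.
    beta_bound, scalar_shape, log_sigma2_bound, k_max
        Prior hyper-parameters (see :class:`~phylorates.priors.PriorSpec`).
    random_state
        Seed; a fixed seed gives bit-identical chains.

    Attributes
    ----------
    samples_ : PosteriorSamples
        Full retained posterior.
    diagnostics_ : ChainDiagnostics
        Per-parameter ESS and per-move acceptance rates.
    coef_ : ndarray of shape (n_features,)
        Posterior median coefficients (intercept excluded).
    intercept_ : float
        Posterior median intercept.
    lambda_, sigma2_ : float
        Posterior medians of lambda and the background rate.
    branch_rates_ : ndarray of shape (n_samples, n_nodes)
        Per-branch effective scalar trace.
    """

    def __init__(
        self,
        tree: Phylogeny | None = None,
        *,
        n_iter: int = 20_000,
        burnin: int = 2_000,
        thin: int = 10,
        rj: bool = True,
        lam: float | None = None,
        sigma2: float | None = None,
        power: float = 1.0,
        beta_bound: float = 100.0,
        scalar_shape: float = 1.1,
        log_sigma2_bound: float = 20.0,
        k_max: int | None = None,
        move_weights: dict | None = None,
        adapt: bool = True,
        feature_names: list[str] | None = None,
        ess_threshold: float = 1000.0,
        random_state: int | None = None,
    ) -> None:
        self.tree = tree
        self.n_iter = n_iter
        self.burnin = burnin
        self.thin = thin
        self.rj = rj
        self.lam = lam
        self.sigma2 = sigma2
        self.power = power
        self.beta_bound = beta_bound
        self.scalar_shape = scalar_shape
        self.log_sigma2_bound = log_sigma2_bound
        self.k_max = k_max
        self.move_weights = move_weights
        self.adapt = adapt
        self.feature_names = feature_names
        self.ess_threshold = ess_threshold
        self.random_state = random_state

    # ------------------------------------------------------------------ #

    def _settings(self) -> ChainSettings:
        return ChainSettings(
            n_iter=self.n_iter,
            burnin=self.burnin,
            thin=self.thin,
            seed=self.random_state,
            power=self.power,
            rj=self.rj,
            fix_lambda=self.lam,
            fix_sigma2=self.sigma2,
            adapt=self.adapt,
            move_weights=self.move_weights,
        )

    def _priors(self) -> PriorSpec:
        return PriorSpec(
            beta_bound=self.beta_bound,
            scalar_shape=self.scalar_shape,
            log_sigma2_bound=self.log_sigma2_bound,
            k_max=self.k_max,
        )

    def _dataset(self, X, y) -> AnalysisDataset:
        if self.tree is None:
            raise ValueError("a tree is required to fit this estimator")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n = self.tree.n_tips
        if X.shape[0] != n or y.shape[0] != n:
            raise ValueError(
                f"X and y must have one row per tree tip ({n}), got "
                f"{X.shape[0]} and {y.shape[0]}"
            )
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise ValueError("X and y must be finite (no missing data)")
        names = list(self.feature_names or [f"x{j}" for j in range(X.shape[1])])
        if len(names) != X.shape[1]:
            raise ValueError("feature_names length does not match X")
        return AnalysisDataset(
            tree=self.tree,
            response="y",
            y=y,
            X=np.column_stack([np.ones(n), X]),
            names=[INTERCEPT, *names],
        )

    # ------------------------------------------------------------------ #

    def fit(self, X, y):
        """Run the chain and summarize the posterior."""
        dataset = self._dataset(X, y)
        samples, diagnostics = run_chain(dataset, self._priors(), self._settings())
        self.samples_ = samples
        self.diagnostics_ = diagnostics
        med = np.median(samples.beta, axis=0)
        self.intercept_ = float(med[0])
        self.coef_ = med[1:]
        self.lambda_ = float(np.median(samples.lam))
        self.sigma2_ = float(np.median(samples.sigma2))
        self.branch_rates_ = samples.branch_rates
        self.n_features_in_ = X.shape[1] if hasattr(X, "shape") else len(X[0])
        self.feature_names_in_ = np.asarray(dataset.names[1:], dtype=object)
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_

    def ess_warnings(self) -> list[str]:
        check_is_fitted(self, "samples_")
        return compute_ess(self.samples_, self.ess_threshold).warnings

    def scaled_tree_newick(self) -> str:
        """Newick of the tree with branches stretched by posterior-median
        effective scalars (long branch = fast evolution)."""
        check_is_fitted(self, "samples_")
        from .scalars import TransformedTree

        med_rates = np.median(self.branch_rates_, axis=0)
        return TransformedTree(
            self.tree, self.tree.edge_length * med_rates
        ).to_newick()
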
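"""Reversible-jump MCMC over the variable-rates regression posterior.

The sampler explores regression coefficients, the background rate
sigma_b^2, Pagel's lambda, and a variable-dimension set of rate scalars.
Moves:

* random-walk updates of single coefficients (flat prior within bounds),
* random-walk on log sigma_b^2,
* random-walk on lambda with reflection at [0, 1],
* multiplicative random-walk on an existing scalar's value,
* reversible-jump birth — a uniformly chosen unoccupied location (any
  non-root branch, or any non-root internal node as a whole clade)
  receives a scalar drawn from its gamma prior,
* reversible-jump death — a uniformly chosen existing scalar is removed.

With the configuration prior of :class:`~phylorates.priors.PriorSpec`
(uniform on the number of scalars, uniform location subsets, i.i.d. gamma
values) and these proposals, the Green acceptance ratio for birth/death
collapses to the tempered likelihood ratio times the ratio of move
probabilities, which differs from 1 only at the k = 0 / k = k_max
boundaries.

Proposal step sizes adapt by Robbins–Monro toward a target acceptance rate
during burn-in only and are frozen afterwards, preserving detailed
balance for the retained samples. A fixed seed gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .data import AnalysisDataset
from .diagnostics import ChainDiagnostics, ess
from .likelihood import CovarianceCache, ModelState, gls_fit
from .priors import PriorSpec
from .scalars import BRANCH, CLADE, Placement, ScalarConfiguration
from .tree import Phylogeny

__all__ = [
    "ChainSettings",
    "PosteriorSamples",
    "run_chain",
    "compute_ess",
    "scalar_locations",
    "PAPER_SCALE",
    "DESK_SCALE",
]

_LOG2PI = float(np.log(2.0 * np.pi))

_MOVES = ("beta", "sigma2", "lambda", "value", "birth", "death", "exchange")


@dataclass
class ChainSettings:
    """Chain length, seed, proposal configuration and model restrictions.

    ``power`` tempers the likelihood (target = prior * L^power), used by the
    stepping-stone evidence estimator; ``power = 0`` samples the prior.
    ``fix_lambda`` / ``fix_sigma2`` pin those parameters; ``rj = False``
    disables rate scalars entirely (constant-rate regression).
    """

    n_iter: int = 20_000
    burnin: int = 2_000
    thin: int = 10
    seed: int | None = None
    power: float = 1.0
    rj: bool = True
    fix_lambda: float | None = None
    fix_sigma2: float | None = None
    adapt: bool = True
    target_accept: float = 0.3
    move_weights: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.burnin >= self.n_iter:
            raise ValueError("burn-in must be smaller than the iteration count")
        if self.thin < 1:
            raise ValueError("thinning interval must be >= 1")
        if self.fix_lambda is not None and not 0.0 <= self.fix_lambda <= 1.0:
            raise ValueError("fixed lambda must lie in [0, 1]")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burnin) // self.thin


#: chain preset matching the published analysis scale
PAPER_SCALE = ChainSettings(n_iter=200_500_000, burnin=500_000, thin=100_000)
#: default desk-scale preset for interactive work and tests
DESK_SCALE = ChainSettings()


def scalar_locations(tree: Phylogeny) -> list[Placement]:
    """Legal scalar locations: every non-root branch and, as whole clades,
    every non-root internal node. Tip clades coincide with tip branches and
    are represented once, as branch placements."""
    locs = [Placement(v, BRANCH) for v in range(tree.n_nodes) if v != tree.root]
    locs += [
        Placement(v, CLADE)
        for v in range(tree.n_tips, tree.n_nodes)
        if v != tree.root
    ]
    return locs


@dataclass
class PosteriorSamples:
    """Retained draws from one chain."""

    names: list[str]
    beta: np.ndarray  # (S, p)
    sigma2: np.ndarray  # (S,)
    lam: np.ndarray  # (S,)
    n_scalars: np.ndarray  # (S,)
    loglik: np.ndarray  # (S,) untempered
    logprior: np.ndarray  # (S,)
    configs: list[ScalarConfiguration]
    branch_rates: np.ndarray  # (S, n_nodes) effective per-branch scalars
    tree: Phylogeny
    settings: ChainSettings
    priors: PriorSpec

    def __len__(self) -> int:
        return self.beta.shape[0]

    def states(self):
        for i in range(len(self)):
            yield ModelState(
                beta=self.beta[i],
                sigma2=float(self.sigma2[i]),
                lam=float(self.lam[i]),
                config=self.configs[i],
            )

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "loglik": self.loglik,
                "logprior": self.logprior,
                **{f"beta[{n}]": self.beta[:, j] for j, n in enumerate(self.names)},
                "sigma2": self.sigma2,
                "lambda": self.lam,
                "n_scalars": self.n_scalars,
                "scalars": [c.serialize() for c in self.configs],
            }
        )
        return df

    def write_trace(self, path) -> None:
        """Delimited trace, one row per retained iteration."""
        self.to_dataframe().to_csv(path, sep="\t", index_label="sample")


def compute_ess(samples: PosteriorSamples, threshold: float = 1000.0) -> ChainDiagnostics:
    """Autocorrelation-based effective sample sizes for a chain.

    Emits a warning entry for every monitored parameter whose ESS falls
    below ``threshold`` (the published QC bar is 1,000).
    """
    values = {f"beta[{n}]": samples.beta[:, j] for j, n in enumerate(samples.names)}
    if samples.settings.fix_sigma2 is None:
        values["sigma2"] = samples.sigma2
    if samples.settings.fix_lambda is None:
        values["lambda"] = samples.lam
    values["loglik"] = samples.loglik
    ess_map = {k: ess(v) for k, v in values.items()}
    warnings = [
        f"ESS below {threshold:g} for {k}: {v:.1f}"
        for k, v in ess_map.items()
        if np.isfinite(v) and v < threshold
    ]
    warnings += [f"degenerate (constant) trace for {k}" for k, v in ess_map.items() if not np.isfinite(v)]
    return ChainDiagnostics(ess=ess_map, acceptance={}, warnings=warnings)


# --------------------------------------------------------------------------- #


class _Chain:
    """Mutable sampler state; one instance per run_chain call."""

    def __init__(
        self,
        dataset: AnalysisDataset,
        priors: PriorSpec,
        settings: ChainSettings,
    ) -> None:
        if not (np.all(np.isfinite(dataset.X)) and np.all(np.isfinite(dataset.y))):
            raise FloatingPointError(
                "non-finite values in design or response at initialization"
            )
        self.ds = dataset
        self.priors = priors
        self.st = settings
        self.tree = dataset.tree
        self.n, self.p = dataset.X.shape
        self.rng = np.random.default_rng(settings.seed)

        self.locations = scalar_locations(self.tree)
        self.L = len(self.locations)
        self.k_max = min(priors.k_max, self.L) if priors.k_max is not None else self.L
        if not settings.rj:
            self.k_max = 0
        # cover masks per location (bool over nodes)
        masks = np.zeros((self.L, self.tree.n_nodes), dtype=bool)
        for i, loc in enumerate(self.locations):
            if loc.kind == BRANCH:
                masks[i, loc.node] = True
            else:
                masks[i] = self.tree.clade_masks[loc.node]
        self.cover = masks

        self.cache = CovarianceCache(self.tree, dataset.X, dataset.y)

        # ---- initial state: GLS under lambda=1, no scalars
        self.log_rate = np.zeros(self.tree.n_nodes)
        self.cache.set_lengths(self.tree.edge_length, 1.0)
        V1 = (self.tree.path_matrix.T * self.tree.edge_length) @ self.tree.path_matrix
        beta0, cov_unit, s2_ml = gls_fit(dataset.X, dataset.y, V1)
        self.beta = np.clip(beta0, -priors.beta_bound, priors.beta_bound)
        if settings.fix_sigma2 is not None:
            self.log_s2 = math.log(settings.fix_sigma2)
        else:
            self.log_s2 = float(
                np.clip(math.log(s2_ml), -priors.log_sigma2_bound + 1e-9,
                        priors.log_sigma2_bound - 1e-9)
            )
        self.lam = settings.fix_lambda if settings.fix_lambda is not None else 0.5
        self.cache.set_lambda(self.lam)
        self.quad = self.cache.quad(self.beta)
        self.occupied: dict[int, float] = {}  # location index -> scalar value

        if not np.isfinite(self.loglik()):
            raise FloatingPointError("non-finite likelihood at initialization")

        # ---- proposal steps (adapted during burn-in)
        sd = np.sqrt(np.maximum(np.diag(cov_unit) * s2_ml, 1e-12))
        self.step_beta = np.log(2.4 * sd)
        self.step = {"sigma2": math.log(0.5), "lambda": math.log(0.1),
                     "value": math.log(0.5), "exchange": math.log(0.5)}
        self.adapt_count = {m: 0 for m in ("beta", "sigma2", "lambda", "value", "exchange")}

        # ---- move weights
        w = {"beta": 0.35, "sigma2": 0.10, "lambda": 0.10,
             "value": 0.19, "birth": 0.095, "death": 0.095, "exchange": 0.07}
        if settings.move_weights:
            w.update(settings.move_weights)
        if settings.fix_sigma2 is not None:
            w["sigma2"] = 0.0
            w["exchange"] = 0.0
        if settings.fix_lambda is not None:
            w["lambda"] = 0.0
        if not settings.rj or self.k_max == 0:
            w["value"] = w["birth"] = w["death"] = w["exchange"] = 0.0
        self.base_weights = np.array([w[m] for m in _MOVES], float)
        if self.base_weights.sum() <= 0:
            raise ValueError("no moves enabled")
        self._prob_cache: dict[tuple[bool, bool], np.ndarray] = {}

        self.prop = {m: 0 for m in _MOVES}
        self.acc = {m: 0 for m in _MOVES}

    # -- probabilities ---------------------------------------------------- #

    def move_probs(self, k: int) -> np.ndarray:
        key = (k > 0, k < self.k_max)
        probs = self._prob_cache.get(key)
        if probs is None:
            w = self.base_weights.copy()
            if k == 0:
                w[_MOVES.index("value")] = 0.0
                w[_MOVES.index("death")] = 0.0
                w[_MOVES.index("exchange")] = 0.0
            if k >= self.k_max:
                w[_MOVES.index("birth")] = 0.0
            probs = w / w.sum()
            self._prob_cache[key] = probs
        return probs

    # -- likelihood pieces ------------------------------------------------ #

    def loglik(self, quad: float | None = None, log_s2: float | None = None) -> float:
        q = self.quad if quad is None else quad
        ls2 = self.log_s2 if log_s2 is None else log_s2
        return -0.5 * (
            self.n * (_LOG2PI + ls2) + self.cache.logdet + q * math.exp(-ls2)
        )

    def _refactor(self) -> None:
        lengths = self.tree.edge_length * np.exp(self.log_rate)
        self.cache.set_lengths(lengths, self.lam)
        self.quad = self.cache.quad(self.beta)

    # -- adaptation -------------------------------------------------------- #

    def _adapt(self, move: str, accepted: float, j: int | None = None) -> None:
        self.adapt_count[move] += 1
        gain = 1.0 / self.adapt_count[move] ** 0.6
        delta = gain * (accepted - self.st.target_accept)
        if move == "beta":
            self.step_beta[j] = np.clip(self.step_beta[j] + delta, -25.0, 25.0)
        else:
            self.step[move] = float(np.clip(self.step[move] + delta, -25.0, 25.0))

    # -- moves -------------------------------------------------------------- #

    def do_beta(self, adapting: bool) -> bool:
        j = int(self.rng.integers(self.p))
        delta = self.rng.normal() * math.exp(self.step_beta[j])
        new_bj = self.beta[j] + delta
        accepted = False
        if abs(new_bj) <= self.priors.beta_bound:
            r_new = (self.cache.ys - self.cache.Xs @ self.beta) - self.cache.Xs[:, j] * delta
            quad_new = float(r_new @ r_new)
            dll = -0.5 * (quad_new - self.quad) * math.exp(-self.log_s2)
            if math.log(self.rng.random()) < self.st.power * dll:
                self.beta[j] = new_bj
                self.quad = quad_new
                accepted = True
        if adapting:
            self._adapt("beta", float(accepted), j)
        return accepted

    def do_sigma2(self, adapting: bool) -> bool:
        new_ls2 = self.log_s2 + self.rng.normal() * math.exp(self.step["sigma2"])
        accepted = False
        if abs(new_ls2) <= self.priors.log_sigma2_bound:
            dll = self.loglik(log_s2=new_ls2) - self.loglik()
            if math.log(self.rng.random()) < self.st.power * dll:
                self.log_s2 = new_ls2
                accepted = True
        if adapting:
            self._adapt("sigma2", float(accepted))
        return accepted

    def do_lambda(self, adapting: bool) -> bool:
        new_lam = self.lam + self.rng.normal() * math.exp(self.step["lambda"])
        new_lam = new_lam % 2.0
        if new_lam > 1.0:
            new_lam = 2.0 - new_lam
        old = (self.cache.Xs, self.cache.ys, self.cache.logdet, self.quad, self.lam)
        ll_old = self.loglik()
        self.cache.set_lambda(new_lam)
        quad_new = self.cache.quad(self.beta)
        self.quad, self.lam = quad_new, new_lam
        dll = self.loglik() - ll_old
        accepted = math.log(self.rng.random()) < self.st.power * dll
        if not accepted:
            self.cache.Xs, self.cache.ys, self.cache.logdet, self.quad, self.lam = old
        if adapting:
            self._adapt("lambda", float(accepted))
        return accepted

    def _try_rates(self, mask: np.ndarray, dlog: float, extra_logacc: float) -> bool:
        """Shared accept/reject for moves that change effective rates."""
        old = (
            self.cache._raw_V,
            self.cache.Xs,
            self.cache.ys,
            self.cache.logdet,
            self.quad,
        )
        old_vals = self.log_rate[mask].copy()
        ll_old = self.loglik()
        self.log_rate[mask] += dlog
        self._refactor()
        dll = self.loglik() - ll_old
        if math.log(self.rng.random()) < self.st.power * dll + extra_logacc:
            return True
        self.log_rate[mask] = old_vals
        (
            self.cache._raw_V,
            self.cache.Xs,
            self.cache.ys,
            self.cache.logdet,
            self.quad,
        ) = old
        return False

    def do_value(self, adapting: bool) -> bool:
        idx = list(self.occupied)[int(self.rng.integers(len(self.occupied)))]
        r_old = self.occupied[idx]
        r_new = r_old * math.exp(self.rng.normal() * math.exp(self.step["value"]))
        extra = (
            self.priors.scalar_logpdf(r_new)
            - self.priors.scalar_logpdf(r_old)
            + math.log(r_new)
            - math.log(r_old)  # Jacobian of the log-space random walk
        )
        accepted = self._try_rates(
            self.cover[idx], math.log(r_new) - math.log(r_old), extra
        )
        if accepted:
            self.occupied[idx] = r_new
        if adapting:
            self._adapt("value", float(accepted))
        return accepted

    def do_exchange(self, adapting: bool) -> bool:
        """Trade magnitude between the background rate and one scalar.

        Proposes sigma2 -> c * sigma2 and r -> r / c for a random placement
        (c log-symmetric). For placements covering much of the tree the
        likelihood is nearly invariant, so this mixes along the
        sigma2-versus-broad-scalar ridge that plain random walks cross
        slowly.
        """
        idx = list(self.occupied)[int(self.rng.integers(len(self.occupied)))]
        r_old = self.occupied[idx]
        logc = self.rng.normal() * math.exp(self.step["exchange"])
        r_new = r_old * math.exp(-logc)
        new_ls2 = self.log_s2 + logc
        accepted = False
        if abs(new_ls2) <= self.priors.log_sigma2_bound and r_new > 0:
            extra = (
                self.priors.scalar_logpdf(r_new)
                - self.priors.scalar_logpdf(r_old)
                + math.log(r_new)
                - math.log(r_old)
            )
            old_ls2 = self.log_s2
            old_quad = self.quad
            old = (
                self.cache._raw_V,
                self.cache.Xs,
                self.cache.ys,
                self.cache.logdet,
            )
            old_vals = self.log_rate[self.cover[idx]].copy()
            ll_old = self.loglik()
            self.log_rate[self.cover[idx]] -= logc
            self._refactor()
            self.log_s2 = new_ls2
            dll = self.loglik() - ll_old
            if math.log(self.rng.random()) < self.st.power * dll + extra:
                self.occupied[idx] = r_new
                accepted = True
            else:
                self.log_rate[self.cover[idx]] = old_vals
                self.log_s2 = old_ls2
                self.quad = old_quad
                (
                    self.cache._raw_V,
                    self.cache.Xs,
                    self.cache.ys,
                    self.cache.logdet,
                ) = old
        if adapting:
            self._adapt("exchange", float(accepted))
        return accepted

    def do_birth(self) -> bool:
        k = len(self.occupied)
        # uniform draw among unoccupied locations
        while True:
            idx = int(self.rng.integers(self.L))
            if idx not in self.occupied:
                break
        r_new = self.priors.sample_scalar(self.rng)
        if not r_new > 0:
            return False
        pb = self.move_probs(k)[_MOVES.index("birth")]
        pd_rev = self.move_probs(k + 1)[_MOVES.index("death")]
        extra = math.log(pd_rev) - math.log(pb)
        accepted = self._try_rates(self.cover[idx], math.log(r_new), extra)
        if accepted:
            self.occupied[idx] = r_new
        return accepted

    def do_death(self) -> bool:
        k = len(self.occupied)
        idx = list(self.occupied)[int(self.rng.integers(k))]
        r_old = self.occupied[idx]
        pd = self.move_probs(k)[_MOVES.index("death")]
        pb_rev = self.move_probs(k - 1)[_MOVES.index("birth")]
        extra = math.log(pb_rev) - math.log(pd)
        accepted = self._try_rates(self.cover[idx], -math.log(r_old), extra)
        if accepted:
            del self.occupied[idx]
        return accepted

    # -- records ------------------------------------------------------------ #

    def current_config(self) -> ScalarConfiguration:
        return ScalarConfiguration(
            {self.locations[i]: r for i, r in self.occupied.items()}
        )

    def exact_rates(self) -> np.ndarray:
        """Effective per-branch scalars rebuilt from the placements.

        The incremental ``log_rate`` carries float residues of order 1e-16
        after births and deaths; a branch with no covering placement must
        report exactly 1 (it counts on neither side of the 95% shift rule),
        so retained samples recompute rates from scratch.
        """
        log_r = np.zeros(self.tree.n_nodes)
        for idx, r in self.occupied.items():
            log_r[self.cover[idx]] += math.log(r)
        log_r[self.tree.root] = 0.0
        return np.exp(log_r)

    def log_prior(self) -> float:
        return self.priors.log_prior(
            self.beta,
            math.exp(self.log_s2),
            self.lam,
            np.array(list(self.occupied.values())),
            self.L,
            self.k_max,
        )


def run_chain(
    dataset: AnalysisDataset,
    priors: PriorSpec | None = None,
    settings: ChainSettings | None = None,
) -> tuple[PosteriorSamples, ChainDiagnostics]:
    """Sample the variable-rates regression posterior.

    Returns the retained samples (count ``(n_iter - burnin) // thin``) and
    chain diagnostics (per-parameter ESS, per-move acceptance rates).
    """
    priors = priors if priors is not None else PriorSpec()
    settings = settings if settings is not None else DESK_SCALE
    chain = _Chain(dataset, priors, settings)

    S = settings.n_retained
    p = chain.p
    out_beta = np.empty((S, p))
    out_sigma2 = np.empty(S)
    out_lam = np.empty(S)
    out_k = np.empty(S, dtype=int)
    out_ll = np.empty(S)
    out_lp = np.empty(S)
    out_rates = np.empty((S, chain.tree.n_nodes))
    configs: list[ScalarConfiguration] = []

    rng = chain.rng
    s = 0
    for it in range(1, settings.n_iter + 1):
        adapting = settings.adapt and it <= settings.burnin
        probs = chain.move_probs(len(chain.occupied))
        u = rng.random()
        move = _MOVES[int(np.searchsorted(np.cumsum(probs), u))]
        if move == "beta":
            accepted = chain.do_beta(adapting)
        elif move == "sigma2":
            accepted = chain.do_sigma2(adapting)
        elif move == "lambda":
            accepted = chain.do_lambda(adapting)
        elif move == "value":
            accepted = chain.do_value(adapting)
        elif move == "birth":
            accepted = chain.do_birth()
        elif move == "death":
            accepted = chain.do_death()
        else:
            accepted = chain.do_exchange(adapting)
        if not adapting:
            chain.prop[move] += 1
            chain.acc[move] += int(accepted)

        if it > settings.burnin and (it - settings.burnin) % settings.thin == 0:
            out_beta[s] = chain.beta
            out_sigma2[s] = math.exp(chain.log_s2)
            out_lam[s] = chain.lam
            out_k[s] = len(chain.occupied)
            out_ll[s] = chain.loglik()
            out_lp[s] = chain.log_prior()
            out_rates[s] = chain.exact_rates()
            configs.append(chain.current_config())
            s += 1

    samples = PosteriorSamples(
        names=list(dataset.names),
        beta=out_beta[:s],
        sigma2=out_sigma2[:s],
        lam=out_lam[:s],
        n_scalars=out_k[:s],
        loglik=out_ll[:s],
        logprior=out_lp[:s],
        configs=configs,
        branch_rates=out_rates[:s],
        tree=chain.tree,
        settings=settings,
        priors=priors,
    )
    diagnostics = compute_ess(samples)
    diagnostics.acceptance = {
        m: (chain.acc[m] / chain.prop[m]) if chain.prop[m] else np.nan
        for m in _MOVES
        if chain.prop[m] or chain.base_weights[_MOVES.index(m)] > 0
    }
    return samples, diagnostics
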
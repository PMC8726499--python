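"""Synthetic data with recorded ground truth.

Generates the three ingredients the analysis consumes — a time-calibrated
tree, phylogenetically clustered binary predictors, and continuous traits
on log10 scale with phylogenetically structured residuals — under exactly
the generative model the inference assumes, so parameter-recovery and
shift-detection claims can be tested against a known truth.

Trees are pure-birth (or birth–death) simulations scaled to unit depth.
Binary predictors evolve under a two-state continuous-time Markov process
from an absent root state (care and terrestriality are derived states in
amphibians), resampled until enough species exhibit the trait. Continuous
responses are ``X beta`` plus a multivariate-normal residual whose
covariance is the lambda-transformed, scalar-stretched tree — planted
whole-clade rate multipliers create the rate shifts the pipeline is asked
to find.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from dendropy.model import birthdeath
from scipy.linalg import cholesky

from .data import AnalysisDataset, INTERCEPT
from .likelihood import phylo_covariance
from .scalars import BRANCH, Placement, ScalarConfiguration, apply_scalars
from .tree import Phylogeny

__all__ = [
    "GroundTruth",
    "simulate_tree",
    "simulate_binary_traits",
    "simulate_continuous_traits",
    "make_dataset",
    "write_dataset",
    "PRESETS",
]


@dataclass
class GroundTruth:
    """Planted parameters of a synthetic dataset."""

    beta: dict[str, float]
    sigma2: float
    lam: float
    config: ScalarConfiguration
    predictor_rates: dict[str, tuple[float, float]]
    seed: int
    preset: str = ""
    shift_clade_tips: tuple[str, ...] = ()

    def to_json(self) -> str:
        payload = {
            "preset": self.preset,
            "seed": self.seed,
            "beta": self.beta,
            "sigma2": self.sigma2,
            "lambda": self.lam,
            "scalars": self.config.serialize(),
            "predictor_rates": {k: list(v) for k, v in self.predictor_rates.items()},
            "shift_clade_tips": list(self.shift_clade_tips),
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            beta=d["beta"],
            sigma2=d["sigma2"],
            lam=d["lambda"],
            config=ScalarConfiguration.deserialize(d["scalars"]),
            predictor_rates={k: tuple(v) for k, v in d["predictor_rates"].items()},
            seed=d["seed"],
            preset=d.get("preset", ""),
            shift_clade_tips=tuple(d.get("shift_clade_tips", ())),
        )


def simulate_tree(n_tips: int, model: str = "yule", seed: int | None = None) -> Phylogeny:
    """Simulate an ultrametric bifurcating tree scaled to unit mean depth.

    ``model`` is ``"yule"`` (pure birth) or ``"birth-death"`` (extinction
    at half the speciation rate, extinct lineages pruned).
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    if model == "yule":
        birth, death = 1.0, 0.0
    elif model == "birth-death":
        birth, death = 1.0, 0.5
    else:
        raise ValueError(f"unknown tree model: {model!r}")
    rng = random.Random(None if seed is None else int(seed))
    dtree = birthdeath.birth_death_tree(
        birth_rate=birth,
        death_rate=death,
        num_extant_tips=n_tips,
        rng=rng,
        repeat_until_success=True,
    )
    # the simulation stops at the n-th speciation, leaving the newest pair
    # with zero-length branches; extend all tip edges by the waiting time to
    # the next event so the n-lineage period has positive duration
    extra = rng.expovariate(n_tips * birth)
    for i, leaf in enumerate(dtree.leaf_node_iter()):
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
        if leaf.taxon is None:
            leaf.taxon = dtree.taxon_namespace.new_taxon(label=f"t{i + 1}")
        else:
            leaf.taxon.label = f"t{i + 1}"
    phylo = Phylogeny.from_dendropy(dtree)
    depths = phylo.tip_depths()
    lengths = phylo.edge_length / float(np.mean(depths))
    lengths[phylo.root] = 0.0
    return Phylogeny(
        phylo.parent, lengths, phylo.tip_labels, children=phylo.children
    )


def _transition_sample(
    tree: Phylogeny, gain: float, loss: float, rng: np.random.Generator
) -> np.ndarray:
    """One two-state Markov realization along the tree; root state absent."""
    q = gain + loss
    state = np.zeros(tree.n_nodes, dtype=int)
    for v in tree.postorder[::-1]:  # preorder: parents before children
        if v == tree.root:
            continue
        t = tree.edge_length[v]
        frac = 1.0 - np.exp(-q * t)
        if state[tree.parent[v]] == 0:
            p_switch = (gain / q) * frac
        else:
            p_switch = (loss / q) * frac
        flip = rng.random() < p_switch
        state[v] = 1 - state[tree.parent[v]] if flip else state[tree.parent[v]]
    return state[: tree.n_tips]


def simulate_binary_traits(
    tree: Phylogeny,
    gain_rate: float,
    loss_rate: float,
    min_present: int = 5,
    seed: int | None = None,
    n_traits: int = 1,
    rng: np.random.Generator | None = None,
    target_count: int | None = None,
    target_tol: float = 0.2,
    max_tries: int = 500,
) -> np.ndarray:
    """Binary predictors evolved under a two-state Markov process.

    Columns are resampled (up to ``max_tries`` draws from the same stream)
    until more than ``min_present`` species carry the derived state; with
    ``target_count`` the accepted prevalence must additionally fall within
    ``target_tol`` (relative) of the target. Returns an (n_tips, n_traits)
    0/1 array; phylogenetic clustering of the 1s arises from the shared
    history, not from any explicit constraint.
    """
    if gain_rate <= 0 or loss_rate < 0:
        raise ValueError("rates must be positive (loss may be zero only if gain > 0)")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = np.empty((tree.n_tips, n_traits), dtype=int)
    for j in range(n_traits):
        for attempt in range(max_tries):
            col = _transition_sample(tree, gain_rate, loss_rate, rng)
            n_present = int(col.sum())
            if n_present <= min_present or n_present == tree.n_tips:
                continue
            if target_count is not None and abs(n_present - target_count) > (
                target_tol * target_count
            ):
                continue
            out[:, j] = col
            break
        else:
            raise RuntimeError(
                f"could not generate binary trait {j} with > {min_present} "
                f"present species in {max_tries} tries"
            )
    return out


def _mvn_residual(
    tree: Phylogeny,
    sigma2: float,
    lam: float,
    config: ScalarConfiguration,
    rng: np.random.Generator,
) -> np.ndarray:
    V = phylo_covariance(apply_scalars(tree, config), lam)
    L = cholesky(sigma2 * V, lower=True)
    return L @ rng.standard_normal(tree.n_tips)


def simulate_continuous_traits(
    tree: Phylogeny,
    predictors: pd.DataFrame,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
    response: str = "response",
) -> pd.DataFrame:
    """Generate the response: X beta plus a phylogenetic residual.

    ``predictors`` is tip-indexed (tree tip order) with one column per
    named effect in ``truth.beta`` (the intercept key excepted); the
    residual is MVN(0, sigma2 * V(lambda, scalars)).
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    mu = np.full(tree.n_tips, truth.beta.get(INTERCEPT, 0.0))
    for name, b in truth.beta.items():
        if name == INTERCEPT:
            continue
        mu = mu + b * predictors[name].to_numpy(dtype=float)
    resid = _mvn_residual(tree, truth.sigma2, truth.lam, truth.config, rng)
    out = predictors.copy()
    out[response] = mu + resid
    return out


def simulate_bm_trait(
    tree: Phylogeny,
    sigma2: float,
    root_value: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Plain Brownian trait (used for continuous covariates like body size)."""
    return root_value + _mvn_residual(tree, sigma2, 1.0, ScalarConfiguration(), rng)


# --------------------------------------------------------------------------- #
# presets


def _pick_shift_clade(
    tree: Phylogeny, min_frac: float = 0.1, max_frac: float = 0.3
) -> int:
    """Internal non-root node to carry the planted shift.

    Among clades holding 10-30% of the tips, the one subtended by the
    longest stem branch: a shift needs evolutionary time on the founding
    lineage to be expressible as a stem-rate excess at all. Falls back to
    the clade closest to 20% of tips if the size window is empty.
    """
    n = tree.n_tips
    candidates = [
        v
        for v in range(n, tree.n_nodes)
        if v != tree.root
        and min_frac * n <= int(tree.tips_below[v].sum()) <= max_frac * n
    ]
    if candidates:
        return max(candidates, key=lambda v: tree.edge_length[v])
    target = 0.5 * (min_frac + max_frac) * n
    return min(
        (v for v in range(n, tree.n_nodes) if v != tree.root),
        key=lambda v: abs(int(tree.tips_below[v].sum()) - target),
    )


#: prevalence targets (species out of 805) for the paper-shape preset
PAPER_SHAPE_PREVALENCE = {
    "female_egg_attendance": 80,
    "male_egg_attendance": 85,
    "egg_brooding": 30,
    "female_tadpole_attendance": 25,
    "male_tadpole_attendance": 12,
    "female_tadpole_transport": 30,
    "male_tadpole_transport": 40,
    "tadpole_feeding": 25,
    "juvenile_attendance": 10,
    "viviparity": 22,
    "direct_development": 120,
    "terrestrial_eggs": 240,
    "terrestrial_larvae": 60,
}

PRESETS = ("small", "recovery", "shift-attribution", "paper-shape")

# default residual structure: phylogenetic s.d. ~0.14 per unit depth on
# log10 scale, high but imperfect signal
_SIGMA2 = 0.02


def make_dataset(preset_name: str, seed: int) -> tuple[AnalysisDataset, GroundTruth]:
    """Build a named synthetic dataset with its ground truth.

    Presets:

    * ``small`` — 50 tips; body size + one binary care predictor.
    * ``recovery`` — 100 tips; three binary predictors with true effects
      0.2, 0 and -0.3 on the log10 response.
    * ``shift-attribution`` — 100 tips; a binary predictor present exactly
      in one ~20-tip clade that also carries a planted 8x whole-clade rate
      scalar.
    * ``paper-shape`` — 805 tips; body size, a trade-off partner trait and
      13 binary predictors with amphibian-like prevalences.
    """
    if preset_name not in PRESETS:
        raise KeyError(f"unknown preset {preset_name!r}; choose from {PRESETS}")
    ss = np.random.SeedSequence([hash_preset(preset_name), int(seed)])
    tree_seed, traits_seed = (int(s) for s in ss.generate_state(2) >> 1)
    rng = np.random.default_rng(traits_seed)

    if preset_name == "small":
        tree = simulate_tree(50, "yule", tree_seed)
        care = simulate_binary_traits(tree, gain_rate=1.0, loss_rate=0.5, rng=rng)
        body = simulate_bm_trait(tree, sigma2=0.1, root_value=1.5, rng=rng)
        preds = pd.DataFrame(
            {"body_size": body, "care": care[:, 0]}, index=tree.tip_labels
        )
        truth = GroundTruth(
            beta={INTERCEPT: 0.3, "body_size": 0.6, "care": 0.25},
            sigma2=_SIGMA2,
            lam=1.0,
            config=ScalarConfiguration(),
            predictor_rates={"care": (1.0, 0.5)},
            seed=seed,
            preset=preset_name,
        )
    elif preset_name == "recovery":
        tree = simulate_tree(100, "yule", tree_seed)
        cols = simulate_binary_traits(
            tree, gain_rate=1.2, loss_rate=0.6, n_traits=3, rng=rng, min_present=9
        )
        preds = pd.DataFrame(
            {f"pred_{j + 1}": cols[:, j] for j in range(3)}, index=tree.tip_labels
        )
        truth = GroundTruth(
            beta={INTERCEPT: 0.2, "pred_1": 0.2, "pred_2": 0.0, "pred_3": -0.3},
            sigma2=_SIGMA2,
            lam=0.9,
            config=ScalarConfiguration(),
            predictor_rates={f"pred_{j + 1}": (1.2, 0.6) for j in range(3)},
            seed=seed,
            preset=preset_name,
        )
    elif preset_name == "shift-attribution":
        tree = simulate_tree(100, "yule", tree_seed)
        node = _pick_shift_clade(tree)
        clade_tips = tree.tips_below[node, : tree.n_tips]
        body = simulate_bm_trait(tree, sigma2=0.1, root_value=1.5, rng=rng)
        preds = pd.DataFrame(
            {"body_size": body, "care": clade_tips.astype(int)},
            index=tree.tip_labels,
        )
        # the rate shift is generated by the predictor (a large trait jump
        # on the clade's founding lineage, where the care trait arose) on
        # top of an 8x scalar planted on that stem branch
        truth = GroundTruth(
            beta={INTERCEPT: 0.2, "body_size": 0.5, "care": 1.2},
            sigma2=_SIGMA2,
            lam=1.0,
            config=ScalarConfiguration({Placement(node, BRANCH): 8.0}),
            predictor_rates={},
            seed=seed,
            preset=preset_name,
            shift_clade_tips=tree.clade_tips(node),
        )
    else:  # paper-shape
        tree = simulate_tree(805, "yule", tree_seed)
        n = tree.n_tips
        cols = {}
        for name, count in PAPER_SHAPE_PREVALENCE.items():
            pi = count / 805.0
            total = 3.0
            cols[name] = simulate_binary_traits(
                tree,
                gain_rate=pi * total,
                loss_rate=(1 - pi) * total,
                rng=rng,
                target_count=count,
                target_tol=0.15,
            )[:, 0]
        body = simulate_bm_trait(tree, sigma2=0.1, root_value=1.6, rng=rng)
        clutch = simulate_bm_trait(tree, sigma2=0.15, root_value=2.0, rng=rng)
        preds = pd.DataFrame(
            {"body_size": body, "clutch_size": clutch, **cols},
            index=tree.tip_labels,
        )
        beta = {
            INTERCEPT: -0.6,
            "body_size": 0.5,
            "clutch_size": -0.2,
            "terrestrial_eggs": 0.08,
            "direct_development": 0.15,
            "egg_brooding": 0.2,
            "female_egg_attendance": 0.06,
            "male_egg_attendance": 0.08,
            "female_tadpole_attendance": -0.3,
            "tadpole_feeding": -0.17,
        }
        beta.update(
            {k: 0.0 for k in PAPER_SHAPE_PREVALENCE if k not in beta}
        )
        truth = GroundTruth(
            beta=beta,
            sigma2=_SIGMA2,
            lam=0.9,
            config=ScalarConfiguration(),
            predictor_rates={
                k: (PAPER_SHAPE_PREVALENCE[k] / 805.0 * 3.0,
                    (1 - PAPER_SHAPE_PREVALENCE[k] / 805.0) * 3.0)
                for k in PAPER_SHAPE_PREVALENCE
            },
            seed=seed,
            preset=preset_name,
        )

    table = simulate_continuous_traits(tree, preds, truth, rng=rng, response="egg_size")
    names = [c for c in table.columns if c != "egg_size"]
    X = np.column_stack(
        [np.ones(tree.n_tips)] + [table[c].to_numpy(dtype=float) for c in names]
    )
    dataset = AnalysisDataset(
        tree=tree,
        response="egg_size",
        y=table["egg_size"].to_numpy(dtype=float),
        X=X,
        names=[INTERCEPT, *names],
    )
    return dataset, truth


def hash_preset(name: str) -> int:
    """Stable small integer per preset name (order in the registry)."""
    return PRESETS.index(name) + 1


def write_dataset(dataset: AnalysisDataset, truth: GroundTruth, outdir) -> list[Path]:
    """Write tree (Newick), trait table (TSV) and ground truth (JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree_path = outdir / "tree.nwk"
    dataset.tree.write(tree_path)
    table = pd.DataFrame(
        {dataset.response: dataset.y},
        index=pd.Index(dataset.tree.tip_labels, name="species"),
    )
    for j, name in enumerate(dataset.names):
        if name == INTERCEPT:
            continue
        table[name] = dataset.X[:, j]
    traits_path = outdir / "traits.tsv"
    table.to_csv(traits_path, sep="\t", float_format="%.17g")
    truth_path = outdir / "truth.json"
    truth_path.write_text(truth.to_json() + "\n")
    return [tree_path, traits_path, truth_path]
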
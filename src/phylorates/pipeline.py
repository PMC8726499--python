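"""The full analysis: significance, model reduction, effect sizes, shifts.

A predictor's significance is Px — the fraction of its posterior on the
minority side of zero — with Px < 0.05 the significance bar. Backward
elimination removes the least significant predictor (largest Px) one at a
time, refitting until every remaining predictor clears the bar. Effect
sizes are changes in median stepping-stone log marginal likelihood when a
single predictor is removed from the reduced model, and for a binary
predictor on a log10 response the fitted coefficient translates to a
percentage change (10^beta - 1) * 100 in the response, present versus
absent (covariates cancel, so this is the change for a species of average
size by linearity in log space).

A branch shows an exceptional rate shift when its effective scalar exceeds
1 (or stays below 1) in at least 95% of posterior samples. Comparing the
flagged sets of a simple model (allometry + trade-off only) and the
reduced model attributes shifts: branches exceptional under the simple
model but not the reduced one are "explained" by the added predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import INTERCEPT, AnalysisDataset, TraitTable
from .diagnostics import ess
from .evidence import stepping_stone_logZ
from .mcmc import ChainSettings, PosteriorSamples, run_chain
from .priors import PriorSpec

__all__ = [
    "posterior_px",
    "significance_report",
    "subset_dataset",
    "backward_eliminate",
    "EliminationResult",
    "effect_size_delta_logZ",
    "percent_change",
    "percent_change_inverse",
    "detect_exceptional_branches",
    "RateShiftReport",
    "attribute_shifts",
    "AttributionSummary",
    "compute_vif",
]


# --------------------------------------------------------------------------- #
# significance


def posterior_px(beta_samples) -> float:
    """Fraction of the posterior on the minority side of zero.

    Exact zeros count on both sides, so Px is in [0, 0.5]; for continuous
    samples the distinction is measure-zero.
    """
    b = np.asarray(beta_samples, dtype=float).ravel()
    if b.size == 0:
        raise ValueError("empty posterior sample")
    # capped at 1/2: a tie-heavy sample (many exact zeros) straddles zero
    # completely, and both one-sided fractions can then exceed 1/2
    return float(min(np.mean(b <= 0), np.mean(b >= 0), 0.5))


def significance_report(
    samples: PosteriorSamples, hdi_prob: float = 0.95
) -> pd.DataFrame:
    """Per-coefficient posterior summary: mean, median, HPD interval, Px, ESS."""
    import arviz as az

    rows = []
    for j, name in enumerate(samples.names):
        b = samples.beta[:, j]
        lo, hi = az.hdi(b, hdi_prob=hdi_prob)
        rows.append(
            {
                "predictor": name,
                "mean": float(np.mean(b)),
                "median": float(np.median(b)),
                "hpd_lower": float(lo),
                "hpd_upper": float(hi),
                "px": posterior_px(b),
                "ess": ess(b),
            }
        )
    return pd.DataFrame(rows).set_index("predictor")


def subset_dataset(dataset: AnalysisDataset, predictors: list[str]) -> AnalysisDataset:
    """Restrict the design matrix to the named predictors (intercept kept)."""
    idx = [0] + [dataset.names.index(p) for p in predictors]
    return AnalysisDataset(
        tree=dataset.tree,
        response=dataset.response,
        y=dataset.y,
        X=dataset.X[:, idx],
        names=[INTERCEPT, *predictors],
    )


@dataclass
class EliminationResult:
    """Audit trail of a backward elimination."""

    reduced: list[str]
    steps: list[dict] = field(default_factory=list)  # removed, px, report per refit
    final_samples: PosteriorSamples | None = None


def backward_eliminate(
    dataset: AnalysisDataset,
    priors: PriorSpec | None = None,
    settings: ChainSettings | None = None,
    predictors: list[str] | None = None,
    locked: tuple[str, ...] = (),
    px_threshold: float = 0.05,
) -> EliminationResult:
    """Strict stepwise model reduction under the Px < threshold rule.

    At each step the single eliminable predictor with the largest Px is
    removed if Px >= threshold (ties broken toward the smaller absolute
    median coefficient, so the trail is deterministic) and the model is
    refit; ``locked`` predictors are never removed. Per-step chains derive
    their seeds from the settings seed.
    """
    priors = priors if priors is not None else PriorSpec()
    settings = settings if settings is not None else ChainSettings()
    current = list(predictors if predictors is not None else dataset.predictors)
    result = EliminationResult(reduced=current)
    step = 0
    while True:
        st = settings
        if settings.seed is not None:
            st = replace(settings, seed=settings.seed + 1000 * step)
        sub = subset_dataset(dataset, current)
        samples, _ = run_chain(sub, priors, st)
        report = significance_report(samples)
        eliminable = report.loc[[p for p in current if p not in locked]].copy()
        eliminable["_abs_median"] = eliminable["median"].abs()
        worst = eliminable.sort_values(["px", "_abs_median"], ascending=[False, True])
        result.steps.append(
            {"predictors": list(current), "report": report, "removed": None}
        )
        if len(eliminable) == 0 or worst["px"].iloc[0] < px_threshold:
            result.reduced = current
            result.final_samples = samples
            return result
        removed = worst.index[0]
        result.steps[-1]["removed"] = removed
        current = [p for p in current if p != removed]
        step += 1


# --------------------------------------------------------------------------- #
# effect sizes


def percent_change(median_beta: float) -> float:
    """Percentage change in a log10-scale response when a binary predictor
    flips from absent to present: (10^beta - 1) * 100."""
    return float((10.0 ** median_beta - 1.0) * 100.0)


def percent_change_inverse(pct: float) -> float:
    """Coefficient implied by a percentage change (inverse of
    :func:`percent_change`)."""
    return float(np.log10(1.0 + pct / 100.0))


def effect_size_delta_logZ(
    dataset: AnalysisDataset,
    reduced_predictors: list[str],
    priors: PriorSpec | None = None,
    settings: ChainSettings | None = None,
    n_stones: int = 16,
    n_replicates: int = 3,
    seed: int | None = None,
    reduced_samples: PosteriorSamples | None = None,
) -> pd.DataFrame:
    """Marginal-likelihood effect sizes for the reduced model.

    For each retained predictor, Delta = median logZ(reduced) - median
    logZ(reduced without that predictor) across ``n_replicates`` replicate
    stepping-stone estimates; larger Delta means a larger effect. Binary
    predictors also get the percentage-change translation of their median
    coefficient from ``reduced_samples`` (fitted here if not supplied).
    """
    priors = priors if priors is not None else PriorSpec()
    settings = settings if settings is not None else ChainSettings(
        n_iter=4000, burnin=1000, thin=2
    )
    rng = np.random.default_rng(seed)

    def median_logZ(predictors: list[str]) -> float:
        sub = subset_dataset(dataset, predictors)
        vals = []
        for _ in range(n_replicates):
            res = stepping_stone_logZ(
                sub, priors, settings, n_stones=n_stones,
                seed=int(rng.integers(2**31 - 1)),
            )
            vals.append(res.logZ)
        return float(np.median(vals))

    logZ_reduced = median_logZ(reduced_predictors)
    if reduced_samples is None:
        sub = subset_dataset(dataset, reduced_predictors)
        st = settings if seed is None else replace(settings, seed=seed)
        reduced_samples, _ = run_chain(sub, priors, st)
    medians = {
        n: float(np.median(reduced_samples.beta[:, j]))
        for j, n in enumerate(reduced_samples.names)
    }
    rows = []
    for p in reduced_predictors:
        delta = logZ_reduced - median_logZ([q for q in reduced_predictors if q != p])
        j = dataset.names.index(p)
        binary = set(np.unique(dataset.X[:, j])) <= {0.0, 1.0}
        rows.append(
            {
                "predictor": p,
                "delta_logZ": delta,
                "median_beta": medians[p],
                "percent_change": percent_change(medians[p]) if binary else np.nan,
            }
        )
    df = pd.DataFrame(rows).set_index("predictor")
    df.attrs["logZ_reduced"] = logZ_reduced
    return df


# --------------------------------------------------------------------------- #
# rate shifts


@dataclass
class RateShiftReport:
    """Per-branch posterior shift summary for one fitted model.

    ``table`` has one row per non-root branch: the posterior fraction of
    samples with effective scalar above/below 1 (a branch covered by no
    placement has scalar exactly 1 and counts on neither side), the median
    effective scalar, the branch's descendant tips, and the flag.
    """

    table: pd.DataFrame
    threshold: float
    tip_signature: tuple[str, ...]

    @property
    def flagged(self) -> pd.DataFrame:
        return self.table[self.table["direction"] != ""]

    def flagged_branches(self) -> set[frozenset]:
        """Branch identities (descendant tip sets) of flagged branches."""
        return {frozenset(t) for t in self.flagged["tips"]}

    @property
    def n_flagged(self) -> int:
        return int((self.table["direction"] != "").sum())


def detect_exceptional_branches(
    samples: PosteriorSamples, threshold: float = 0.95
) -> RateShiftReport:
    """Branches whose effective scalar departs from 1 in >= ``threshold``
    of the posterior (positive shifts above 1, negative below)."""
    tree = samples.tree
    rates = samples.branch_rates
    rows = []
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        r = rates[:, v]
        frac_gt = float(np.mean(r > 1.0))
        frac_lt = float(np.mean(r < 1.0))
        if frac_gt >= threshold:
            direction = "positive"
        elif frac_lt >= threshold:
            direction = "negative"
        else:
            direction = ""
        rows.append(
            {
                "node": v,
                "n_tips": int(tree.tips_below[v].sum()),
                "frac_above_1": frac_gt,
                "frac_below_1": frac_lt,
                "median_rate": float(np.median(r)),
                "direction": direction,
                "tips": tree.clade_tips(v),
            }
        )
    table = pd.DataFrame(rows).set_index("node")
    return RateShiftReport(
        table=table,
        threshold=threshold,
        tip_signature=tuple(sorted(tree.tip_labels)),
    )


@dataclass
class AttributionSummary:
    """Simple-vs-reduced shift attribution (which shifts the predictors explain)."""

    n_simple: int
    n_reduced: int
    n_explained: int
    explained: set[frozenset]
    percent_explained: float | None
    note: str = ""


def attribute_shifts(
    simple_report: RateShiftReport, reduced_report: RateShiftReport
) -> AttributionSummary:
    """Branches exceptional under the simple model but not the reduced one.

    Branch identity across the two (independently fitted, same-tree) models
    is the branch's descendant tip set. If the predictors added to the
    reduced model drive the rate heterogeneity, the reduced model should
    flag fewer branches; the difference set is "explained".
    """
    if simple_report.tip_signature != reduced_report.tip_signature:
        raise ValueError("shift reports come from different trees")
    simple = simple_report.flagged_branches()
    reduced = reduced_report.flagged_branches()
    explained = simple - reduced
    if simple:
        pct = 100.0 * len(explained) / len(simple)
        note = ""
    else:
        pct = None
        note = "no branches flagged in the simple model; percentage undefined"
    return AttributionSummary(
        n_simple=len(simple),
        n_reduced=len(reduced),
        n_explained=len(explained),
        explained=explained,
        percent_explained=pct,
        note=note,
    )


# --------------------------------------------------------------------------- #
# collinearity


def compute_vif(
    table: TraitTable | pd.DataFrame, predictors: list[str]
) -> pd.DataFrame:
    """Variance inflation factors from a non-phylogenetic regression.

    VIF_j = 1 / (1 - R^2_j) with R^2_j from an ordinary least-squares
    regression of predictor j on all the others plus an intercept. Flags
    at 5 (likely problematic) and 10 (very problematic); a perfectly
    collinear predictor is reported with infinite VIF and an error flag
    rather than raising.
    """
    import statsmodels.api as sm

    if isinstance(table, TraitTable):
        df = table.data
    else:
        df = table
    if len(predictors) < 2:
        raise ValueError("VIF needs at least two predictors")
    X = df[list(predictors)].to_numpy(dtype=float)
    if np.any(np.ptp(X, axis=0) == 0):
        const = [p for p, r in zip(predictors, np.ptp(X, axis=0)) if r == 0]
        raise ValueError(f"constant predictor columns: {const}")
    rows = []
    for j, name in enumerate(predictors):
        others = np.delete(X, j, axis=1)
        fit = sm.OLS(X[:, j], sm.add_constant(others)).fit()
        r2 = min(float(fit.rsquared), 1.0)
        if 1.0 - r2 < 1e-12:
            vif = np.inf
            error = "perfect collinearity"
        else:
            vif = 1.0 / (1.0 - r2)
            error = ""
        rows.append(
            {
                "predictor": name,
                "vif": vif,
                "likely_problematic": bool(vif > 5),
                "very_problematic": bool(vif > 10),
                "error": error,
            }
        )
    return pd.DataFrame(rows).set_index("predictor")
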
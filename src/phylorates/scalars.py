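"""Branch-specific rate scalars.

A variable-rates model decomposes the Brownian variance of a trait into a
global background rate and a set of positive multipliers ``r`` placed on
single branches or on whole clades. A branch's *effective* rate is the
product of its own single-branch scalar (if any) and every whole-clade
scalar placed on an ancestor whose clade covers it; a branch covered by no
placement evolves at exactly the background rate (effective scalar 1). A
clade placement covers the clade's stem branch as well as every branch
below it, so a clade placement on a tip is the same thing as a
single-branch placement there.

Multiplying each branch length by its effective scalar "stretches" fast
branches and "compresses" slow ones, turning rate heterogeneity back into
plain Brownian motion on a rescaled tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np

from .tree import Phylogeny

__all__ = ["Placement", "ScalarConfiguration", "TransformedTree", "apply_scalars"]

BRANCH = "branch"
CLADE = "clade"


@dataclass(frozen=True, order=True)
class Placement:
    """Location of one rate scalar: a node index plus a kind.

    ``kind == "branch"`` scales only the branch above ``node``;
    ``kind == "clade"`` scales that branch and every branch below it.
    """

    node: int
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in (BRANCH, CLADE):
            raise ValueError(f"unknown placement kind: {self.kind!r}")


class ScalarConfiguration:
    """An assignment of rate scalars to placements (the RJ-MCMC object).

    At most one scalar per (node, kind); all values strictly positive. The
    empty configuration is the constant-rate model. The root admits no
    placement: it has no branch, and a whole-clade scalar there would scale
    every branch and be exactly confounded with the background rate.
    """

    def __init__(self, placements: Mapping[Placement, float] | None = None) -> None:
        self._placements: dict[Placement, float] = {}
        if placements:
            for loc, r in placements.items():
                if not isinstance(loc, Placement):
                    loc = Placement(*loc)
                r = float(r)
                if not (r > 0) or not np.isfinite(r):
                    raise ValueError(f"scalar at {loc} must be positive, got {r}")
                if loc in self._placements:
                    raise ValueError(f"duplicate placement {loc}")
                self._placements[loc] = r

    def __len__(self) -> int:
        return len(self._placements)

    def __iter__(self) -> Iterator[tuple[Placement, float]]:
        return iter(sorted(self._placements.items()))

    def __eq__(self, other) -> bool:
        return isinstance(other, ScalarConfiguration) and (
            self._placements == other._placements
        )

    def items(self) -> Iterable[tuple[Placement, float]]:
        return self._placements.items()

    def validate(self, tree: Phylogeny) -> None:
        for loc in self._placements:
            if not (0 <= loc.node < tree.n_nodes):
                raise ValueError(f"placement references unknown node {loc.node}")
            if loc.node == tree.root:
                raise ValueError(
                    "no scalar may be placed at the root (confounded with the "
                    "background rate)"
                )
            if loc.kind == CLADE and loc.node < tree.n_tips:
                # permitted but identical to a branch placement; normalize
                raise ValueError(
                    "clade placements at tips are stored as branch placements"
                )

    def effective_log_rates(self, tree: Phylogeny) -> np.ndarray:
        """Per-node log effective scalar of the branch above each node."""
        self.validate(tree)
        log_r = np.zeros(tree.n_nodes)
        for loc, r in self._placements.items():
            if loc.kind == BRANCH:
                log_r[loc.node] += np.log(r)
            else:
                log_r[tree.clade_masks[loc.node]] += np.log(r)
        log_r[tree.root] = 0.0
        return log_r

    def effective_rates(self, tree: Phylogeny) -> np.ndarray:
        return np.exp(self.effective_log_rates(tree))

    def serialize(self) -> str:
        """Compact text form for trace files: ``node:kind:r;...``."""
        return ";".join(
            f"{loc.node}:{loc.kind}:{r:.17g}" for loc, r in sorted(self._placements.items())
        )

    @classmethod
    def deserialize(cls, text: str) -> "ScalarConfiguration":
        if not text.strip():
            return cls()
        out = {}
        for chunk in text.strip().split(";"):
            node, kind, r = chunk.split(":")
            out[Placement(int(node), kind)] = float(r)
        return cls(out)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ScalarConfiguration({dict(sorted(self._placements.items()))!r})"


@dataclass
class TransformedTree:
    """A tree with branch lengths stretched by effective rate scalars."""

    tree: Phylogeny
    lengths: np.ndarray  # per-node effective branch length

    def to_newick(self) -> str:
        """Newick of the rate-scaled tree (long branch = fast evolution)."""
        scaled = Phylogeny(
            self.tree.parent,
            self.lengths,
            self.tree.tip_labels,
            validate=False,
            children=self.tree.children,
        )
        return scaled.to_newick()


def apply_scalars(tree: Phylogeny, config: ScalarConfiguration) -> TransformedTree:
    """Stretch each branch by its effective scalar; the input is untouched."""
    rates = config.effective_rates(tree)
    return TransformedTree(tree=tree, lengths=tree.edge_length * rates)
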
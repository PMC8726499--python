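"""Rooted bifurcating time trees.

The phylogeny is the covariance scaffold of the whole analysis: under
Brownian motion the covariance between two species' trait values is the
shared root-to-tip path length, so the tree is held as flat arrays from
which that quantity can be assembled with a single matrix product.

Trees are read and written through :mod:`dendropy` (Newick and Nexus,
including the ``.trees`` Nexus dialect used by comparative-methods
software) and validated on construction: exactly one root, strictly
bifurcating, positive branch lengths everywhere except the optional root
stem, unique tip labels.
"""

from __future__ import annotations

from functools import cached_property
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = ["Phylogeny", "TreeValidationError", "read_tree"]


class TreeValidationError(ValueError):
    """Raised when a tree violates the analysis invariants."""


def _normalize_label(label: str) -> str:
    """Exact-match normalization: trim whitespace, spaces -> underscores."""
    return "_".join(str(label).strip().split())


class Phylogeny:
    """A rooted, strictly bifurcating tree with branch lengths.

    Nodes are indexed ``0 .. n_nodes-1`` with tips ``0 .. n_tips-1`` (in
    left-to-right traversal order, which is also the row order of every
    trait vector used against this tree) and internal nodes following in
    preorder; the root is index ``n_tips``.

    Parameters
    ----------
    parent
        Parent index per node; ``-1`` for the root.
    edge_length
        Length of the branch above each node; the root entry is ignored
        for covariance purposes (the root stem, if present in the source
        file, is recorded here but never used).
    tip_labels
        Species names of tips ``0 .. n_tips-1``.
    """

    def __init__(
        self,
        parent: Sequence[int],
        edge_length: Sequence[float],
        tip_labels: Sequence[str],
        validate: bool = True,
        children: Sequence[Sequence[int]] | None = None,
    ) -> None:
        self.parent = np.asarray(parent, dtype=np.intp)
        self.edge_length = np.asarray(edge_length, dtype=float)
        self.tip_labels = [str(t) for t in tip_labels]
        self.n_nodes = self.parent.size
        self.n_tips = len(self.tip_labels)
        self.root = int(np.flatnonzero(self.parent < 0)[0]) if self.n_nodes else -1
        if children is not None:
            # caller-supplied child order (keeps the rendered tree identical
            # to its source); must agree with the parent pointers
            self._children = [list(c) for c in children]
        else:
            self._children = [[] for _ in range(self.n_nodes)]
            for v in range(self.n_nodes):
                p = self.parent[v]
                if p >= 0:
                    self._children[p].append(v)
        if validate:
            self._validate()

    # ------------------------------------------------------------------ #
    # construction

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Phylogeny":
        seed = dtree.seed_node
        # preorder walk; tips take low indices in traversal order
        preorder = list(seed.preorder_iter())
        tips = [nd for nd in preorder if nd.is_leaf()]
        internals = [nd for nd in preorder if not nd.is_leaf()]
        index = {}
        for i, nd in enumerate(tips):
            index[id(nd)] = i
        for j, nd in enumerate(internals):
            index[id(nd)] = len(tips) + j

        n_nodes = len(preorder)
        parent = np.full(n_nodes, -1, dtype=np.intp)
        length = np.zeros(n_nodes, dtype=float)
        labels = []
        missing = []
        for nd in preorder:
            v = index[id(nd)]
            if nd.parent_node is not None:
                parent[v] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    missing.append(_dendropy_name(nd))
                else:
                    length[v] = float(nd.edge.length)
            elif nd.edge.length is not None:
                length[v] = float(nd.edge.length)  # root stem, ignored downstream
        if missing:
            raise TreeValidationError(
                f"branch lengths missing above nodes: {missing[:10]}"
            )
        for nd in tips:
            lab = nd.taxon.label if nd.taxon is not None else (nd.label or "")
            labels.append(_normalize_label(lab))
        children: list[list[int]] = [[] for _ in range(n_nodes)]
        for nd in preorder:
            children[index[id(nd)]] = [index[id(c)] for c in nd.child_nodes()]
        return cls(parent, length, labels, children=children)

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises many parser-specific errors
            raise TreeValidationError(f"could not parse newick: {exc}") from exc
        return cls.from_dendropy(dtree)

    # ------------------------------------------------------------------ #
    # validation

    def _validate(self) -> None:
        if self.n_nodes == 0:
            raise TreeValidationError("empty tree")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise TreeValidationError(f"expected exactly one root, found {roots.size}")
        seen = set()
        dups = sorted({t for t in self.tip_labels if t in seen or seen.add(t)})
        if dups:
            raise TreeValidationError(f"duplicate tip labels: {dups}")
        bad_arity = []
        for v in range(self.n_nodes):
            nc = len(self._children[v])
            if v < self.n_tips:
                if nc != 0:
                    raise TreeValidationError(f"tip index {v} has children")
            elif nc != 2:
                bad_arity.append(self.node_name(v))
        if bad_arity:
            raise TreeValidationError(
                f"tree is not strictly bifurcating; offending nodes: {bad_arity}"
            )
        nonroot = np.arange(self.n_nodes) != self.root
        bad_len = np.flatnonzero(nonroot & (self.edge_length <= 0))
        if bad_len.size:
            names = [self.node_name(int(v)) for v in bad_len[:10]]
            raise TreeValidationError(
                f"non-positive branch lengths above nodes: {names}"
            )

    # ------------------------------------------------------------------ #
    # structure

    @property
    def children(self) -> list[list[int]]:
        return self._children

    def is_tip(self, v: int) -> bool:
        return v < self.n_tips

    @cached_property
    def postorder(self) -> np.ndarray:
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self._children[v])
        return np.asarray(order[::-1], dtype=np.intp)

    @cached_property
    def path_matrix(self) -> np.ndarray:
        """Float (n_nodes, n_tips) indicator: node v lies on the root-to-tip
        path of tip i (equivalently tip i descends from v). The root row is
        zero — the root stem never enters the covariance."""
        below = self.tips_below
        B = below.astype(float)
        B[self.root, :] = 0.0
        return B

    @cached_property
    def tips_below(self) -> np.ndarray:
        """Bool (n_nodes, n_tips): tip i is in the clade of node v."""
        M = np.zeros((self.n_nodes, self.n_tips), dtype=bool)
        for v in self.postorder:
            if v < self.n_tips:
                M[v, v] = True
            else:
                for c in self._children[v]:
                    M[v] |= M[c]
        return M

    @cached_property
    def clade_masks(self) -> np.ndarray:
        """Bool (n_nodes, n_nodes): node u is in the subtree rooted at v
        (including v itself, i.e. including v's stem branch)."""
        M = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        for v in self.postorder:
            M[v, v] = True
            for c in self._children[v]:
                M[v] |= M[c]
        return M

    def clade_tips(self, v: int) -> tuple[str, ...]:
        """Sorted tip labels descending from node v (branch identity key)."""
        return tuple(sorted(self.tip_labels[i] for i in np.flatnonzero(self.tips_below[v])))

    def node_name(self, v: int) -> str:
        if v < self.n_tips:
            return self.tip_labels[v]
        tips = self.clade_tips(v)
        head = ",".join(tips[:3]) + ("..." if len(tips) > 3 else "")
        return f"mrca({head})[{len(tips)} tips]"

    def tip_depths(self, lengths: np.ndarray | None = None) -> np.ndarray:
        w = self.edge_length if lengths is None else np.asarray(lengths, float)
        return w @ self.path_matrix

    def patristic_distances(self) -> np.ndarray:
        """Pairwise tip-to-tip path lengths."""
        V = (self.path_matrix.T * self.edge_length) @ self.path_matrix
        d = np.diag(V)
        return d[:, None] + d[None, :] - 2.0 * V

    # ------------------------------------------------------------------ #
    # IO / manipulation

    def to_newick(self) -> str:
        def render(v: int) -> str:
            if v < self.n_tips:
                core = self.tip_labels[v]
            else:
                core = "(" + ",".join(render(c) for c in self._children[v]) + ")"
            if v == self.root:
                return core
            return f"{core}:{self.edge_length[v]:.17g}"

        import sys

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 10 * self.n_nodes + 100))
        try:
            return render(self.root) + ";"
        finally:
            sys.setrecursionlimit(old)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def to_dendropy(self) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.to_newick(), schema="newick", preserve_underscores=True
        )

    def prune_to(self, keep: Iterable[str]) -> tuple["Phylogeny", list[str]]:
        """Prune to the given tip labels.

        Degree-2 nodes created by pruning are collapsed by summing their two
        incident branch lengths. Returns the pruned tree and the sorted list
        of tips that were dropped.
        """
        keep = {_normalize_label(k) for k in keep}
        present = set(self.tip_labels)
        target = keep & present
        if not target:
            raise TreeValidationError("no overlap between tree tips and requested labels")
        dropped = sorted(present - target)
        if not dropped:
            return self, []
        dtree = self.to_dendropy()
        taxa = [t for t in dtree.taxon_namespace if _normalize_label(t.label) in target]
        dtree.retain_taxa(taxa)
        dtree.suppress_unifurcations()
        return Phylogeny.from_dendropy(dtree), dropped

    # ------------------------------------------------------------------ #

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny(n_tips={self.n_tips}, n_nodes={self.n_nodes})"


def _dendropy_name(nd: dendropy.Node) -> str:
    if nd.taxon is not None:
        return nd.taxon.label
    if nd.is_leaf():
        return nd.label or "<unnamed tip>"
    tips = [lf.taxon.label if lf.taxon else "?" for lf in nd.leaf_iter()]
    return "mrca(" + ",".join(tips[:3]) + ("...)" if len(tips) > 3 else ")")


def read_tree(path, format: str | None = None) -> Phylogeny:
    """Read a tree from Newick or Nexus.

    ``format`` may be ``"newick"``, ``"nexus"`` or ``None`` to guess from the
    file extension (``.nex``, ``.nexus`` and ``.trees`` are treated as Nexus).
    If the file holds several trees the first is used.
    """
    path = str(path)
    if format is None:
        lower = path.lower()
        format = (
            "nexus"
            if lower.endswith((".nex", ".nexus", ".trees"))
            else "newick"
        )
    if format not in ("newick", "nexus"):
        raise ValueError(f"unsupported tree format: {format!r}")
    try:
        trees = dendropy.TreeList.get(
            path=path, schema=format, preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises many parser-specific errors
        raise TreeValidationError(f"could not parse tree file {path}: {exc}") from exc
    if len(trees) == 0:
        raise TreeValidationError(f"no trees found in {path}")
    return Phylogeny.from_dendropy(trees[0])
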
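"""Trait tables and tree/table alignment.

A trait table carries one row per species: three continuous traits on
log10 scale (egg size in log10 mm, clutch size in log10 count, body length
in log10 mm in the motivating application) and any number of binary 0/1
predictors (parental-care forms, terrestrial eggs/larvae, direct
development). No missing values are allowed in any used column — the
analysis assumes a complete-case table.

``align_dataset`` joins a table to a tree by exact species-name match
(after trimming whitespace and normalizing spaces to underscores; no fuzzy
matching — a silent mis-join is worse than a dropped species), prunes the
tree to the intersection, and emits the design matrix in tip order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tree import Phylogeny, _normalize_label

__all__ = [
    "TraitTable",
    "AnalysisDataset",
    "DropReport",
    "read_traits",
    "align_dataset",
    "check_category_counts",
]


class TraitValidationError(ValueError):
    """Raised when a trait table violates the analysis invariants."""


@dataclass
class TraitTable:
    """Validated species-by-trait table.

    ``data`` is indexed by normalized species name; ``continuous`` and
    ``binary`` name the validated column groups.
    """

    data: pd.DataFrame
    continuous: list[str]
    binary: list[str]

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)


def read_traits(
    path,
    species_column: str = "species",
    continuous: tuple[str, ...] | list[str] = (),
    binary: tuple[str, ...] | list[str] = (),
    log10_transform: bool = False,
    column_map: dict[str, str] | None = None,
) -> TraitTable:
    """Read and validate a species-by-trait table.

    Accepts comma- or tab-delimited text (sniffed) and ``.xlsx``. Column
    names may be remapped via ``column_map`` (file name -> analysis name).
    ``log10_transform=True`` applies log10 to the continuous columns at read
    time — the single place the transform may happen, so it is never
    double-applied; values are otherwise taken to be on log10 scale already.
    """
    path = str(path)
    if path.lower().endswith((".xlsx", ".xls")):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep=None, engine="python")
    if column_map:
        df = df.rename(columns=column_map)
    return build_trait_table(
        df,
        species_column=species_column,
        continuous=list(continuous),
        binary=list(binary),
        log10_transform=log10_transform,
    )


def build_trait_table(
    df: pd.DataFrame,
    species_column: str = "species",
    continuous: list[str] | None = None,
    binary: list[str] | None = None,
    log10_transform: bool = False,
) -> TraitTable:
    """Validate an in-memory data frame into a :class:`TraitTable`."""
    df = df.copy()
    continuous = list(continuous or [])
    binary = list(binary or [])
    missing_cols = [
        c for c in [species_column, *continuous, *binary] if c not in df.columns
    ]
    if missing_cols:
        raise TraitValidationError(f"missing columns: {missing_cols}")

    df[species_column] = df[species_column].map(_normalize_label)
    dup = df[species_column][df[species_column].duplicated()].tolist()
    if dup:
        raise TraitValidationError(f"duplicate species rows: {sorted(set(dup))}")
    df = df.set_index(species_column)

    used = continuous + binary
    na = df[used].isna()
    if na.to_numpy().any():
        rows = df.index[na.any(axis=1)].tolist()
        raise TraitValidationError(f"missing values in rows: {rows[:10]}")

    for col in continuous:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.index[vals.isna()].tolist()
            raise TraitValidationError(f"non-numeric values in {col!r}: rows {bad[:10]}")
        df[col] = vals.astype(float)
        if log10_transform:
            if (df[col] <= 0).any():
                bad = df.index[df[col] <= 0].tolist()
                raise TraitValidationError(
                    f"non-positive values in {col!r} cannot be log10-transformed: "
                    f"rows {bad[:10]}"
                )
            df[col] = np.log10(df[col])
        if not np.isfinite(df[col]).all():
            bad = df.index[~np.isfinite(df[col])].tolist()
            raise TraitValidationError(f"non-finite values in {col!r}: rows {bad[:10]}")

    for col in binary:
        vals = pd.to_numeric(df[col], errors="coerce")
        ok = vals.isin([0, 1])
        if not ok.all():
            bad = df.index[~ok].tolist()
            raise TraitValidationError(
                f"non-binary entries in {col!r}: rows {bad[:10]} (values must be 0/1)"
            )
        df[col] = vals.astype(int)

    return TraitTable(data=df[used], continuous=continuous, binary=binary)


@dataclass
class DropReport:
    """Species lost on each side of a tree/table join."""

    dropped_from_tree: list[str] = field(default_factory=list)
    dropped_from_table: list[str] = field(default_factory=list)

    @property
    def any(self) -> bool:
        return bool(self.dropped_from_tree or self.dropped_from_table)


@dataclass
class AnalysisDataset:
    """Aligned, analysis-ready data: pruned tree + response + design.

    Rows of ``y`` and ``X`` follow the tree's tip order; ``X`` carries a
    leading intercept column and ``names`` the matching column names.
    """

    tree: Phylogeny
    response: str
    y: np.ndarray
    X: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, float)
        self.X = np.asarray(self.X, float)
        if self.X.shape != (self.tree.n_tips, len(self.names)):
            raise ValueError("design matrix shape does not match tree/names")
        if self.y.shape != (self.tree.n_tips,):
            raise ValueError("response length does not match tree")

    @property
    def predictors(self) -> list[str]:
        return self.names[1:]


INTERCEPT = "(Intercept)"


def align_dataset(
    tree: Phylogeny,
    traits: TraitTable,
    response: str,
    predictors: list[str],
) -> tuple[AnalysisDataset, DropReport]:
    """Join tree and table into an :class:`AnalysisDataset`.

    The tree is pruned to the species intersection (degree-2 nodes
    collapsed), table rows are reordered to tip order, and the design
    matrix is assembled as [intercept | predictors in the declared order].
    """
    table_species = set(traits.species)
    tree_species = set(tree.tip_labels)
    common = table_species & tree_species
    if not common:
        raise ValueError("tree and trait table share no species")
    report = DropReport(
        dropped_from_tree=sorted(tree_species - common),
        dropped_from_table=sorted(table_species - common),
    )
    pruned, _ = tree.prune_to(common)
    rows = traits.data.loc[pruned.tip_labels]
    for col in [response, *predictors]:
        if col not in rows.columns:
            raise KeyError(f"column {col!r} not in trait table")
    y = rows[response].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(rows))] + [rows[p].to_numpy(dtype=float) for p in predictors]
    )
    dataset = AnalysisDataset(
        tree=pruned,
        response=response,
        y=y,
        X=X,
        names=[INTERCEPT, *predictors],
    )
    return dataset, report


def check_category_counts(
    traits: TraitTable, min_present: int = 5
) -> pd.DataFrame:
    """Flag binary predictors too rare to analyse.

    A predictor is usable only when *more than* ``min_present`` species
    exhibit it (score 1); rarer predictors are flagged for exclusion.
    """
    rows = []
    for col in traits.binary:
        n_present = int(traits.data[col].sum())
        rows.append(
            {
                "predictor": col,
                "n_present": n_present,
                "flagged": n_present <= min_present,
            }
        )
    return pd.DataFrame(rows).set_index("predictor")
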
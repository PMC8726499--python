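import numpy as np
import pandas as pd
import pytest

from phylorates import (
    Phylogeny,
    align_dataset,
    build_trait_table,
    check_category_counts,
    read_traits,
)
from phylorates.data import TraitValidationError


def toy_frame():
    return pd.DataFrame(
        {
            "species": ["A", "B", "C"],
            "egg_size": [0.1, 0.4, 0.2],
            "clutch_size": [2.0, 1.5, 1.8],
            "care": [0, 1, 0],
        }
    )


class TestReading:
    def test_csv_roundtrip(self, tmp_path):
        path = tmp_path / "traits.csv"
        toy_frame().to_csv(path, index=False)
        t = read_traits(
            path, continuous=["egg_size", "clutch_size"], binary=["care"]
        )
        assert len(t) == 3
        assert t.species == ["A", "B", "C"]

    def test_tsv_sniffed(self, tmp_path):
        path = tmp_path / "traits.tsv"
        toy_frame().to_csv(path, sep="\t", index=False)
        t = read_traits(path, continuous=["egg_size"], binary=["care"])
        assert list(t.data["egg_size"]) == [0.1, 0.4, 0.2]

    def test_xlsx(self, tmp_path):
        path = tmp_path / "traits.xlsx"
        toy_frame().to_excel(path, index=False)
        t = read_traits(path, continuous=["egg_size"], binary=["care"])
        assert len(t) == 3

    def test_column_map(self, tmp_path):
        df = toy_frame().rename(columns={"egg_size": "Egg size (mm)"})
        path = tmp_path / "traits.csv"
        df.to_csv(path, index=False)
        t = read_traits(
            path,
            continuous=["egg_size"],
            binary=["care"],
            column_map={"Egg size (mm)": "egg_size"},
        )
        assert "egg_size" in t.data.columns


class TestValidation:
    def test_missing_column(self):
        with pytest.raises(TraitValidationError, match="missing columns"):
            build_trait_table(toy_frame(), continuous=["body_size"])

    def test_non_binary_entry_names_row_and_column(self):
        df = toy_frame()
        df.loc[1, "care"] = 2
        with pytest.raises(TraitValidationError, match=r"care.*B"):
            build_trait_table(df, binary=["care"])

    def test_missing_value_rejected(self):
        df = toy_frame()
        df.loc[2, "egg_size"] = np.nan
        with pytest.raises(TraitValidationError, match="missing values"):
            build_trait_table(df, continuous=["egg_size"])

    def test_log10_transform_applied_once(self):
        df = toy_frame()
        df["egg_size"] = [10.0, 100.0, 1.0]
        t = build_trait_table(df, continuous=["egg_size"], log10_transform=True)
        assert np.allclose(t.data["egg_size"], [1.0, 2.0, 0.0])

    def test_duplicate_species_rejected(self):
        df = pd.concat([toy_frame(), toy_frame().iloc[[0]]])
        with pytest.raises(TraitValidationError, match="duplicate"):
            build_trait_table(df, continuous=["egg_size"])


class TestAlignment:
    def tree4(self):
        return Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")

    def test_drop_from_tree_reported(self):
        table = build_trait_table(
            toy_frame(), continuous=["egg_size", "clutch_size"], binary=["care"]
        )
        ds, report = align_dataset(self.tree4(), table, "egg_size", ["care"])
        assert report.dropped_from_tree == ["D"]
        assert report.dropped_from_table == []
        assert ds.tree.n_tips == 3
        assert ds.names == ["(Intercept)", "care"]

    def test_row_order_matches_tip_order(self):
        df = toy_frame()
        df["species"] = ["C", "A", "B"]  # scrambled input order
        table = build_trait_table(df, continuous=["egg_size"], binary=["care"])
        tree = Phylogeny.from_newick("(A:2,(B:1,C:1):1);")
        ds, report = align_dataset(tree, table, "egg_size", ["care"])
        assert not report.any
        expect = {"C": 0.1, "A": 0.4, "B": 0.2}
        assert list(ds.y) == [expect[s] for s in ds.tree.tip_labels]

    def test_table_only_species_dropped(self):
        df = toy_frame()
        df.loc[len(df)] = ["Z", 0.3, 1.0, 1]
        table = build_trait_table(
            df, continuous=["egg_size", "clutch_size"], binary=["care"]
        )
        tree = Phylogeny.from_newick("(A:2,(B:1,C:1):1);")
        _, report = align_dataset(tree, table, "egg_size", ["care"])
        assert report.dropped_from_table == ["Z"]

    def test_empty_intersection_raises(self):
        table = build_trait_table(toy_frame(), continuous=["egg_size"])
        tree = Phylogeny.from_newick("(X:1,(Y:0.5,Z:0.5):0.5);")
        with pytest.raises(ValueError, match="no species"):
            align_dataset(tree, table, "egg_size", [])


class TestCategoryCounts:
    @pytest.mark.parametrize(
        "n_present, flagged", [(5, True), (6, False), (0, True)]
    )
    def test_min_present_boundary(self, n_present, flagged):
        n = 20
        df = pd.DataFrame(
            {
                "species": [f"s{i}" for i in range(n)],
                "care": [1] * n_present + [0] * (n - n_present),
            }
        )
        table = build_trait_table(df, binary=["care"])
        rep = check_category_counts(table, min_present=5)
        assert rep.loc["care", "n_present"] == n_present
        assert bool(rep.loc["care", "flagged"]) is flagged
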
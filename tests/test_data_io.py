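"""Dataset loading, median binarization, frequency tables, network formats."""

import numpy as np
import pytest

from anblearn import (Dataset, Structure, VariableSpec, build_cft,
                      discretize_median, load_dataset, read_edge_list,
                      read_network, write_edge_list, write_network)
from conftest import random_dataset


class TestLoadDataset:
    def test_rows_with_missing_marker_are_dropped(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("c,a\nyes,1\nno,2\nyes,?\nno,1\nyes,2\n")
        ds = load_dataset(p, "c")
        assert ds.n_rows == 4
        assert [v.name for v in ds.variables] == ["c", "a"]

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("c,a\n")
        with pytest.raises(ValueError, match="empty"):
            load_dataset(p, "c")

    def test_all_rows_missing_rejected(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("c,a\nyes,?\n?,1\n")
        with pytest.raises(ValueError, match="empty"):
            load_dataset(p, "c")

    def test_categorical_states_sorted_lexicographically(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("c,a\nx,a\ny,b\nx,a\n")
        ds = load_dataset(p, "c")
        assert ds.variables[1].states == ("a", "b")
        assert ds.rows[:, 1].tolist() == [1, 2, 1]

    def test_unknown_class_rejected(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("c,a\nx,1\ny,2\n")
        with pytest.raises(ValueError, match="unknown class"):
            load_dataset(p, "nope")

    def test_single_state_column_rejected(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("c,a\nx,1\ny,1\n")
        with pytest.raises(ValueError, match="cardinality"):
            load_dataset(p, "c")

    def test_continuous_column_binarized_and_deterministic(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("c,a\nx,1.0\ny,2.0\nx,3.0\ny,4.0\nx,5.0\n")
        ds1 = load_dataset(p, "c", continuous_columns=["a"])
        ds2 = load_dataset(p, "c", continuous_columns=["a"])
        assert ds1.rows[:, 1].tolist() == [1, 1, 1, 2, 2]
        assert np.array_equal(ds1.rows, ds2.rows)

    def test_class_index_follows_column_position(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("a,c\n1,x\n2,y\n")
        assert load_dataset(p, "c").class_index == 1


class TestDiscretizeMedian:
    @pytest.mark.parametrize("values,expected", [
        ([1, 2, 3, 4, 5], [1, 1, 1, 2, 2]),   # ties at the median go low
        ([0, 10], [1, 2]),
        ([3.5, -1.0, 3.5, 10.0], [1, 1, 1, 2]),
    ])
    def test_examples(self, values, expected):
        assert discretize_median(values).tolist() == expected

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            discretize_median([7, 7, 7])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            discretize_median([])


class TestBuildCft:
    def test_manual_tally(self, four_row_dataset):
        cft = build_cft(four_row_dataset, 1, (0,))
        assert cft.counts.tolist() == [[2, 1], [1, 0]]
        assert cft.marginals.tolist() == [3, 1]

    def test_empty_parent_set_is_marginal_table(self, four_row_dataset):
        jft = build_cft(four_row_dataset, 1, ())
        assert jft.counts.tolist() == [[3, 1]]
        assert jft.marginals.tolist() == [4]

    def test_empty_dataset_gives_all_zero_table(self):
        ds = Dataset([VariableSpec("a", ("1", "2")), VariableSpec("b", ("1", "2"))],
                     np.empty((0, 2)), 0)
        assert build_cft(ds, 0, (1,)).counts.sum() == 0

    def test_child_in_parents_rejected(self, four_row_dataset):
        with pytest.raises(ValueError):
            build_cft(four_row_dataset, 0, (0, 1))

    def test_count_conservation_on_random_fixtures(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            ds = random_dataset(rng, 4, int(rng.integers(0, 40)))
            child = int(rng.integers(0, 4))
            parents = tuple(p for p in range(4)
                            if p != child and rng.random() < 0.5)
            cft = build_cft(ds, child, parents)
            assert cft.counts.sum() == ds.n_rows
            assert np.array_equal(cft.marginals, cft.counts.sum(axis=1))

    def test_child_marginalization_matches_joint_of_parents(self):
        rng = np.random.default_rng(6)
        ds = random_dataset(rng, 3, 50)
        cft = build_cft(ds, 2, (0, 1))
        # independent tally of the parent configurations
        _, counts = np.unique(
            (ds.rows[:, 0] - 1) * ds.variables[1].cardinality + (ds.rows[:, 1] - 1),
            return_counts=True)
        direct = np.zeros(cft.q)
        uniq = np.unique((ds.rows[:, 0] - 1) * ds.variables[1].cardinality
                         + (ds.rows[:, 1] - 1))
        direct[uniq] = counts
        assert np.array_equal(cft.marginals, direct)


class TestNetworkFormats:
    def _tiny_model(self):
        from anblearn import NetworkModel
        structure = Structure((frozenset(), frozenset({0})), class_index=0)
        variables = [VariableSpec("X", ("a", "b")), VariableSpec("Y", ("u", "v"))]
        cpts = [np.array([[0.4, 0.6]]), np.array([[0.9, 0.1], [0.2, 0.8]])]
        return NetworkModel(structure=structure, variables=variables, cpts=cpts)

    def test_bif_round_trip(self, tmp_path):
        model = self._tiny_model()
        path = tmp_path / "m.bif"
        write_network(model, path)
        back = read_network(path)
        assert [v.name for v in back.variables] == ["X", "Y"]
        assert back.structure.parent_sets == model.structure.parent_sets
        for a, b in zip(back.cpts, model.cpts):
            assert np.allclose(a, b, atol=1e-9)

    def test_json_round_trip_keeps_class(self, tmp_path):
        model = self._tiny_model()
        path = tmp_path / "m.json"
        write_network(model, path)
        back = read_network(path)
        assert back.structure.class_index == 0
        for a, b in zip(back.cpts, model.cpts):
            assert np.allclose(a, b, atol=1e-12)

    def test_random_network_round_trip(self, tmp_path):
        from anblearn import random_discrete_network
        model = random_discrete_network(5, 2, cardinalities=[2, 3, 2, 2, 3], seed=9)
        path = tmp_path / "m.bif"
        write_network(model, path)
        back = read_network(path)
        assert back.structure.parent_sets == model.structure.parent_sets
        for a, b in zip(back.cpts, model.cpts):
            assert np.allclose(a, b, atol=1e-9)

    def test_unnormalized_cpt_rejected(self, tmp_path):
        path = tmp_path / "bad.bif"
        path.write_text(
            "network unknown {\n}\n"
            "variable X {\n  type discrete [ 2 ] { a, b };\n}\n"
            "probability ( X ) {\n  table 0.6, 0.6;\n}\n")
        with pytest.raises(ValueError, match="sum to 1"):
            read_network(path)

    def test_two_node_bif(self, tmp_path):
        path = tmp_path / "two.bif"
        path.write_text(
            "network unknown {\n}\n"
            "variable X {\n  type discrete [ 2 ] { a, b };\n}\n"
            "variable Y {\n  type discrete [ 2 ] { u, v };\n}\n"
            "probability ( X ) {\n  table 0.5, 0.5;\n}\n"
            "probability ( Y | X ) {\n  (a) 0.9, 0.1;\n  (b) 0.3, 0.7;\n}\n")
        model = read_network(path)
        assert model.structure.parent_sets[1] == frozenset({0})

    def test_edge_list_round_trip(self, tmp_path):
        g = Structure((frozenset(), frozenset({0}), frozenset({0, 1})))
        path = tmp_path / "g.edges"
        write_edge_list(g, path, ["a", "b", "c"])
        back = read_edge_list(path, ["a", "b", "c"])
        assert back.parent_sets == g.parent_sets
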
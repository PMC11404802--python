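"""Containers and text-format round trips."""

import math

import numpy as np
import pandas as pd
import pytest

from cliquebars import (
    Bar,
    Barcode,
    CohortManifest,
    WeightedNetwork,
    load_correlation_matrix,
    load_manifest,
    read_barcode,
    write_barcode,
    write_correlation_matrix,
    write_manifest,
)


class TestLoadCorrelationMatrix:
    def test_identity_matrix_gives_zero_weights(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("1,0,0\n0,1,0\n0,0,1\n")
        net = load_correlation_matrix(p)
        assert net.n_nodes == 3
        assert np.all(net.edge_weights() == 0.0)

    def test_two_node_single_edge(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("1,0.5\n0.5,1\n")
        net = load_correlation_matrix(p)
        assert net.n_nodes == 2
        assert net.delta_max == net.delta_min == 0.5

    def test_symmetrize_averages_with_transpose(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("1,0.5\n0.4,1\n")
        net = load_correlation_matrix(p, symmetrize=True)
        assert net.weights[0, 1] == pytest.approx(0.45, abs=1e-15)

    def test_asymmetry_without_flag_is_error(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("1,0.5\n0.4,1\n")
        with pytest.raises(ValueError, match="symmetr"):
            load_correlation_matrix(p)

    @pytest.mark.parametrize("sep", [",", "\t", " "])
    def test_delimiter_autodetected(self, tmp_path, sep):
        p = tmp_path / "m.txt"
        rows = [["1", "0.3", "0.2"], ["0.3", "1", "-0.1"], ["0.2", "-0.1", "1"]]
        p.write_text("\n".join(sep.join(r) for r in rows) + "\n")
        net = load_correlation_matrix(p)
        assert net.weights[1, 2] == -0.1

    def test_label_header_row(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("roiA,roiB\n1,0.5\n0.5,1\n")
        net = load_correlation_matrix(p)
        assert net.node_labels == ["roiA", "roiB"]

    def test_nonsquare_is_format_error(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("1,0.5,0.2\n0.5,1,0.1\n")
        with pytest.raises(ValueError, match="square"):
            load_correlation_matrix(p)

    def test_nan_entry_is_value_error(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("1,nan\nnan,1\n")
        with pytest.raises(ValueError, match="NaN|Inf"):
            load_correlation_matrix(p)

    def test_single_cell_matrix_rejected(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("1\n")
        with pytest.raises(ValueError, match="2x2"):
            load_correlation_matrix(p)

    def test_out_of_range_correlation_rejected(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("1,1.5\n1.5,1\n")
        with pytest.raises(ValueError, match=r"\[-1, 1\]"):
            load_correlation_matrix(p)

    def test_matrix_round_trip_exact(self, tmp_path, rng):
        w = rng.uniform(-1, 1, (7, 7))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        net = WeightedNetwork(w, subject_id="rt")
        write_correlation_matrix(net, tmp_path / "rt.csv")
        back = load_correlation_matrix(tmp_path / "rt.csv")
        assert np.abs(back.weights - net.weights).max() <= 1e-12


class TestManifest:
    def _write(self, tmp_path, rows):
        for r in rows:
            (tmp_path / r[-1]).write_text("1,0.5\n0.5,1\n")
        p = tmp_path / "manifest.csv"
        p.write_text(
            "subject_id,group,sex,age,matrix_path\n"
            + "\n".join(",".join(map(str, r)) for r in rows)
            + "\n"
        )
        return p

    def test_two_rows_one_per_group(self, tmp_path):
        p = self._write(tmp_path, [("s1", "control", 0, 15, "s1.csv"),
                                   ("s2", "case", 1, 16, "s2.csv")])
        m = load_manifest(p)
        assert len(m) == 2 and m.n_control == 1 and m.n_case == 1

    def test_isad_alias_maps_to_case(self, tmp_path):
        p = self._write(tmp_path, [("s1", "ISAD", 0, 15, "s1.csv"),
                                   ("s2", "HC", 1, 16, "s2.csv")])
        m = load_manifest(p)
        assert list(m.table["group"]) == ["case", "control"]

    def test_missing_matrix_names_subject(self, tmp_path):
        p = tmp_path / "manifest.csv"
        p.write_text("subject_id,group,sex,age,matrix_path\n"
                     "s9,control,0,15,absent.csv\n")
        with pytest.raises(FileNotFoundError, match="s9"):
            load_manifest(p)

    def test_duplicate_subject_id_rejected(self):
        df = pd.DataFrame(
            [("s1", "control", 0, 15, "a"), ("s1", "case", 1, 16, "b")],
            columns=["subject_id", "group", "sex", "age", "matrix_path"],
        )
        with pytest.raises(ValueError, match="duplicate"):
            CohortManifest(df)

    def test_unknown_group_label_rejected(self):
        df = pd.DataFrame(
            [("s1", "weird", 0, 15, "a")],
            columns=["subject_id", "group", "sex", "age", "matrix_path"],
        )
        with pytest.raises(ValueError, match="group"):
            CohortManifest(df)

    def test_unparseable_age_rejected(self):
        df = pd.DataFrame(
            [("s1", "control", 0, "teen", "a")],
            columns=["subject_id", "group", "sex", "age", "matrix_path"],
        )
        with pytest.raises(ValueError, match="age"):
            CohortManifest(df)

    def test_round_trip(self, tmp_path):
        p = self._write(tmp_path, [("s1", "control", 0, 15, "s1.csv"),
                                   ("s2", "case", 1, 16.5, "s2.csv")])
        m = load_manifest(p)
        write_manifest(m, tmp_path / "out.csv")
        m2 = load_manifest(tmp_path / "out.csv", resolve_paths=False)
        pd.testing.assert_frame_equal(m.table.drop(columns="matrix_path"),
                                      m2.table.drop(columns="matrix_path"))


class TestBarcodeFile:
    def test_single_essential_bar(self, tmp_path):
        bc = Barcode("s", [Bar(0, 0.0, math.inf)])
        write_barcode(bc, tmp_path / "b.csv")
        lines = (tmp_path / "b.csv").read_text().splitlines()
        assert lines == ["dim,birth,death", "0,0,inf"]

    def test_empty_barcode_header_only(self, tmp_path):
        write_barcode(Barcode("s", []), tmp_path / "b.csv")
        assert (tmp_path / "b.csv").read_text() == "dim,birth,death\n"

    def test_round_trip_is_identity(self, tmp_path, rng):
        bars = []
        for _ in range(50):
            birth = rng.uniform(0, 0.9)
            death = birth + rng.uniform(1e-6, 0.1)
            bars.append(Bar(int(rng.integers(0, 2)), birth, death))
        bars += [Bar(0, 0.0, math.inf), Bar(1, 0.25, math.inf),
                 Bar(0, 0.0, 0.5), Bar(0, 0.0, 0.5)]  # duplicates kept
        bc = Barcode("s", bars)
        write_barcode(bc, tmp_path / "b.csv")
        back = read_barcode(tmp_path / "b.csv", subject_id="s")
        assert back.as_multiset() == bc.as_multiset()


def test_network_rejects_sub_two_nodes():
    with pytest.raises(ValueError):
        WeightedNetwork(np.array([[1.0]]))


def test_network_kills_subtolerance_asymmetry():
    w = np.array([[0.0, 0.3], [0.3 + 1e-14, 0.0]])
    net = WeightedNetwork(w)
    assert net.weights[0, 1] == net.weights[1, 0]
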
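"""Readers/writers: parsing contracts, probe collapsing, network dedup,
GMT/JSON round-trips."""

import json

import networkx as nx
import numpy as np
import pytest

import netmark as nm
from netmark.errors import (
    EmptyResultError,
    FormatError,
    LabeledDataError,
    ParseError,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text, encoding="utf-8")
    return p


EXPR = "id\ts1\ts2\ts3\ts4\ngA\t1\t2\t3\t4\ngB\t4\t3\t2\t1\ngC\t0.5\t0.5\t1.5\t1.5\n"
LABELS = "s1\tcase\ns2\tcase\ns3\tcontrol\ns4\tcontrol\n"


class TestReadExpression:
    def test_basic_parse(self, tmp_path):
        ds = nm.read_expression(
            _write(tmp_path, "e.tsv", EXPR), _write(tmp_path, "l.tsv", LABELS)
        )
        assert ds.values.shape == (3, 4)
        assert ds.gene_ids == ("gA", "gB", "gC")
        assert set(ds.labels.values()) == {"case", "control"}

    def test_geo_banner_lines_skipped(self, tmp_path):
        ds = nm.read_expression(
            _write(tmp_path, "e.tsv", "!Series_title\tfoo\n" + EXPR),
            _write(tmp_path, "l.tsv", LABELS),
        )
        assert ds.n_genes == 3

    def test_missing_label_rejected(self, tmp_path):
        bad = "s1\tcase\ns2\tcase\ns3\tcontrol\n"  # s4 unlabeled
        with pytest.raises(LabeledDataError):
            nm.read_expression(
                _write(tmp_path, "e.tsv", EXPR), _write(tmp_path, "l.tsv", bad)
            )

    def test_non_numeric_cell_reports_coordinates(self, tmp_path):
        broken = EXPR.replace("3\t2", "3\toops")
        with pytest.raises(ParseError, match="oops.*'gB'.*'s3'"):
            nm.read_expression(
                _write(tmp_path, "e.tsv", broken), _write(tmp_path, "l.tsv", LABELS)
            )

    def test_duplicate_sample_id_rejected(self, tmp_path):
        dup = EXPR.replace("s1\ts2", "s1\ts1")
        with pytest.raises(FormatError, match="duplicate sample"):
            nm.read_expression(
                _write(tmp_path, "e.tsv", dup), _write(tmp_path, "l.tsv", LABELS)
            )

    def test_nan_rejected(self, tmp_path):
        bad = EXPR.replace("0.5\t0.5", "nan\t0.5")
        with pytest.raises(FormatError, match="non-finite"):
            nm.read_expression(
                _write(tmp_path, "e.tsv", bad), _write(tmp_path, "l.tsv", LABELS)
            )

    def test_roundtrip_identity(self, tmp_path, tiny_ds):
        nm.write_expression(tiny_ds, tmp_path / "e.tsv", tmp_path / "l.tsv")
        back = nm.read_expression(tmp_path / "e.tsv", tmp_path / "l.tsv")
        assert back.gene_ids == tiny_ds.gene_ids
        assert back.sample_ids == tiny_ds.sample_ids
        assert dict(back.labels) == dict(tiny_ds.labels)
        np.testing.assert_array_equal(back.values, tiny_ds.values)


class TestCollapseProbes:
    def test_two_probes_average(self):
        ds = nm.ExpressionDataset(
            gene_ids=("p1", "p2"),
            sample_ids=("s1", "s2"),
            values=np.array([[2.0, 10.0], [4.0, 20.0]]),
            labels={"s1": "case", "s2": "control"},
        )
        ann = nm.AnnotationTable({"p1": "G", "p2": "G"})
        out = nm.collapse_probes(ds, ann)
        assert out.gene_ids == ("G",)
        np.testing.assert_allclose(out.values, [[3.0, 15.0]])

    def test_bijective_mapping_renames_only(self, tiny_ds):
        ann = nm.AnnotationTable({"gA": "E1", "gB": "E2", "gC": "E3"})
        out = nm.collapse_probes(tiny_ds, ann)
        assert out.gene_ids == ("E1", "E2", "E3")
        np.testing.assert_array_equal(out.values, tiny_ds.values)

    def test_grouped_mean_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=(5, 6))
        samples = tuple(f"s{i}" for i in range(6))
        labels = {s: ("case" if i < 3 else "control") for i, s in enumerate(samples)}
        ds = nm.ExpressionDataset(
            gene_ids=tuple(f"p{i}" for i in range(5)),
            sample_ids=samples,
            values=values,
            labels=labels,
        )
        ann = nm.AnnotationTable(
            {"p0": "GA", "p1": "GA", "p2": "GA", "p3": "GB", "p4": "GB"}
        )
        out, report = nm.collapse_probes(ds, ann, return_report=True)
        assert out.n_genes == 2 and report["n_dropped_unmapped"] == 0
        np.testing.assert_allclose(out.values[0], values[:3].mean(axis=0))
        np.testing.assert_allclose(out.values[1], values[3:].mean(axis=0))
        # column sums equal sums of per-gene probe means
        np.testing.assert_allclose(
            out.values.sum(axis=0),
            values[:3].mean(axis=0) + values[3:].mean(axis=0),
        )

    def test_unmapped_probes_dropped_and_counted(self, tiny_ds):
        ann = nm.AnnotationTable({"gA": "E1"})
        out, report = nm.collapse_probes(tiny_ds, ann, return_report=True)
        assert out.gene_ids == ("E1",)
        assert report["n_dropped_unmapped"] == 2

    def test_empty_intersection_raises(self, tiny_ds):
        with pytest.raises(EmptyResultError):
            nm.collapse_probes(tiny_ds, nm.AnnotationTable({"px": "E1"}))


class TestReadNetwork:
    def test_dedup_and_self_loop(self, tmp_path):
        net = nm.read_network(_write(tmp_path, "n.tsv", "A\tB\nB\tA\nA\tA\n"))
        assert net.n_nodes == 2 and net.n_edges == 1

    def test_path_graph_degrees(self, tmp_path):
        net = nm.read_network(_write(tmp_path, "n.tsv", "A\tB\nB\tC\nC\tD\n"))
        degs = sorted(dict(net.graph.degree()).values())
        assert degs == [1, 1, 2, 2]

    def test_random_duplicates_vs_set_oracle(self, tmp_path):
        rng = np.random.default_rng(3)
        nodes = [f"n{i}" for i in range(12)]
        edges = []
        while len(edges) < 40:
            u, v = rng.choice(nodes, 2, replace=False)
            edges.append((str(u), str(v)))
        edges += edges[:10]  # duplicates
        rng.shuffle(edges)
        text = "\n".join(f"{u}\t{v}" for u, v in edges) + "\n"
        net = nm.read_network(_write(tmp_path, "n.tsv", text))
        oracle = {frozenset(e) for e in edges if e[0] != e[1]}
        assert net.edge_set() == oracle

    def test_sif_multi_target(self, tmp_path):
        net = nm.read_network(_write(tmp_path, "n.sif", "A pp B C\nB pp D\n"))
        assert net.edge_set() == {
            frozenset({"A", "B"}),
            frozenset({"A", "C"}),
            frozenset({"B", "D"}),
        }

    def test_reserialization_idempotent(self, tmp_path):
        g = nx.gnp_random_graph(15, 0.25, seed=5)
        g = nx.relabel_nodes(g, {i: f"x{i}" for i in range(15)})
        net = nm.InteractionNetwork(graph=g)
        nm.write_network(net, tmp_path / "n.tsv")
        back = nm.read_network(tmp_path / "n.tsv")
        assert back.nodes == net.nodes
        assert back.edge_set() == net.edge_set()

    def test_empty_and_malformed(self, tmp_path):
        with pytest.raises(FormatError):
            nm.read_network(_write(tmp_path, "e.tsv", "\n\n"))
        with pytest.raises(ParseError, match="line 2"):
            nm.read_network(_write(tmp_path, "m.tsv", "A\tB\nloner\n"))


class TestSubnetworkIO:
    def _set(self, n):
        subs = [
            nm.Subnetwork(
                seed=f"g{i}",
                members=frozenset({f"g{i}", f"g{i}x", f"g{i}y"}),
                score=0.5 + i / 100,
                p_gene_null=0.01,
                p_label_null=0.02,
                p_random_null=0.03,
                frequency=i,
            )
            for i in range(n)
        ]
        return nm.SubnetworkSet(subnetworks=subs, metadata={"run": "t"})

    def test_gmt_line_per_subnetwork_with_members(self, tmp_path):
        nm.write_subnetworks(self._set(1), tmp_path / "s.gmt", tmp_path / "s.json")
        line = (tmp_path / "s.gmt").read_text().strip().split("\t")
        assert len(line) == 2 + 3  # name, description, 3 members

    def test_nineteen_subnetworks_nineteen_lines(self, tmp_path):
        nm.write_subnetworks(self._set(19), tmp_path / "s.gmt", tmp_path / "s.json")
        assert len((tmp_path / "s.gmt").read_text().strip().splitlines()) == 19

    def test_json_roundtrip_lossless(self, tmp_path):
        sset = self._set(4)
        nm.write_subnetworks(sset, tmp_path / "s.gmt", tmp_path / "s.json")
        back = nm.read_subnetworks(tmp_path / "s.json")
        assert back.subnetworks == sset.subnetworks
        assert back.metadata == sset.metadata

    def test_empty_set_warns_but_writes(self, tmp_path, caplog):
        nm.write_subnetworks(
            nm.SubnetworkSet(subnetworks=[]), tmp_path / "s.gmt", tmp_path / "s.json"
        )
        assert (tmp_path / "s.gmt").read_text() == ""
        assert json.loads((tmp_path / "s.json").read_text())["subnetworks"] == []


class TestQuantileNormalize:
    def test_columns_share_distribution(self):
        rng = np.random.default_rng(0)
        ds = nm.ExpressionDataset(
            gene_ids=tuple(f"g{i}" for i in range(50)),
            sample_ids=("a", "b", "c"),
            values=rng.normal(size=(50, 3)) * [1, 5, 10] + [0, 3, -2],
            labels={"a": "case", "b": "case", "c": "control"},
        )
        out = nm.quantile_normalize(ds)
        ref = np.sort(out.values[:, 0])
        for j in (1, 2):
            np.testing.assert_allclose(np.sort(out.values[:, j]), ref, atol=1e-9)

    def test_ties_get_mean_of_tied_quantiles(self):
        ds = nm.ExpressionDataset(
            gene_ids=("g1", "g2", "g3"),
            sample_ids=("a", "b"),
            values=np.array([[1.0, 5.0], [1.0, 2.0], [3.0, 8.0]]),
            labels={"a": "case", "b": "control"},
        )
        out = nm.quantile_normalize(ds)
        # column a has a tie at rank (1,2): both rows get the same value
        assert out.values[0, 0] == out.values[1, 0]
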
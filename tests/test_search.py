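"""Core search machinery: z-scoring, activity, mutual information, greedy
expansion, and the permutation filter's contracts."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import netmark as nm
from netmark.errors import ConfigError, ContractError, IntegrationError
from tests.conftest import make_two_class_ds


def plugin_mi_oracle(table) -> float:
    """Direct evaluation of the plug-in MI formula on a joint count table."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    mi = 0.0
    for b in range(table.shape[0]):
        for c in range(table.shape[1]):
            p = table[b, c] / n
            if p > 0:
                pb = table[b, :].sum() / n
                pc = table[:, c].sum() / n
                mi += p * math.log2(p / (pb * pc))
    return mi


class TestZScore:
    def test_row_standardized(self):
        ds = make_two_class_ds(1, 2, 1, seed=1)
        dsz = nm.zscore_normalize(ds)
        row = dsz.values[0]
        assert abs(row.mean()) < 1e-12
        assert abs(row.std(ddof=1) - 1.0) < 1e-12

    def test_constant_row_zeroed(self):
        ds = nm.ExpressionDataset(
            gene_ids=("g1", "g2"),
            sample_ids=("a", "b", "c"),
            values=np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]]),
            labels={"a": "case", "b": "case", "c": "control"},
        )
        dsz = nm.zscore_normalize(ds)
        np.testing.assert_array_equal(dsz.values[0], 0.0)

    def test_random_matrix_recomputation(self):
        ds = make_two_class_ds(20, 5, 5, seed=4)
        dsz = nm.zscore_normalize(ds)
        assert np.all(np.abs(dsz.values.mean(axis=1)) < 1e-12)
        assert np.all(np.abs(dsz.values.std(axis=1, ddof=1) - 1.0) < 1e-12)


class TestActivity:
    def test_singleton_identity(self):
        ds = nm.zscore_normalize(make_two_class_ds(3, 3, 3, seed=2))
        np.testing.assert_array_equal(nm.activity(ds, ["g001"]), ds.values[1])

    def test_opposite_zscores_cancel(self):
        ds = nm.ExpressionDataset(
            gene_ids=("u", "d"),
            sample_ids=("a", "b"),
            values=np.array([[1.0, -1.0], [-1.0, 1.0]]),
            labels={"a": "case", "b": "control"},
        )
        np.testing.assert_allclose(nm.activity(ds, ["u", "d"]), [0.0, 0.0])

    def test_mean_matches_bruteforce(self):
        ds = nm.zscore_normalize(make_two_class_ds(8, 4, 4, seed=3))
        members = ["g000", "g002", "g004", "g006", "g007"]
        idx = [int(m[1:]) for m in members]
        np.testing.assert_allclose(
            nm.activity(ds, members), ds.values[idx].mean(axis=0)
        )

    def test_oriented_mean_aligns_directions(self):
        # one up- and one down-shifted gene: plain mean cancels, oriented adds
        ds = nm.zscore_normalize(
            make_two_class_ds(2, 10, 10, effects={0: 3.0, 1: -3.0}, seed=5)
        )
        plain = nm.activity(ds, ["g000", "g001"], mode="mean")
        oriented = nm.activity(ds, ["g000", "g001"], mode="oriented_mean")
        y = ds.class_indicator().astype(bool)
        assert abs(plain[y].mean() - plain[~y].mean()) < 0.5
        assert oriented[y].mean() - oriented[~y].mean() > 1.5

    def test_unknown_gene_rejected(self, tiny_ds):
        with pytest.raises(ContractError):
            nm.activity(tiny_ds, ["nope"])


class TestMutualInformation:
    def test_perfect_association_one_bit(self):
        act = np.array([0.0, 0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1.0])
        labels = ["case"] * 4 + ["control"] * 4
        assert nm.mutual_information(act, labels, n_bins=2) == pytest.approx(1.0)

    def test_constant_activity_zero(self):
        assert nm.mutual_information(
            np.zeros(6), ["case"] * 3 + ["control"] * 3, n_bins=4
        ) == 0.0

    def test_hand_table(self):
        # joint counts {(b0,case)=3,(b0,ctrl)=1,(b1,case)=1,(b1,ctrl)=3}
        act = np.array([0, 0, 0, 1, 0, 1, 1, 1], dtype=float)
        labels = ["case"] * 4 + ["control"] * 4
        expected = plugin_mi_oracle([[3, 1], [1, 3]])
        assert nm.mutual_information(act, labels, 2) == pytest.approx(expected)
        assert expected == pytest.approx(0.75 * math.log2(1.5) - 0.25)

    def test_single_class_rejected(self):
        with pytest.raises(ContractError):
            nm.mutual_information(np.arange(4.0), ["case"] * 4, 2)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        acts=st.lists(st.floats(-5, 5, allow_nan=False), min_size=4, max_size=30),
        n_bins=st.integers(2, 8),
        data=st.data(),
    )
    def test_bounded_by_label_entropy_and_nonnegative(self, acts, n_bins, data):
        n = len(acts)
        n_case = data.draw(st.integers(1, n - 1))
        labels = ["case"] * n_case + ["control"] * (n - n_case)
        mi = nm.mutual_information(np.array(acts), labels, n_bins)
        p = n_case / n
        h = -(p * math.log2(p) + (1 - p) * math.log2(1 - p))
        assert -1e-12 <= mi <= h + 1e-9


def exhaustive_best_mi(ds_z, net, seed, max_size, n_bins, mode):
    """Enumerate every connected subgraph containing ``seed`` (<= max_size)
    and return the best MI; independent connectivity check via BFS."""
    nodes = sorted(set(ds_z.gene_ids) & net.nodes)
    adj = {u: set(net.graph.neighbors(u)) & set(nodes) for u in nodes}

    def connected(sub):
        start = next(iter(sub))
        seen = {start}
        stack = [start]
        while stack:
            for v in adj[stack.pop()] & sub:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return seen == sub

    others = [n for n in nodes if n != seed]
    best = -1.0
    for r in range(0, min(max_size, len(nodes))):
        for combo in itertools.combinations(others, r):
            sub = frozenset(combo) | {seed}
            if not connected(set(sub)):
                continue
            act = nm.activity(ds_z, sub, mode=mode)
            labels = [ds_z.labels[s] for s in ds_z.sample_ids]
            best = max(best, nm.mutual_information(act, labels, n_bins))
    return best


class TestGreedySearch:
    def test_isolated_seed_singleton(self):
        ds = nm.zscore_normalize(make_two_class_ds(3, 4, 4, seed=1))
        g = nx.Graph()
        g.add_nodes_from(["g000", "g001"])
        g.add_edge("g001", "g002")
        net = nm.InteractionNetwork(graph=g)
        cfg = nm.SearchConfig()
        sub = nm.greedy_search("g000", ds, net, cfg)
        assert sub.members == frozenset({"g000"})
        labels = [ds.labels[s] for s in ds.sample_ids]
        expected = nm.mutual_information(
            nm.activity(ds, ["g000"]), labels, cfg.resolve_n_bins(8)
        )
        assert sub.score == pytest.approx(expected)

    def test_pair_signal_path_graph(self):
        # A alone is uninformative, A+B jointly separate perfectly; C is noise.
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        e = np.array([-1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0])
        rng = np.random.default_rng(0)
        values = np.vstack([e, 2 * y - e, rng.normal(size=8)])
        ds = nm.ExpressionDataset(
            gene_ids=("A", "B", "C"),
            sample_ids=tuple(f"s{i}" for i in range(8)),
            values=values,
            labels={
                f"s{i}": ("control" if i < 4 else "case") for i in range(8)
            },
        )
        dsz = nm.zscore_normalize(ds)
        g = nx.Graph([("A", "B"), ("B", "C")])
        net = nm.InteractionNetwork(graph=g)
        cfg = nm.SearchConfig()
        sub = nm.greedy_search("A", dsz, net, cfg)
        assert sub.members == frozenset({"A", "B"})
        best = exhaustive_best_mi(
            dsz, net, "A", cfg.max_subnetwork_size,
            cfg.resolve_n_bins(8), cfg.activity_mode,
        )
        assert sub.score == pytest.approx(best)

    @pytest.mark.parametrize("trial", range(12))
    def test_greedy_bounded_by_exhaustive(self, trial):
        rng = np.random.default_rng(100 + trial)
        n_nodes = int(rng.integers(4, 9))
        g = nx.gnp_random_graph(n_nodes, 0.45, seed=int(rng.integers(1 << 30)))
        g = nx.relabel_nodes(g, {i: f"g{i:03d}" for i in range(n_nodes)})
        net = nm.InteractionNetwork(graph=g)
        ds = nm.zscore_normalize(
            make_two_class_ds(n_nodes, 8, 8, seed=200 + trial)
        )
        cfg = nm.SearchConfig(max_subnetwork_size=n_nodes)
        seed = "g000"
        sub = nm.greedy_search(seed, ds, net, cfg)
        best = exhaustive_best_mi(
            ds, net, seed, n_nodes, cfg.resolve_n_bins(16), cfg.activity_mode
        )
        assert sub.score <= best + 1e-12

    def test_invariants_on_random_inputs(self):
        for trial in range(10):
            cfg_s = nm.SyntheticConfig(n_genes=40, n_case=10, n_control=10,
                                       seed=trial, module_size=3)
            net, truth, ds = nm.simulate(cfg_s)
            cfg = nm.SearchConfig(max_subnetwork_size=4)
            res = nm.search_all_seeds(ds, net, cfg)
            for sub in res.subnetworks:
                assert sub.size <= 4
                assert net.is_connected_subset(sub.members)
                assert sub.seed in sub.members

    def test_seed_not_in_network_rejected(self, tiny_ds):
        net = nm.InteractionNetwork(graph=nx.Graph([("x", "y")]))
        with pytest.raises(ContractError):
            nm.greedy_search("gA", nm.zscore_normalize(tiny_ds), net, nm.SearchConfig())


class TestSearchAllSeeds:
    def test_one_candidate_per_shared_gene(self):
        cfg_s = nm.SyntheticConfig(n_genes=30, n_case=6, n_control=6, seed=2,
                                   module_size=2)
        net, truth, ds = nm.simulate(cfg_s)
        res = nm.search_all_seeds(ds, net, nm.SearchConfig())
        assert len(res) == 30  # one per network protein measured

    def test_partial_overlap_counts_shared_only(self):
        ds = make_two_class_ds(6, 5, 5, seed=3)
        g = nx.path_graph(4)
        g = nx.relabel_nodes(g, {0: "g000", 1: "g001", 2: "g002", 3: "zzz"})
        net = nm.InteractionNetwork(graph=g)
        res = nm.search_all_seeds(ds, net, nm.SearchConfig())
        assert len(res) == 3

    def test_disjoint_gene_sets_rejected(self):
        ds = make_two_class_ds(4, 5, 5, seed=1)
        net = nm.InteractionNetwork(graph=nx.Graph([("x", "y")]))
        with pytest.raises(IntegrationError):
            nm.search_all_seeds(ds, net, nm.SearchConfig())

    def test_determinism_bit_identical(self):
        cfg_s = nm.SyntheticConfig(n_genes=40, n_case=10, n_control=10, seed=5)
        net, truth, ds = nm.simulate(cfg_s)
        cfg = nm.SearchConfig(rng_seed=3)
        a = nm.search_all_seeds(ds, net, cfg)
        b = nm.search_all_seeds(ds, net, cfg)
        assert a.subnetworks == b.subnetworks


class TestPermutationFilter:
    def test_too_few_permutations_rejected(self):
        cfg_s = nm.SyntheticConfig(n_genes=10, n_case=10, n_control=10, seed=1)
        net, truth, ds = nm.simulate(cfg_s)
        cfg = nm.SearchConfig(n_permutations=10, alpha=0.05)
        cands = nm.search_all_seeds(ds, net, cfg)
        with pytest.raises(ConfigError, match="cannot reach alpha"):
            nm.permutation_filter(cands, ds, net, cfg)

    def test_planted_strong_module_retained(self):
        hits = 0
        for seed in range(10):
            cfg_s = nm.SyntheticConfig(
                n_genes=60, n_case=25, n_control=25, effect_size=3.0,
                module_size=4, connector_fraction=0.0, seed=seed,
            )
            net, truth, ds = nm.simulate(cfg_s)
            cfg = nm.SearchConfig(rng_seed=seed)
            cands = nm.search_all_seeds(ds, net, cfg)
            sig = nm.permutation_filter(cands, ds, net, cfg)
            planted = truth.planted_modules[0]
            if any(sub.members & planted for sub in sig.subnetworks):
                hits += 1
        assert hits >= 9

    def test_pvalue_floor_at_perfect_separation(self):
        # a hugely separated module should reach the estimator's floor
        cfg_s = nm.SyntheticConfig(
            n_genes=30, n_case=20, n_control=20, effect_size=8.0,
            module_size=3, connector_fraction=0.0, noise_sd=0.5, seed=4,
        )
        net, truth, ds = nm.simulate(cfg_s)
        cfg = nm.SearchConfig(rng_seed=4, n_permutations=99)
        cands = nm.search_all_seeds(ds, net, cfg)
        sig = nm.permutation_filter(cands, ds, net, cfg)
        floor = 1.0 / (1 + 99)
        assert any(
            sub.p_gene_null == pytest.approx(floor) for sub in sig.subnetworks
        )

    def test_filter_determinism(self):
        cfg_s = nm.SyntheticConfig(n_genes=40, n_case=12, n_control=12, seed=6)
        net, truth, ds = nm.simulate(cfg_s)
        cfg = nm.SearchConfig(rng_seed=11)
        cands = nm.search_all_seeds(ds, net, cfg)
        a = nm.permutation_filter(cands, ds, net, cfg)
        b = nm.permutation_filter(cands, ds, net, cfg)
        assert a.subnetworks == b.subnetworks
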
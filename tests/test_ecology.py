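"""Diversity indices, hotspot rule, correlations, and network statistics.

Network statistics are checked against exhaustive oracles: all-pairs
correlation scans for edges, enumeration of every shortest path for stress
centrality, and a scan over every partition of small graphs for modularity.
"""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from aurox.ecology import (
    ALPHA,
    EcologyError,
    OtuTable,
    berger_parker,
    build_network,
    chao1,
    classify_hotspots,
    diversity_gold_correlation,
    diversity_table,
    greedy_modules,
    inverse_simpson,
    pearson_with_p,
    stress_centrality,
)
from aurox.synthetic import gen_toy_network

counts_vectors = st.lists(st.integers(0, 500), min_size=1, max_size=40).filter(
    lambda x: sum(x) > 0
)


class TestAlphaDiversity:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([10, 10, 10, 10], 4.0),
            ([50, 25, 25], 1 / 0.375),
            ([7], 1.0),
        ],
    )
    def test_inverse_simpson(self, counts, expected):
        assert inverse_simpson(counts) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "counts, expected",
        [([50, 25, 25], 0.5), ([9], 1.0), ([3, 3, 3, 3, 3], 0.2)],
    )
    def test_berger_parker(self, counts, expected):
        assert berger_parker(counts) == pytest.approx(expected)

    def test_berger_parker_reciprocal_flag(self):
        assert berger_parker([50, 25, 25], reciprocal=True) == pytest.approx(2.0)

    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([1, 1, 2, 5, 9], 5 + 4 / 2),       # f1=2, f2=1
            ([5, 9, 20], 3.0),                  # no singletons
            ([1, 1, 5, 9, 20], 5 + 1.0),        # f2=0 bias-corrected branch
        ],
    )
    def test_chao1(self, counts, expected):
        assert chao1(counts) == pytest.approx(expected)

    def test_empty_site_rejected(self):
        with pytest.raises(EcologyError, match="empty site"):
            inverse_simpson([0, 0])

    @given(counts_vectors)
    @settings(max_examples=100, deadline=None)
    def test_index_ranges(self, counts):
        d = inverse_simpson(counts)
        bp = berger_parker(counts)
        richness = int(np.sum(np.asarray(counts) > 0))
        assert 1.0 <= d <= richness + 1e-9
        assert 0.0 < bp <= 1.0
        assert chao1(counts) >= richness


class TestHotspots:
    def make_meta(self, au_values):
        return pd.DataFrame(
            {"area": ["anomaly"] * len(au_values), "au": au_values},
            index=[f"s{i}" for i in range(len(au_values))],
        )

    def test_threshold_from_published_median(self):
        # values with median exactly 3.54 ng/g
        meta = self.make_meta([1.0, 2.0, 3.54, 6.0, 40.0])
        labels, thr = classify_hotspots(meta)
        assert thr == pytest.approx(1.5 * 3.54)  # 5.31
        assert bool(labels.loc["s3"]) is True      # 6.0 >= 5.31
        assert bool(labels.loc["s1"]) is False     # 2.0 < 5.31

    def test_inclusive_at_threshold(self):
        at_threshold = 1.5 * 3.54
        meta = self.make_meta([3.54, 3.54, at_threshold])
        labels, thr = classify_hotspots(meta)
        assert thr == pytest.approx(5.31)
        assert bool(labels.loc["s2"]) is True  # >= is inclusive

    @given(st.floats(0.1, 100.0))
    @settings(max_examples=30, deadline=None)
    def test_scale_equivariance(self, k):
        au = np.asarray([1.0, 2.5, 3.54, 6.0, 40.0])
        l1, t1 = classify_hotspots(self.make_meta(au))
        l2, t2 = classify_hotspots(self.make_meta(au * k))
        assert t2 == pytest.approx(k * t1, rel=1e-12)
        assert (l1.to_numpy() == l2.to_numpy()).all()

    def test_missing_gold_rejected(self):
        meta = self.make_meta([1.0, np.nan])
        with pytest.raises(EcologyError, match="missing gold"):
            classify_hotspots(meta)


def table_from_counts(counts, au):
    tax = pd.DataFrame(
        {"otu": counts.columns, "order": list(counts.columns),
         "phylum": ["Ascomycota"] * counts.shape[1]}
    ).set_index("otu")
    meta = pd.DataFrame(
        {"area": ["anomaly"] * len(counts), "au": au}, index=counts.index
    )
    return OtuTable(counts, tax, meta)


class TestDiversityGoldCorrelation:
    def test_monotone_gradient_significant(self):
        # evenness (hence inverse Simpson) increases monotonically with gold
        rows, au = [], []
        for k in [5, 10, 20, 30, 40]:
            rows.append([160 - 3 * k, k, k, k])
            au.append(float(k))
        counts = pd.DataFrame(
            rows, index=[f"s{i}" for i in range(5)],
            columns=[f"OTU{j}" for j in range(4)],
        )
        table = table_from_counts(counts, au)
        res = diversity_gold_correlation(table)
        assert res.loc["anomaly", "r"] > 0.9
        assert bool(res.loc["anomaly", "significant"]) is True

    def test_zero_variance_rejected(self):
        counts = pd.DataFrame(
            [[10, 10]] * 4, index=[f"s{i}" for i in range(4)],
            columns=["OTU0", "OTU1"],
        )
        table = table_from_counts(counts, [1.0, 2.0, 3.0, 4.0])
        with pytest.raises(EcologyError, match="zero variance"):
            diversity_gold_correlation(table)

    def test_p_value_matches_t_transform(self):
        x = [1.0, 2.0, 4.0, 8.0, 9.0]
        y = [2.1, 2.9, 4.2, 7.5, 9.9]
        r, p = pearson_with_p(x, y)
        from scipy.stats import t as tdist

        t_stat = r * np.sqrt(3) / np.sqrt(1 - r**2)
        assert p == pytest.approx(2 * tdist.sf(abs(t_stat), df=3), abs=1e-12)


class TestNetworkConstruction:
    def test_covarying_pair_positive_edge(self):
        base = np.asarray([1.0, 2, 3, 4, 5, 6, 7])
        counts = pd.DataFrame(
            {"OTU0": 10 * base, "OTU1": 20 * base,
             "OTU2": np.asarray([70, 60, 50, 40, 30, 20, 10.0])},
            index=[f"s{i}" for i in range(7)],
        ).astype(int)
        table = table_from_counts(counts, np.arange(7) + 1.0)
        net = build_network(table, min_prevalence=7, threshold=0.95, level=None)
        assert net.graph.has_edge("OTU0", "OTU1")
        assert net.graph["OTU0"]["OTU1"]["sign"] == 1
        assert net.graph["OTU0"]["OTU2"]["sign"] == -1

    def test_edges_match_bruteforce_scan(self, tiny_otu_table):
        threshold = 0.7
        net = build_network(
            tiny_otu_table, min_prevalence=7, threshold=threshold, level=None
        )
        rel = tiny_otu_table.counts.div(
            tiny_otu_table.counts.sum(axis=1), axis=0
        ).drop(columns=net.excluded)
        expected = set()
        for a, b in itertools.combinations(rel.columns, 2):
            r = np.corrcoef(rel[a], rel[b])[0, 1]
            if abs(r) >= threshold:
                expected.add(frozenset((a, b)))
        got = {frozenset(e) for e in net.graph.edges}
        assert got == expected

    def test_constant_relative_abundance_excluded(self):
        # equal row totals, so OTUc's relative abundance is exactly constant
        x = np.asarray([20, 40, 60, 80, 100, 120, 140])
        counts = pd.DataFrame(
            {"OTUa": x, "OTUb": 150 - x, "OTUc": np.full(7, 50)},
            index=[f"s{i}" for i in range(7)],
        )
        table = table_from_counts(counts, np.arange(7) + 1.0)
        net = build_network(table, min_prevalence=7, threshold=0.7, level=None)
        assert net.excluded == ["OTUc"]
        assert "OTUc" not in net.graph
        assert net.graph["OTUa"]["OTUb"]["sign"] == -1

    def test_prevalence_filter(self, tiny_otu_table):
        counts = tiny_otu_table.counts.copy()
        counts.loc[counts.index[:4], "OTU5"] = 0  # present in only 4 of 8 sites
        table = OtuTable(counts, tiny_otu_table.taxonomy, tiny_otu_table.site_meta)
        net = build_network(table, min_prevalence=7, threshold=0.5, level=None)
        assert "OTU5" not in net.graph


def exhaustive_best_modularity(g):
    """Max modularity over every partition of the nodes (<= 8 nodes)."""
    nodes = list(g.nodes)

    def partitions(seq):
        if not seq:
            yield []
            return
        head, rest = seq[0], seq[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [part[i] + [head]] + part[i + 1:]
            yield part + [[head]]

    return max(
        nx.community.modularity(g, [set(b) for b in part])
        for part in partitions(nodes)
    )


class TestModules:
    def test_two_triangles(self):
        net = gen_toy_network("two_cliques", 3)
        modules, q = greedy_modules(net)
        assert len(set(modules.values())) == 2
        assert q == pytest.approx(0.5)

    def test_single_edge(self):
        net = gen_toy_network("path", 2)
        modules, q = greedy_modules(net)
        assert len(set(modules.values())) == 1
        assert q == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "motif, n", [("two_cliques", 3), ("path", 4), ("star", 3), ("two_cliques", 4)]
    )
    def test_matches_exhaustive_optimum(self, motif, n):
        net = gen_toy_network(motif, n)
        _, q = greedy_modules(net)
        assert q == pytest.approx(exhaustive_best_modularity(net.graph), abs=1e-12)

    def test_empty_graph_rejected(self):
        net = gen_toy_network("custom", edges=[])
        with pytest.raises(EcologyError, match="no edges"):
            greedy_modules(net)


def bruteforce_stress(g, x):
    """Count shortest s-t paths through x by enumerating all simple paths."""
    total = 0
    for s, t in itertools.combinations(g.nodes, 2):
        if x in (s, t):
            continue
        paths = list(nx.all_simple_paths(g, s, t))
        if not paths:
            continue
        d = min(len(p) for p in paths)
        total += sum(1 for p in paths if len(p) == d and x in p[1:-1])
    return total


class TestStressCentrality:
    def test_path_midpoint(self):
        net = gen_toy_network("path", 3)
        assert stress_centrality(net, "1") == 1
        assert stress_centrality(net, "0") == 0

    def test_star_center(self):
        net = gen_toy_network("star", 3)
        assert stress_centrality(net, "0") == 3  # one per leaf pair

    def test_clique_all_zero(self):
        net = gen_toy_network("clique", 4)
        assert all(v == 0 for v in stress_centrality(net).values())

    def test_parallel_shortest_paths_counted(self):
        # square a-b-c-d-a: two shortest paths between opposite corners
        net = gen_toy_network("custom", edges=[(0, 1), (1, 2), (2, 3), (3, 0)])
        cent = stress_centrality(net)
        assert all(v == 1 for v in cent.values())

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_on_random_graphs(self, seed):
        g = nx.gnp_random_graph(8, 0.4, seed=seed)
        g = nx.relabel_nodes(g, {v: str(v) for v in g.nodes})
        cent = stress_centrality(g)
        for node in g.nodes:
            assert cent[node] == bruteforce_stress(g, node)

    def test_unknown_node_rejected(self):
        net = gen_toy_network("path", 3)
        with pytest.raises(EcologyError, match="unknown node"):
            stress_centrality(net, "zz")


class TestAggregationAndIO:
    def test_order_aggregation_sums_counts(self, tiny_otu_table):
        tax = tiny_otu_table.taxonomy.copy()
        tax["order"] = ["A", "A", "B", "B", "B", "C"]
        table = OtuTable(tiny_otu_table.counts, tax, tiny_otu_table.site_meta)
        agg = table.aggregate("order")
        assert set(agg.columns) == {"A", "B", "C"}
        expected = tiny_otu_table.counts[["OTU1", "OTU2"]].sum(axis=1)
        assert (agg["A"] == expected).all()

    def test_tsv_round_trip(self, tiny_otu_table, tmp_path):
        tiny_otu_table.counts.to_csv(tmp_path / "counts.tsv", sep="\t")
        tiny_otu_table.taxonomy.to_csv(tmp_path / "tax.tsv", sep="\t")
        tiny_otu_table.site_meta.to_csv(tmp_path / "meta.tsv", sep="\t")
        table = OtuTable.from_tsv(
            tmp_path / "counts.tsv", tmp_path / "tax.tsv", tmp_path / "meta.tsv"
        )
        assert (table.counts == tiny_otu_table.counts).all().all()

    def test_shared_file_header_variant(self, tiny_otu_table, tmp_path):
        shared = tiny_otu_table.counts.reset_index().rename(columns={"site": "Group"})
        shared.insert(0, "label", 0.03)
        shared.insert(2, "numOtus", tiny_otu_table.counts.shape[1])
        shared.to_csv(tmp_path / "counts.shared", sep="\t", index=False)
        tiny_otu_table.taxonomy.to_csv(tmp_path / "tax.tsv", sep="\t")
        tiny_otu_table.site_meta.to_csv(tmp_path / "meta.tsv", sep="\t")
        table = OtuTable.from_tsv(
            tmp_path / "counts.shared", tmp_path / "tax.tsv", tmp_path / "meta.tsv"
        )
        assert (table.counts == tiny_otu_table.counts).all().all()

    def test_negative_counts_rejected(self, tiny_otu_table):
        bad = tiny_otu_table.counts.copy()
        bad.iloc[0, 0] = -1
        with pytest.raises(EcologyError, match="non-negative"):
            OtuTable(bad, tiny_otu_table.taxonomy, tiny_otu_table.site_meta)
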
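import itertools
from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pdcorenet import io as io_mod
from pdcorenet import network as net
from pdcorenet import normtype
from tests.conftest import random_edge_set

STRING_HEADER = (
    "protein1 protein2 neighborhood fusion cooccurence coexpression "
    "experimental database textmining combined_score"
)


def write_string(tmp_path, rows):
    p = tmp_path / "string.tsv"
    p.write_text(STRING_HEADER + "\n" + "\n".join(rows) + ("\n" if rows else ""))
    return str(p)


def write_gm(tmp_path, rows):
    p = tmp_path / "gm.tsv"
    p.write_text(
        "Gene_A\tGene_B\tWeight\tNetwork_Group\n"
        + "\n".join(rows) + ("\n" if rows else "")
    )
    return str(p)


class TestParseString:
    def test_textmining_only_edge_dropped(self, tmp_path):
        path = write_string(tmp_path, ["A B 0 0 0 0 0 0 900 900"])
        assert len(net.parse_string_edges(path)) == 0

    def test_experimental_edge_kept_with_channel(self, tmp_path):
        path = write_string(tmp_path, ["A B 0 0 0 0 400 0 0 400"])
        df = net.parse_string_edges(path)
        assert len(df) == 1
        assert df.iloc[0]["channel"] == "experimental"

    def test_min_combined_score_filter(self, tmp_path):
        path = write_string(tmp_path, ["A B 0 0 0 0 400 0 0 400"])
        assert len(net.parse_string_edges(path, min_combined_score=500)) == 0

    def test_malformed_row_reports_line(self, tmp_path):
        path = write_string(
            tmp_path, ["A B 0 0 0 0 400 0 0 400", "C D 0 0 0 0 oops 0 0 1"]
        )
        with pytest.raises(ValueError, match="line 3"):
            net.parse_string_edges(path)

    def test_unknown_column_errors(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("protein1 protein2 bogus\nA B 1\n")
        with pytest.raises(ValueError, match="header"):
            net.parse_string_edges(str(p))

    def test_kept_set_matches_bruteforce_scan(self, hub_edge_tables):
        _, _, string_path, _ = hub_edge_tables
        raw = pd.read_csv(string_path, sep=r"\s+")
        excluded = {"textmining", "cooccurence", "neighborhood"}
        retained = [c for c in net.STRING_CHANNELS if c not in excluded]
        expect = set()
        for row in raw.itertuples(index=False):
            d = row._asdict()
            if any(d[c] > 0 for c in retained):
                a, b = sorted((d["protein1"], d["protein2"]))
                expect.add((a, b))
        got = net.parse_string_edges(string_path)
        assert set(zip(got["gene_a"], got["gene_b"])) == expect


class TestParseGenemania:
    def test_predicted_dropped(self, tmp_path):
        path = write_gm(tmp_path, ["A\tB\t0.5\tPredicted"])
        assert len(net.parse_genemania_edges(path)) == 0

    def test_case_and_plural_insensitive_match(self, tmp_path):
        path = write_gm(tmp_path, ["A\tB\t0.5\tpathway", "C\tD\t0.2\tPHYSICAL INTERACTION"])
        df = net.parse_genemania_edges(path)
        assert set(df["channel"]) == {"Pathways", "Physical Interactions"}

    def test_scan_matches_oracle(self, hub_edge_tables):
        _, _, _, gm_path = hub_edge_tables
        raw = pd.read_csv(gm_path, sep="\t")
        allowed = {"genetic interaction", "pathway", "physical interaction"}
        expect = {
            tuple(sorted((a, b)))
            for a, b, _, cat in raw.itertuples(index=False)
            if cat.lower().rstrip("s") in allowed
        }
        got = net.parse_genemania_edges(gm_path)
        assert set(zip(got["gene_a"], got["gene_b"])) == expect


class TestCuration:
    def test_non_deg_edges_removed(self):
        edges = pd.DataFrame(
            [("deg1", "other", "string", "experimental", 1.0),
             ("deg1", "deg2", "string", "experimental", 1.0)],
            columns=net.EDGE_COLUMNS,
        )
        n = net.curate_deg_network(edges, {"deg1", "deg2"})
        assert set(n.graph.edges) == {("deg1", "deg2")}

    def test_multi_source_pair_is_one_edge_with_provenance(self):
        edges = pd.DataFrame(
            [("a", "b", "string", "experimental", 1.0),
             ("a", "b", "genemania", "Pathways", 0.5)],
            columns=net.EDGE_COLUMNS,
        )
        n = net.curate_deg_network(edges, {"a", "b"})
        assert n.n_edges == 1
        assert n.graph["a"]["b"]["provenance"] == {
            ("string", "experimental"), ("genemania", "Pathways")
        }

    def test_disconnected_degs_reported(self):
        edges = pd.DataFrame(
            [("a", "b", "string", "experimental", 1.0)],
            columns=net.EDGE_COLUMNS,
        )
        n = net.curate_deg_network(edges, {"a", "b", "lonely"})
        assert n.disconnected == ["lonely"]
        assert n.n_connected == 2

    def test_counts_match_bruteforce_filter(self, hub_edge_tables, ppi_universe):
        merged, hubs, _, _ = hub_edge_tables
        deg_set = set(ppi_universe[:60])
        n = net.curate_deg_network(merged, deg_set)
        pairs = {
            (a, b)
            for a, b in zip(merged["gene_a"], merged["gene_b"])
            if a in deg_set and b in deg_set
        }
        assert n.n_edges == len(pairs)
        assert set(n.graph.nodes) == {g for p in pairs for g in p}
        # induced-subgraph property
        assert all(a in deg_set and b in deg_set for a, b in n.graph.edges)


class TestTopology:
    def test_path_and_star_closed_forms(self):
        path = nx.path_graph(["a", "b", "c"])
        n = net.Network(path, frozenset("abc"))
        bc = net.betweenness(n)
        assert bc["b"] == 1.0 and bc["a"] == 0.0 and bc["c"] == 0.0
        star = nx.star_graph(6)  # center 0, 6 leaves
        bs = net.betweenness(net.Network(star, frozenset(star.nodes)))
        assert bs[0] == comb(6, 2)

    def test_diameter_examples(self):
        tri = nx.cycle_graph(3)
        assert net.network_diameter(net.Network(tri, frozenset(tri))) == 1
        p4 = nx.path_graph(4)
        assert net.network_diameter(net.Network(p4, frozenset(p4))) == 3

    def test_diameter_uses_largest_component(self):
        g = nx.path_graph(5)
        g.add_edge("x", "y")
        assert net.network_diameter(net.Network(g, frozenset(g))) == 4

    def test_empty_graph_diameter_errors(self):
        with pytest.raises(ValueError):
            net.network_diameter(net.Network(nx.Graph(), frozenset()))


class TestWilcoxonRanksum:
    def test_documented_exact_example(self):
        u, p = net.wilcoxon_ranksum([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_identical_multisets_give_p_one(self):
        _, p = net.wilcoxon_ranksum([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_matches_scipy_exact_for_small_tie_free_samples(self):
        rng = np.random.default_rng(0)
        for n in range(1, 9):
            for m in range(1, 9):
                x = rng.normal(size=n)
                y = rng.normal(size=m)
                u, p = net.wilcoxon_ranksum(x, y)
                ref = stats.mannwhitneyu(
                    x, y, alternative="two-sided", method="exact"
                )
                assert u == pytest.approx(ref.statistic)
                assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_with_ties(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 4, size=30).astype(float)
        y = rng.integers(0, 4, size=40).astype(float)
        _, p = net.wilcoxon_ranksum(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestNullModel:
    def test_replicates_exclude_degs_and_match_size(self, flat_edge_table,
                                                    ppi_universe):
        deg_set = set(ppi_universe[:20])
        res = net.random_network_null(
            ppi_universe, deg_set, flat_edge_table, n_replicates=5, seed=3
        )
        assert res.n_replicates == 5
        assert len(res.node_counts) == 5

    def test_edgeless_deg_set_not_significant(self, flat_edge_table,
                                              ppi_universe):
        phantom = [f"X{i}" for i in range(20)]
        universe = ppi_universe + phantom
        res = net.random_network_null(
            universe, set(phantom), flat_edge_table, n_replicates=10, seed=4
        )
        assert len(res.deg_degrees) == 0 and res.p_value == 1.0

    def test_universe_too_small_errors(self, flat_edge_table):
        with pytest.raises(ValueError, match="too small"):
            net.random_network_null(
                ["a", "b", "c"], {"a", "b"}, flat_edge_table, seed=0
            )

    def test_planted_hubs_detected(self, hub_edge_tables, ppi_universe):
        merged, hubs, _, _ = hub_edge_tables
        res = net.random_network_null(
            ppi_universe, set(hubs), merged, n_replicates=50, seed=0
        )
        assert res.p_value < 1e-3


class TestCorrelationNetwork:
    def _norm(self, X, genes):
        import anndata as ad

        a = ad.AnnData(
            X=np.asarray(X, float),
            obs=pd.DataFrame(index=[f"c{i}" for i in range(len(X))]),
            var=pd.DataFrame(index=genes),
        )
        return a

    def test_duplicated_gene_gives_edge(self):
        rng = np.random.default_rng(2)
        x = rng.random(30)
        a = self._norm(np.column_stack([x, x, rng.random(30)]),
                       ["g1", "g2", "g3"])
        df = net.correlation_network(a, {"g1", "g2", "g3"})
        assert ("g1", "g2") in set(zip(df["gene_a"], df["gene_b"]))

    def test_r_below_threshold_rejected_despite_tiny_p(self):
        rng = np.random.default_rng(3)
        n = 100000  # huge n: r ~ 0.09 significant but below r_min
        z = rng.normal(size=n)
        x = z + rng.normal(size=n) * 3.2
        y = z + rng.normal(size=n) * 3.2
        r = np.corrcoef(x, y)[0, 1]
        assert 0.05 < r < 0.1
        a = self._norm(np.column_stack([x, y]), ["g1", "g2"])
        df = net.correlation_network(a, {"g1", "g2"})
        assert len(df) == 0

    def test_constant_gene_skipped_with_warning(self):
        a = self._norm(
            np.column_stack([np.full(10, 2.0), np.arange(10.0)]), ["g1", "g2"]
        )
        with pytest.warns(UserWarning, match="constant"):
            df = net.correlation_network(a, {"g1", "g2"})
        assert len(df) == 0

    def test_matches_bruteforce_rule(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 20))
        genes = [f"g{i}" for i in range(20)]
        a = self._norm(X, genes)
        df = net.correlation_network(a, set(genes), r_min=0.1, p_max=0.05)
        got = set(zip(df["gene_a"], df["gene_b"]))
        expect = set()
        for i, j in itertools.combinations(range(20), 2):
            r, p = stats.pearsonr(X[:, i], X[:, j])
            if r > 0.1 and p < 0.05:
                expect.add(tuple(sorted((genes[i], genes[j]))))
        assert got == expect


class TestIntersection:
    def test_disjoint_and_subset_cases(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(30)]
        a = random_edge_set(rng, genes, 20)
        b = random_edge_set(rng, genes, 20)
        empty = net.intersect_networks(a.iloc[:0], b)
        assert len(empty) == 0
        self_int = net.intersect_networks(a, a)
        assert set(zip(self_int["gene_a"], self_int["gene_b"])) == set(
            zip(a["gene_a"], a["gene_b"])
        )

    def test_commutative_idempotent_and_matches_set_intersection(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(25)]
        for _ in range(10):
            a = random_edge_set(rng, genes, int(rng.integers(5, 40)))
            b = random_edge_set(rng, genes, int(rng.integers(5, 40)))
            ab = net.intersect_networks(a, b)
            ba = net.intersect_networks(b, a)
            pa = set(zip(a["gene_a"], a["gene_b"]))
            pb = set(zip(b["gene_a"], b["gene_b"]))
            assert set(zip(ab["gene_a"], ab["gene_b"])) == pa & pb
            pd.testing.assert_frame_equal(
                ab.reset_index(drop=True), ba.reset_index(drop=True)
            )
            again = net.intersect_networks(ab, ab)
            pd.testing.assert_frame_equal(
                ab.reset_index(drop=True), again.reset_index(drop=True)
            )


class TestParkOverlay:
    def make_edges(self, rows):
        return pd.DataFrame(rows, columns=net.EDGE_COLUMNS)

    def test_seed_seed_edges_removed(self):
        edges = self.make_edges(
            [("park1", "park2", "string", "experimental", 1.0)]
        )
        deg_net = net.curate_deg_network(
            self.make_edges([("d1", "d2", "string", "experimental", 1.0)]),
            {"d1", "d2"},
        )
        res = net.park_overlay(edges, deg_net, ["park1", "park2"])
        assert res.seed_partners == {"park1": [], "park2": []}
        assert not res.all_seeds_connected

    def test_seed_deg_edges_counted_once(self):
        edges = self.make_edges(
            [
                ("d1", "park1", "string", "experimental", 1.0),
                ("d1", "park1", "genemania", "Pathways", 0.2),
                ("d2", "park1", "string", "database", 0.9),
            ]
        )
        deg_net = net.curate_deg_network(
            self.make_edges([("d1", "d2", "string", "experimental", 1.0)]),
            {"d1", "d2"},
        )
        res = net.park_overlay(edges, deg_net, ["park1"])
        assert res.seed_partners["park1"] == ["d1", "d2"]
        assert res.deg_touch_counts["d1"] == 1
        assert res.all_seeds_connected

    def test_matches_bruteforce_classification(self, hub_edge_tables,
                                               ppi_universe):
        merged, _, _, _ = hub_edge_tables
        deg_set = set(ppi_universe[:50])
        seeds = ppi_universe[380:]
        deg_net = net.curate_deg_network(merged, deg_set)
        res = net.park_overlay(merged, deg_net, seeds)
        sset = set(seeds)
        expect = {s: set() for s in seeds}
        for a, b in zip(merged["gene_a"], merged["gene_b"]):
            if a in sset and b in deg_set and b not in sset:
                expect[a].add(b)
            elif b in sset and a in deg_set and a not in sset:
                expect[b].add(a)
        assert {s: sorted(v) for s, v in expect.items()} == res.seed_partners


class TestORA:
    def test_boundary_full_overlap(self):
        universe = {f"g{i}" for i in range(20)}
        out = net.ora_enrichment(universe, {"all": sorted(universe)}, universe)
        assert out.loc["all", "p"] == pytest.approx(1.0)

    def test_empty_overlap(self):
        universe = {f"g{i}" for i in range(20)}
        out = net.ora_enrichment(
            {"g0"}, {"other": ["g10", "g11"]}, universe
        )
        assert out.loc["other", "fold"] == 0.0
        assert out.loc["other", "p"] == 1.0

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            net.ora_enrichment(set(), {"s": []}, set())

    def test_tail_matches_exact_fraction_sum(self):
        universe = [f"g{i}" for i in range(1000)]
        gene_set = universe[:20]
        query = universe[:5] + universe[500:505]  # overlap 5, query 10
        out = net.ora_enrichment(set(query), {"s": gene_set}, set(universe))
        N, K, n, k = 1000, 20, 10, 5
        exact = sum(
            Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n))
            for i in range(k, min(K, n) + 1)
        )
        assert out.loc["s", "p"] == pytest.approx(float(exact), rel=1e-10)
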
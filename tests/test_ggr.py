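import math

import networkx as nx
import numpy as np
import pytest
from scipy import integrate

from rewirenet import ggr
from rewirenet.io import canonical_pair

from conftest import make_expression


class TestDifferentialExpression:
    def test_identical_groups_not_de(self):
        expr = make_expression([[1, 1, 1, 1, 1, 1]],
                               conditions=["PB"] * 3 + ["RB"] * 3)
        res = ggr.differential_expression(expr, ["S0", "S1", "S2"],
                                          ["S3", "S4", "S5"], 0.05)
        assert res["t"].iloc[0] == pytest.approx(0.0)
        assert res["p_raw"].iloc[0] == pytest.approx(1.0)
        assert not res["de"].iloc[0]

    def test_t_statistic_against_density_integral(self):
        # P = (1,2,3), R = (4,5,6): pooled sd 1, t = -3.674, df = 4
        expr = make_expression([[1, 2, 3, 4, 5, 6]],
                               conditions=["PB"] * 3 + ["RB"] * 3)
        res = ggr.differential_expression(expr, ["S0", "S1", "S2"],
                                          ["S3", "S4", "S5"], 0.05)
        t = res["t"].iloc[0]
        assert t == pytest.approx(-3 / math.sqrt(2 / 3), rel=1e-6)
        # oracle: numerically integrate the t density tail at df = 4
        df = 4

        def t_pdf(x):
            c = math.gamma((df + 1) / 2) / (
                math.sqrt(df * math.pi) * math.gamma(df / 2)
            )
            return c * (1 + x * x / df) ** (-(df + 1) / 2)

        tail, _ = integrate.quad(t_pdf, abs(t), np.inf)
        assert res["p_raw"].iloc[0] == pytest.approx(2 * tail, rel=1e-6)
        assert res["p_raw"].iloc[0] == pytest.approx(0.0212, abs=2e-3)

    def test_bonferroni_arithmetic(self):
        rng = np.random.default_rng(0)
        values = rng.normal(0, 1, size=(10, 6))
        # gene 0 gets a strong shift so its raw p is small
        values[0, 3:] += 30
        expr = make_expression(values, conditions=["PB"] * 3 + ["RB"] * 3)
        res = ggr.differential_expression(expr, ["S0", "S1", "S2"],
                                          ["S3", "S4", "S5"], 0.05)
        assert res["p_bonferroni"].iloc[0] == pytest.approx(
            min(1.0, res["p_raw"].iloc[0] * 10)
        )
        assert (res["p_bonferroni"] >= res["p_raw"]).all()

    def test_degenerate_unequal_means(self):
        expr = make_expression([[1, 1, 1, 2, 2, 2]],
                               conditions=["PB"] * 3 + ["RB"] * 3)
        res = ggr.differential_expression(expr, ["S0", "S1", "S2"],
                                          ["S3", "S4", "S5"], 0.05)
        assert res["p_raw"].iloc[0] == 0.0

    def test_small_group_rejected(self):
        expr = make_expression([[1, 2, 3]])
        with pytest.raises(ValueError):
            ggr.differential_expression(expr, ["S0"], ["S1", "S2"], 0.05)


class TestCorrelationTable:
    def test_perfect_linear_and_sign(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        expr = make_expression([x, 2 * x + 1, -x])
        corr = ggr.CorrelationTable(expr.values)
        assert corr.pcc("G00", "G01") == pytest.approx(1.0)
        assert corr.pcc("G00", "G02") == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        expr = make_expression([[1, 2, 3, 4], [1, 3, 2, 4]])
        corr = ggr.CorrelationTable(expr.values)
        assert corr.pcc("G00", "G01") == pytest.approx(0.8)

    def test_constant_gene_gets_zero(self):
        expr = make_expression([[1, 2, 3, 4], [5, 5, 5, 5]])
        corr = ggr.CorrelationTable(expr.values)
        assert corr.pcc("G00", "G01") == 0.0

    def test_too_few_samples(self):
        expr = make_expression([[1, 2], [3, 4]])
        with pytest.raises(ValueError):
            ggr.CorrelationTable(expr.values)

    def test_pairs_table_is_upper_triangle(self, rng):
        expr = make_expression(rng.normal(size=(5, 8)))
        pairs = ggr.CorrelationTable(expr.values).pairs(expr.genes)
        assert len(pairs) == 10
        assert (pairs["gene_a"] < pairs["gene_b"]).all()


class TestSelectDirectEdges:
    def test_counting_rule_exact(self, rng):
        # |direct| = ceil(fraction * C(n,2)) for any n
        for n in (2, 5, 13):
            expr = make_expression(rng.normal(size=(n, 6)))
            pairs = ggr.CorrelationTable(expr.values).pairs(expr.genes)
            edges, thr = ggr.select_direct_edges(pairs, 0.20)
            assert len(edges) == math.ceil(0.2 * n * (n - 1) / 2)
            kept = pairs[pairs["pcc"].abs() > thr]
            assert len(kept) <= len(edges)

    def test_single_pair(self, rng):
        expr = make_expression(rng.normal(size=(2, 6)))
        pairs = ggr.CorrelationTable(expr.values).pairs(expr.genes)
        edges, _ = ggr.select_direct_edges(pairs, 0.01)
        assert len(edges) == 1

    def test_tie_break_matches_brute_force(self):
        import pandas as pd
        # ten pairs, three tied at the cut value
        rows = []
        vals = [0.9, 0.8, 0.5, 0.5, 0.5, 0.4, 0.3, 0.2, 0.1, 0.05]
        for i, v in enumerate(vals):
            rows.append((f"A{i:02d}", f"B{i:02d}", v))
        pairs = pd.DataFrame(rows, columns=["gene_a", "gene_b", "pcc"])
        edges, thr = ggr.select_direct_edges(pairs, 0.2)
        # brute-force oracle: full sort by (-|pcc|, pair), take ceil(2)
        ranked = sorted(rows, key=lambda r: (-abs(r[2]), r[0], r[1]))
        expected = {(r[0], r[1]) for r in ranked[:2]}
        assert edges == expected
        assert thr == pytest.approx(0.8)


def _toy_path_setup():
    """6-gene toy: i-L-j significant path, i-M-j insignificant."""
    rng = np.random.default_rng(7)
    n_samples = 12
    f = rng.normal(size=n_samples)
    i = f + 0.1 * rng.normal(size=n_samples)
    linker = f + 0.1 * rng.normal(size=n_samples)
    j = f + 0.1 * rng.normal(size=n_samples)
    decoy = rng.normal(size=(3, n_samples))
    values = np.vstack([i, linker, j, decoy])
    genes = ["gi", "linker", "gj", "m1", "m2", "m3"]
    expr = make_expression(values, genes=genes,
                           samples=[f"S{k}" for k in range(n_samples)],
                           conditions=["PB"] * n_samples)
    ppi = nx.Graph()
    ppi.add_edges_from([("gi", "linker"), ("linker", "gj"),
                        ("gi", "m1"), ("m1", "gj"),
                        ("m2", "m3")])
    corr = ggr.CorrelationTable(expr.values)
    return expr, ppi, corr


class TestPathSignificance:
    def test_hand_enumerated_p_value(self):
        """4 eligible nulls, observed equal to one of them -> p = 2/4."""
        _, ppi, corr = _toy_path_setup()

        class FakeCorr:
            genes = corr.genes

            def __contains__(self, g):
                return True

            def pcc(self, a, b):
                table = {frozenset(p): v for p, v in {
                    ("gi", "linker"): 0.3, ("linker", "gj"): 0.3,
                    ("gi", "m1"): 0.1, ("m1", "gj"): 0.1,
                    ("gi", "m2"): 0.2, ("m2", "gj"): 0.2,
                    ("gi", "m3"): 0.3, ("m3", "gj"): 0.3,
                    ("gi", "gj"): 0.0,
                }.items()}
                return table.get(frozenset((a, b)), 0.9)

            def pcc_profile(self, gene, others):
                return np.array([self.pcc(gene, g) for g in others])

        ppi2 = nx.Graph()
        ppi2.add_edges_from([("gi", "linker"), ("linker", "gj")])
        ppi2.add_nodes_from(["m1", "m2", "m3", "m4"])
        fake = FakeCorr()
        res = ggr.path_significance("gi", "gj", "linker", ppi2, fake,
                                    universe=["m1", "m2", "m3", "m4"])
        # nulls: m1 -> 0.1, m2 -> 0.2, m3 -> 0.3, m4 -> 0.9; observed 0.3
        assert res.statistic == pytest.approx(0.3)
        assert res.n_eligible == 4
        assert res.p_value == pytest.approx(2 / 4)

    def test_maximal_statistic_is_significant(self):
        _, ppi, corr = _toy_path_setup()
        res = ggr.path_significance("gi", "gj", "linker", ppi, corr)
        assert res.p_value == 0.0

    def test_untestable_when_no_eligible(self):
        _, ppi, corr = _toy_path_setup()
        res = ggr.path_significance("gi", "gj", "linker", ppi, corr,
                                    universe=["gi", "gj", "linker", "m1"])
        assert res.untestable and res.p_value == 1.0

    def test_invariant_to_null_enumeration_order(self):
        _, ppi, corr = _toy_path_setup()
        u1 = ["m2", "m3", "m1", "linker", "gj", "gi"]
        u2 = sorted(u1)
        r1 = ggr.path_significance("gi", "gj", "linker", ppi, corr, universe=u1)
        r2 = ggr.path_significance("gi", "gj", "linker", ppi, corr, universe=u2)
        assert r1.p_value == r2.p_value


class TestFindIndirectEdges:
    def test_no_path_no_linkers(self):
        _, ppi, corr = _toy_path_setup()
        indirect, linkers, edges = ggr.find_indirect_edges(
            [("m2", "m3")], ppi, corr, 0.05
        )
        assert indirect == set() and linkers == set()

    def test_toy_graph_matches_exhaustive_oracle(self):
        expr, ppi, corr = _toy_path_setup()
        indirect, linkers, ppi_edges = ggr.find_indirect_edges(
            [("gi", "gj")], ppi, corr, 0.2
        )
        # exhaustive oracle over both length-2 paths
        universe = sorted(g for g in ppi.nodes if g in corr)
        excluded = {"gi", "gj"} | set(nx.common_neighbors(ppi, "gi", "gj"))
        eligible = [g for g in universe if g not in excluded]
        sig = set()
        for mid in nx.common_neighbors(ppi, "gi", "gj"):
            obs = math.sqrt(abs(corr.pcc("gi", mid)) * abs(corr.pcc(mid, "gj")))
            null = [
                math.sqrt(abs(corr.pcc("gi", g)) * abs(corr.pcc(g, "gj")))
                for g in eligible
            ]
            p = sum(v >= obs for v in null) / len(null)
            if p <= 0.2:
                sig.add(mid)
        assert linkers == sig
        assert ("linker" in linkers) and ("m1" not in linkers)
        assert indirect == {("gi", "gj")}
        assert ppi_edges == {("gi", "linker"), ("gj", "linker")}


class TestBuildAndHarmonize:
    def _scenario_expr(self, rng, n=14, n_samples=8):
        return make_expression(rng.normal(size=(n, n_samples)),
                               samples=[f"S{k}" for k in range(n_samples)],
                               conditions=["RB"] * n_samples)

    def test_no_paths_means_direct_only(self, rng):
        expr = self._scenario_expr(rng)
        ppi = nx.Graph()
        ppi.add_nodes_from(expr.genes)
        net = ggr.build_ggr(set(expr.genes[:6]), set(expr.genes[6:10]), expr,
                            ppi, "R")
        assert net.seed.linker_genes == set()
        assert all(labels == frozenset({"direct"})
                   for labels in net.edges.values())

    def test_planted_linker_enters_network(self):
        # i and j both track the linker but not each other, so their only
        # route into R is the significant length-2 PPI path
        rng = np.random.default_rng(11)
        n_samples = 12
        f1, f2 = rng.normal(size=(2, n_samples))
        i = 3 * f1 + 0.2 * rng.normal(size=n_samples)
        j = 3 * f2 + 0.2 * rng.normal(size=n_samples)
        linker = 2 * (f1 + f2) + 0.2 * rng.normal(size=n_samples)
        decoy = rng.normal(size=(3, n_samples))
        values = np.vstack([i, linker, j, decoy])
        genes = ["gi", "linker", "gj", "m1", "m2", "m3"]
        expr = make_expression(values, genes=genes,
                               samples=[f"S{k}" for k in range(n_samples)],
                               conditions=["RB"] * n_samples)
        ppi = nx.Graph()
        ppi.add_edges_from([("gi", "linker"), ("linker", "gj"), ("m2", "m3")])
        net = ggr.build_ggr({"gi"}, {"gj", "m2", "m3"}, expr, ppi, "R",
                            direct_fraction=0.2, path_alpha=0.2)
        assert "linker" in net.nodes
        assert net.has_edge("gi", "linker") and net.has_edge("linker", "gj")
        labels = net.edges[canonical_pair("gi", "linker")]
        assert "ppi" in labels

    def test_node_count_arithmetic(self, rng):
        expr = self._scenario_expr(rng)
        ppi = nx.Graph()
        ppi.add_nodes_from(expr.genes)
        de, cgc = set(expr.genes[:5]), set(expr.genes[4:9])
        net = ggr.build_ggr(de, cgc, expr, ppi, "R")
        assert net.nodes == de | cgc

    def test_empty_core_rejected(self, rng):
        expr = self._scenario_expr(rng)
        with pytest.raises(ValueError):
            ggr.build_ggr(set(), set(), expr, nx.Graph(), "R")

    def test_harmonize_intersection_and_dyads(self, rng):
        seed_r = ggr.SeedGeneSet("R", {"A", "B", "C"}, set(), set())
        seed_p = ggr.SeedGeneSet("P", {"B", "C", "D"}, set(), set())
        net_r = ggr.GGRNetwork("R", {"A", "B", "C"},
                               {("B", "C"): frozenset({"direct"})}, seed_r)
        net_p = ggr.GGRNetwork("P", {"B", "C", "D"},
                               {("C", "D"): frozenset({"direct"})}, seed_p)
        final, restricted, dyads = ggr.harmonize_conditions(net_r, net_p)
        assert final == ["B", "C"]
        assert len(dyads) == 1
        assert dyads.u_r[0] == 1 and dyads.u_p[0] == 0

    def test_harmonize_identity(self, rng):
        import itertools
        genes = ["A", "B", "C", "D"]
        edges = {("A", "B"): frozenset({"direct"}),
                 ("C", "D"): frozenset({"indirect"})}
        seed = ggr.SeedGeneSet("R", set(genes), set(), set())
        net_r = ggr.GGRNetwork("R", set(genes), dict(edges), seed)
        net_p = ggr.GGRNetwork("P", set(genes), dict(edges), seed)
        final, _restricted, dyads = ggr.harmonize_conditions(net_r, net_p)
        assert (dyads.u_r == dyads.u_p).all()
        assert len(dyads) == len(list(itertools.combinations(genes, 2)))
        # indicators match adjacency lookups
        for pair, u in zip(dyads.pairs, dyads.u_r):
            assert bool(u) == (pair in edges)

    def test_empty_intersection_rejected(self):
        s1 = ggr.SeedGeneSet("R", {"A"}, set(), set())
        s2 = ggr.SeedGeneSet("P", {"B"}, set(), set())
        n1 = ggr.GGRNetwork("R", {"A"}, {}, s1)
        n2 = ggr.GGRNetwork("P", {"B"}, {}, s2)
        with pytest.raises(ValueError):
            ggr.harmonize_conditions(n1, n2)


class TestDeterminism:
    def test_build_ggr_deterministic(self, rng):
        expr = make_expression(rng.normal(size=(10, 8)),
                               samples=[f"S{k}" for k in range(8)],
                               conditions=["RB"] * 8)
        ppi = nx.Graph()
        ppi.add_edges_from([(expr.genes[0], expr.genes[9]),
                            (expr.genes[9], expr.genes[1])])
        args = (set(expr.genes[:4]), set(expr.genes[4:8]), expr, ppi, "R")
        n1 = ggr.build_ggr(*args)
        n2 = ggr.build_ggr(*args)
        assert n1.edges == n2.edges and n1.nodes == n2.nodes
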
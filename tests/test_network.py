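"""Network statistics: enrichment, centrality, connectivity regression."""
import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import hypergeom_enrichment_p, logistic_mle
from syndel.models import CoexpressionNetwork
from syndel.network import (
    adjust_regressions,
    centrality_bootstrap,
    exclude_and_rerun,
    filter_density,
    logistic_connectivity,
    max_edge_to_set,
    module_enrichment,
    wnc,
)


def build_network(edges, modules):
    g = nx.Graph()
    g.add_nodes_from(modules)
    g.add_weighted_edges_from(edges)
    return CoexpressionNetwork(g, pd.Series(modules))


@pytest.fixture
def random_network():
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(60)]
    modules = {g: i % 4 for i, g in enumerate(genes)}
    edges = []
    for _ in range(250):
        i, j = rng.integers(0, 60, 2)
        if i != j:
            edges.append((genes[i], genes[j], float(rng.random())))
    return build_network(edges, modules)


class TestWnc:
    def test_isolated_gene_is_zero_and_star_sums(self):
        net = build_network([("c", "a", 1.0), ("c", "b", 1.0), ("c", "d", 1.0)],
                            {"a": 0, "b": 0, "c": 0, "d": 0, "lonely": 1})
        w = wnc(net)
        assert w["lonely"] == 0.0
        assert w["c"] == 3.0

    def test_matches_adjacency_sum_oracle(self, random_network):
        w = wnc(random_network)
        nodes = random_network.nodes
        adj = nx.to_numpy_array(random_network.graph, nodelist=nodes, weight="weight")
        want = pd.Series(adj.sum(axis=1), index=nodes).sort_index()
        assert np.allclose(w, want)

    def test_relabeling_equivariance(self, random_network):
        mapping = {g: f"x_{g}" for g in random_network.nodes}
        relabeled = CoexpressionNetwork(
            nx.relabel_nodes(random_network.graph, mapping),
            random_network.modules.rename(index=mapping))
        w1, w2 = wnc(random_network), wnc(relabeled)
        assert np.allclose(w1.to_numpy(), w2.rename(
            index={v: k for k, v in mapping.items()}).loc[w1.index].to_numpy())


class TestEnrichment:
    def test_p_equals_exhaustive_enumeration(self):
        universe = {f"g{i}" for i in range(20)}
        module = {f"g{i}" for i in range(5)}
        gene_list = ["g0", "g1", "g2", "g3", "g10"]  # overlap 4
        modules = {g: (0 if g in module else 1) for g in universe}
        net = build_network([], modules)
        res = module_enrichment(gene_list, net).set_index("module")
        want = hypergeom_enrichment_p(universe, module, set(gene_list))
        assert res.loc[0, "observed"] == 4
        assert res.loc[0, "pvalue"] == pytest.approx(want, rel=1e-9)

    def test_module_equal_to_universe_forces_p_one(self):
        modules = {f"g{i}": 0 for i in range(10)}
        net = build_network([], modules)
        res = module_enrichment(["g0", "g1"], net)
        assert res["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_observed_equal_expected_gives_zero_lfc(self):
        modules = {f"g{i}": i % 2 for i in range(10)}  # two modules of 5
        net = build_network([], modules)
        res = module_enrichment([f"g{i}" for i in range(0, 4)], net)
        even = res[res["module"] == 0].iloc[0]
        assert even["observed"] == 2 and even["expected"] == 2
        assert even["log2_obs_exp"] == 0.0

    def test_empty_list_observes_nothing(self):
        net = build_network([], {f"g{i}": i % 2 for i in range(6)})
        res = module_enrichment([], net)
        assert (res["observed"] == 0).all()

    def test_gene_outside_universe_rejected(self):
        net = build_network([], {"a": 0, "b": 1})
        with pytest.raises(ValueError, match="outside"):
            module_enrichment(["zzz"], net)


class TestBootstrap:
    def test_whole_universe_gives_p_one(self, random_network):
        obs, p = centrality_bootstrap(random_network, random_network.nodes,
                                      n_boot=100, seed=1)
        assert p == 1.0

    def test_planted_hub_set_is_extreme(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(300)]
        edges = []
        for _ in range(2000):
            i, j = rng.integers(0, 300, 2)
            if i != j:
                w = 10.0 if min(i, j) < 10 else 0.1
                edges.append((genes[i], genes[j], w))
        net = build_network(edges, {g: 0 for g in genes})
        obs, p = centrality_bootstrap(net, genes[:10], n_boot=10_000, seed=3)
        assert p <= 0.001

    def test_default_draw_count_and_determinism(self, random_network):
        import inspect
        assert inspect.signature(centrality_bootstrap).parameters["n_boot"].default == 10_000
        r1 = centrality_bootstrap(random_network, ["g0", "g1"], n_boot=500, seed=9)
        r2 = centrality_bootstrap(random_network, ["g0", "g1"], n_boot=500, seed=9)
        assert r1 == r2

    def test_oversized_gene_set_rejected(self, random_network):
        with pytest.raises(ValueError):
            centrality_bootstrap(random_network, random_network.nodes * 2, n_boot=10)

    def test_p_values_roughly_uniform_on_random_sets(self, random_network):
        rng = np.random.default_rng(5)
        w = wnc(random_network)
        ps = []
        for i in range(200):
            genes = list(rng.choice(random_network.nodes, size=8, replace=False))
            ps.append(centrality_bootstrap(random_network, genes, n_boot=500,
                                           seed=1000 + i, wnc_values=w)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.001


class TestMaxEdge:
    def test_known_small_cases(self):
        net = build_network([("d1", "a", 0.2), ("d2", "a", 0.7), ("d1", "b", 0.3)],
                            {"d1": 0, "d2": 0, "a": 0, "b": 0, "c": 0})
        w = max_edge_to_set(net, ["d1", "d2"])
        assert w["a"] == 0.7 and w["b"] == 0.3 and w["c"] == 0.0
        assert "d1" not in w.index

    def test_matches_exhaustive_scan(self, random_network):
        deleted = ["g0", "g5", "g17"]
        got = max_edge_to_set(random_network, deleted)
        for gene in got.index:
            best = 0.0
            for d in deleted:
                if random_network.graph.has_edge(gene, d):
                    best = max(best, random_network.graph[gene][d]["weight"])
            assert got[gene] == best


class TestLogistic:
    def test_null_has_flat_slope_and_tiny_pseudo_r2(self):
        rng = np.random.default_rng(7)
        w = pd.Series(rng.random(3000))
        y = pd.Series(rng.integers(0, 2, 3000), index=w.index)
        res = logistic_connectivity(w, y)
        assert res.pseudo_r2 < 0.01
        table = adjust_regressions([res])
        assert not table["Significant"].iloc[0]

    def test_slope_recovery_matches_numerical_mle(self):
        rng = np.random.default_rng(8)
        x = rng.random(5000)
        p = 1 / (1 + np.exp(-(-1 + 5 * x)))
        y = (rng.random(5000) < p).astype(int)
        res = logistic_connectivity(pd.Series(x), pd.Series(y))
        i0, s0, ll0 = logistic_mle(x, y)
        assert res.coef == pytest.approx(s0, abs=1e-4)
        # truth (5) inside the Wald 95% interval implied by the reported p
        z = stats.norm.isf(res.pvalue / 2)
        se = res.coef / z
        assert abs(res.coef - 5.0) < 1.96 * se
        fit_ll = -_logistic_negll(res, x, y)
        assert abs(fit_ll - ll0) < 1e-6

    def test_degenerate_design_is_flagged(self):
        w = pd.Series(np.zeros(50))
        y = pd.Series(np.r_[np.ones(25), np.zeros(25)], index=w.index)
        res = logistic_connectivity(w, y)
        assert res.separation
        assert res.pseudo_r2 == 0.0

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError, match="positive and one negative"):
            logistic_connectivity(pd.Series([0.1, 0.2]), pd.Series([1, 1]))


def _logistic_negll(res, x, y):
    # reconstruct the fitted log-likelihood from the reported coefficient
    # and a refit intercept (profile at the reported slope)
    from scipy.optimize import minimize_scalar

    def nll(b0):
        eta = b0 + res.coef * x
        return float(np.sum(np.logaddexp(0, eta)) - np.sum(y * eta))

    return minimize_scalar(nll, bounds=(-10, 10), method="bounded",
                           options={"xatol": 1e-12}).fun


class TestExcludeRerun:
    def test_excluding_isolated_gene_is_a_noop(self, random_network):
        net = random_network.copy()
        net.graph.add_node("iso_del")
        net.modules = pd.concat([net.modules, pd.Series({"iso_del": 0})])
        deleted = ["iso_del", "g0"]
        rng = np.random.default_rng(10)
        w = max_edge_to_set(net, deleted)
        y = pd.Series(rng.integers(0, 2, len(w)), index=w.index)
        base = logistic_connectivity(w, y)
        rerun = exclude_and_rerun(net, "iso_del", deleted, y)
        assert rerun.coef == pytest.approx(base.coef)
        assert rerun.pvalue == pytest.approx(base.pvalue)

    def test_missing_gene_rejected(self, random_network):
        with pytest.raises(ValueError, match="absent"):
            exclude_and_rerun(random_network, "nope", ["nope"], pd.Series(dtype=float))


class TestFilterDensity:
    def test_round_target_keeps_exact_edge_count(self):
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(10)]
        edges = [(genes[i], genes[j], float(rng.random()))
                 for i in range(10) for j in range(i + 1, 10)]
        net = build_network(edges, {g: 0 for g in genes})
        filtered = filter_density(net, 2.15)
        assert filtered.graph.number_of_edges() == 22  # round(21.5)
        kept = sorted(w for _, _, w in filtered.graph.edges(data="weight"))
        want = sorted(w for _, _, w in edges)[-22:]
        assert np.allclose(kept, want)

    def test_sparser_graph_unchanged(self):
        net = build_network([("a", "b", 1.0)], {"a": 0, "b": 0, "c": 0})
        filtered = filter_density(net, 2.15)
        assert filtered.graph.number_of_edges() == 1
        assert set(filtered.graph.nodes) == {"a", "b", "c"}

    def test_isolated_nodes_dropped_after_filtering(self):
        edges = [("a", "b", 0.9), ("c", "d", 0.1), ("a", "c", 0.8), ("b", "d", 0.7)]
        net = build_network(edges, {g: 0 for g in "abcd"})
        filtered = filter_density(net, 0.5)  # keep round(2) = 2 edges
        assert filtered.graph.number_of_edges() == 2
        assert all(filtered.graph.degree(n) > 0 for n in filtered.graph.nodes)
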
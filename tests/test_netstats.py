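import networkx as nx
import numpy as np
import pytest

from metanet.chronology import assign_all_ages
from metanet.netbuild import build_bipartite, slice_by_age
from metanet.netstats import (
    MetricsConfig,
    bartels_rank_test,
    centralities,
    ck_scaling,
    degree_diameter,
    er_random_graph,
    fast_greedy_modularity,
    fit_power_law,
    metrics_timeline,
    sample_discrete_power_law,
    small_world,
)


def ravasz_graph(levels: int = 3) -> nx.Graph:
    """Deterministic hierarchical-modular graph (K5 seed, 4 replicas/level).

    Peripheral nodes of each replica attach to the master hub, producing
    the C(k) ~ k^-1 clustering-degree scaling used as the oracle.
    """
    g = nx.complete_graph(5)  # node 0 = hub, 1..4 peripheral
    periph = [1, 2, 3, 4]
    for _ in range(levels - 1):
        template = g.copy()
        new_periph = []
        for _r in range(4):
            off = g.number_of_nodes()
            g = nx.union(g, nx.relabel_nodes(template, {v: v + off for v in template}))
            new_periph += [p + off for p in periph]
        for p in new_periph:
            g.add_edge(0, p)
        periph = new_periph
    return g


class TestDegreeDiameter:
    @pytest.mark.parametrize(
        "graph,avg,diam",
        [
            (nx.path_graph(4), 1.5, 3),
            (nx.cycle_graph(5), 2.0, 2),
            (nx.star_graph(5), 10 / 6, 2),
        ],
    )
    def test_small_graph_values(self, graph, avg, diam):
        a, d = degree_diameter(graph)
        assert a == pytest.approx(avg)
        assert d == diam

    def test_empty_graph_is_error(self):
        with pytest.raises(ValueError):
            degree_diameter(nx.Graph())


class TestPowerLaw:
    def test_recovers_exponent_and_accepts_true_law(self):
        rng = np.random.default_rng(0)
        x = sample_discrete_power_law(2.5, 1, 5000, rng)
        fit = fit_power_law(x, reps=100, seed=0)
        assert abs(fit.alpha - 2.5) < 0.1
        assert fit.ks_p > 0.05

    def test_agrees_with_igraph_plfit(self):
        ig = pytest.importorskip("igraph")
        rng = np.random.default_rng(3)
        x = sample_discrete_power_law(2.3, 1, 4000, rng)
        mine = fit_power_law(x, pvalue_method="none", xmin=1)
        ref = ig.power_law_fit(list(map(int, x)), xmin=1)
        assert mine.alpha == pytest.approx(ref.alpha, abs=5e-3)

    def test_rejects_geometric_sample(self):
        rng = np.random.default_rng(1)
        geom = rng.geometric(0.35, 5000)
        fit = fit_power_law(geom, reps=100, seed=1, xmin=1)
        assert fit.ks_p < 0.05

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            fit_power_law([3] * 100, pvalue_method="none")
        with pytest.raises(ValueError):
            fit_power_law([1, 2, 0, 4], pvalue_method="none")

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        x = sample_discrete_power_law(2.2, 1, 800, rng)
        a = fit_power_law(x, reps=20, seed=5)
        b = fit_power_law(x, reps=20, seed=5)
        assert (a.alpha, a.xmin, a.ks_p) == (b.alpha, b.xmin, b.ks_p)


class TestBartels:
    def test_monotone_series_hand_computed_rvn(self):
        res = bartels_rank_test(list(range(1, 11)))
        # numerator 9 (unit steps), denominator 82.5
        assert res.rvn == pytest.approx(9 / 82.5)
        assert res.statistic < -3
        assert res.p_value < 0.01

    def test_null_expectation_of_rvn_is_two(self):
        rng = np.random.default_rng(0)
        base = np.arange(1, 51, dtype=float)
        rvns = [bartels_rank_test(rng.permutation(base)).rvn for _ in range(1000)]
        assert abs(np.mean(rvns) - 2.0) < 0.05

    def test_beta_p_matches_permutation_p(self):
        rng = np.random.default_rng(7)
        series = rng.normal(size=30)
        res = bartels_rank_test(series)
        stat_obs = abs(res.rvn - 2.0)
        perm = np.array(
            [
                abs(bartels_rank_test(rng.permutation(series)).rvn - 2.0)
                for _ in range(10_000)
            ]
        )
        p_perm = float(np.mean(perm >= stat_obs - 1e-12))
        assert abs(res.p_value - p_perm) < 0.02

    def test_guard_conditions(self):
        with pytest.raises(ValueError):
            bartels_rank_test([1.0] * 20)
        with pytest.raises(ValueError):
            bartels_rank_test([1, 2, 3])


class TestErGraph:
    def test_saturated_m_gives_complete_graph(self):
        g = er_random_graph(5, 10, seed=0)
        assert g.number_of_edges() == 10

    def test_zero_edges(self):
        assert er_random_graph(10, 0, seed=0).number_of_edges() == 0

    def test_edge_count_exact_across_seeds(self):
        assert all(er_random_graph(30, 44, seed=s).number_of_edges() == 44 for s in range(100))

    def test_out_of_range_m(self):
        with pytest.raises(ValueError):
            er_random_graph(4, 7)


class TestSmallWorld:
    def test_er_self_comparison_near_one(self):
        g = er_random_graph(300, 1500, seed=7)
        sw = small_world(g, n_rand=20, seed=2)
        assert 0.8 < sw.s < 1.2

    def test_watts_strogatz_is_small_world(self):
        ws = nx.watts_strogatz_graph(500, 10, 0.05, seed=42)
        sw = small_world(ws, n_rand=20, seed=1)
        assert sw.s > 2

    def test_complete_graph_limits(self):
        sw = small_world(nx.complete_graph(10), n_rand=5, seed=0)
        assert sw.c_g == pytest.approx(1.0)
        assert sw.l_g == pytest.approx(1.0)
        assert sw.s == pytest.approx(sw.gamma / sw.lam)

    def test_bipartite_input_rejected(self, toy_dataset, toy_ages):
        b = build_bipartite(toy_dataset, toy_ages, "subnetwork")
        with pytest.raises(ValueError, match="two-mode"):
            small_world(b)


def _exhaustive_best_modularity(g: nx.Graph) -> float:
    """Brute-force max modularity over all partitions (tiny graphs only)."""
    nodes = list(g.nodes)
    best = -1.0

    def partitions(seq):
        if not seq:
            yield []
            return
        first, rest = seq[0], seq[1:]
        for smaller in partitions(rest):
            for i, block in enumerate(smaller):
                yield smaller[:i] + [block + [first]] + smaller[i + 1:]
            yield [[first]] + smaller

    for part in partitions(nodes):
        q = nx.community.modularity(g, [set(b) for b in part])
        best = max(best, q)
    return best


class TestModularity:
    def two_triangles(self) -> nx.Graph:
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])
        return g

    def test_two_triangles_reach_exhaustive_optimum(self):
        g = self.two_triangles()
        res = fast_greedy_modularity(g)
        assert res.q == pytest.approx(5 / 14)
        assert res.q == pytest.approx(_exhaustive_best_modularity(g))
        comms = {}
        for node, c in res.membership.items():
            comms.setdefault(c, set()).add(node)
        assert sorted(map(frozenset, comms.values()), key=len) == [
            frozenset({0, 1, 2}),
            frozenset({3, 4, 5}),
        ]

    def test_single_community_on_complete_graph(self):
        res = fast_greedy_modularity(nx.complete_graph(5))
        assert res.q == pytest.approx(0.0)
        assert len(set(res.membership.values())) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_q_matches_definition_on_random_fixtures(self, seed):
        g = nx.gnm_random_graph(20, 40, seed=seed)
        if g.number_of_edges() == 0:
            return
        res = fast_greedy_modularity(g)
        comms = {}
        for node, c in res.membership.items():
            comms.setdefault(c, set()).add(node)
        q_def = nx.community.modularity(g, list(comms.values()))
        assert res.q == pytest.approx(q_def, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_never_exceeds_exhaustive_optimum(self, seed):
        g = nx.gnm_random_graph(7, 12, seed=seed)
        if g.number_of_edges() == 0:
            return
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        res = fast_greedy_modularity(g)
        assert res.q <= _exhaustive_best_modularity(g) + 1e-9

    def test_edgeless_graph_is_error(self):
        with pytest.raises(ValueError):
            fast_greedy_modularity(nx.empty_graph(4))


class TestCkScaling:
    def test_hierarchical_graph_scales_as_inverse_k(self):
        fit = ck_scaling(ravasz_graph(3))
        assert abs(fit.slope - (-1.0)) < 0.25
        assert fit.r2 > 0.9

    def test_complete_graph_is_flat(self):
        fit = ck_scaling(nx.complete_graph(8))
        assert fit.slope == 0.0

    def test_tree_has_no_clustering_classes(self):
        with pytest.raises(ValueError):
            ck_scaling(nx.balanced_tree(2, 4))


class TestCentralities:
    def test_star_center_tops_all_metrics(self):
        g = nx.star_graph(6)  # center node 0
        cent = centralities(g, k=3)
        assert all(cent.top[m][0] == 0 for m in ("degree", "betweenness", "closeness"))

    def test_path_middle_betweenness_pair_count(self):
        g = nx.path_graph(5)  # 0-1-2-3-4
        cent = centralities(g)
        assert cent.table.loc[2, "betweenness"] == pytest.approx(4.0)

    def test_symmetric_tie_broken_lexicographically(self):
        g = nx.Graph([("a", "c"), ("b", "c")])  # a and b symmetric
        cent = centralities(g, k=3)
        assert cent.top["degree"] == ["c", "a", "b"]

    def test_closeness_is_inverse_mean_distance(self):
        g = nx.path_graph(4)
        cent = centralities(g)
        # node 1: distances 1,1,2 -> closeness 3/4
        assert cent.table.loc[1, "closeness"] == pytest.approx(3 / 4)


@pytest.fixture(scope="module")
def timeline(small_sim):
    ages = assign_all_ages(small_sim)
    b = build_bipartite(small_sim, ages, "subnetwork")
    slices = [slice_by_age(b, round(0.1 * i, 1)) for i in range(1, 11)]
    cfg = MetricsConfig(seed=0, n_rand=3, bootstrap_reps=5)
    return metrics_timeline(slices, cfg)


class TestMetricsTimeline:
    def test_all_graph_types_present_at_every_threshold(self, timeline):
        counts = timeline.groupby("graph_type")["nd"].count()
        assert set(counts.index) == {"bipartite", "category_projection", "enzyme_projection"}
        assert (counts == 10).all()

    def test_bipartite_rows_skip_clustering_fields(self, timeline):
        bip = timeline[timeline["graph_type"] == "bipartite"]
        assert bip["c_g"].isna().all()
        assert bip["s"].isna().all()

    def test_enzyme_clustering_rises_with_time(self, timeline):
        from scipy.stats import spearmanr

        enz = timeline[timeline["graph_type"] == "enzyme_projection"].dropna(subset=["c_g"])
        rho = spearmanr(enz["nd"], enz["c_g"]).statistic
        assert rho > 0

    def test_single_slice_gives_single_row_per_type(self, small_sim):
        ages = assign_all_ages(small_sim)
        b = build_bipartite(small_sim, ages, "subnetwork")
        cfg = MetricsConfig(seed=0, n_rand=2, pvalue_method="none")
        df = metrics_timeline([slice_by_age(b, 0.1)], cfg)
        assert len(df) == 3
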
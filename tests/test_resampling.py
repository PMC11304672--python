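import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from telesna import (
    bootstrap_global_ci,
    bootstrap_network,
    bootstrap_node_ci,
    ci_width_vs_samplesize,
    split_half_calibration,
    subsample_distribution,
    subsample_network,
)
from telesna.metrics import global_metrics
from telesna.resampling import _percentile_ci, level_to_m
from telesna.simulate import random_weighted_network


def k4():
    g = nx.Graph()
    for u, v in itertools.combinations("abcd", 2):
        g.add_edge(u, v, weight=1.0)
    return g


def two_node_edge(w=0.6):
    g = nx.Graph()
    g.add_edge("A", "B", weight=w)
    return g


class TestSubsampling:
    def test_full_level_is_identity(self, gnp40, rng):
        sub = subsample_network(gnp40, 40, rng)
        assert nx.utils.graphs_equal(sub, gnp40)

    def test_single_node(self, gnp40, rng):
        sub = subsample_network(gnp40, 1, rng)
        assert sub.number_of_nodes() == 1 and sub.number_of_edges() == 0

    def test_complete_graph_induced(self, rng):
        sub = subsample_network(k4(), 2, rng)
        assert sub.number_of_nodes() == 2 and sub.number_of_edges() == 1

    def test_out_of_range_m(self, rng):
        with pytest.raises(ValueError):
            subsample_network(k4(), 5, rng)
        with pytest.raises(ValueError):
            subsample_network(k4(), 0, rng)

    def test_level_one_distribution_equals_observed(self, gnp40, rng):
        tab = subsample_distribution(gnp40, [1.0], n_rep=5, rng=rng)
        assert (tab["value"] == tab["observed"]).all()

    @pytest.mark.parametrize("m", [2, 3, 4, 5])
    def test_exhaustive_density_unbiased_and_strength_linear(self, m):
        """Over ALL induced m-subgraphs of a 6-node weighted graph, the
        mean density equals the full density exactly and the mean of
        mean-strength equals (m-1)/5 x the full mean strength."""
        for seed in range(5):
            g = random_weighted_network(6, 0.6, seed=seed)
            full = global_metrics(g, {"density", "mean_strength"})
            nodes = sorted(g.nodes())
            dens, ms = [], []
            for keep in itertools.combinations(nodes, m):
                gm = global_metrics(g.subgraph(keep), {"density", "mean_strength"})
                dens.append(gm["density"])
                ms.append(gm["mean_strength"])
            assert np.mean(dens) == pytest.approx(full["density"], abs=1e-12)
            assert np.mean(ms) == pytest.approx(
                (m - 1) / 5 * full["mean_strength"], abs=1e-12)

    def test_subsampled_complete_graph_diameter_is_one(self, rng):
        for m in (2, 3, 4):
            assert global_metrics(subsample_network(k4(), m, rng), {"diameter"})["diameter"] == 1


class TestBootstrapNetwork:
    def test_replicate_has_n_nodes_no_self_loops(self, gnp40, rng):
        rep = bootstrap_network(gnp40, rng)
        assert rep.number_of_nodes() == 40
        assert nx.number_of_selfloops(rep) == 0

    def test_all_distinct_draws_reconstruct_original(self, rng):
        g = random_weighted_network(5, 0.5, seed=3)
        found = 0
        for _ in range(200):
            rep = bootstrap_network(g, rng)
            originals = [rep.nodes[c]["original"] for c in rep.nodes()]
            if len(set(originals)) < 5:
                continue
            found += 1
            mapped = nx.relabel_nodes(rep, {c: rep.nodes[c]["original"] for c in rep.nodes()})
            assert nx.utils.graphs_equal(
                nx.Graph([(u, v, {"weight": d["weight"]}) for u, v, d in mapped.edges(data=True)]),
                nx.Graph([(u, v, {"weight": d["weight"]}) for u, v, d in g.edges(data=True)]),
            )
        assert found > 0  # P(all distinct) = 5!/5^5 ~ 0.038

    def test_duplicate_pair_edge_weight_from_single_edge_network(self, rng):
        g = two_node_edge(0.6)
        seen_dup = False
        for _ in range(50):
            rep = bootstrap_network(g, rng)
            originals = [rep.nodes[c]["original"] for c in rep.nodes()]
            if len(set(originals)) == 1:
                seen_dup = True
                (u, v, d), = rep.edges(data=True)
                assert d["weight"] == 0.6  # only original edge to draw from
        assert seen_dup

    def test_edgeless_network_replicates_edgeless(self, rng):
        g = nx.Graph()
        g.add_nodes_from("abcd")
        for _ in range(10):
            assert bootstrap_network(g, rng).number_of_edges() == 0

    def test_multiplicities_multinomial(self, rng):
        """Node-copy counts across replicates follow multinomial(N, 1/N)."""
        g = random_weighted_network(10, 0.3, seed=1)
        counts = {v: 0 for v in g.nodes()}
        n_rep = 500
        for _ in range(n_rep):
            rep = bootstrap_network(g, rng)
            for c in rep.nodes():
                counts[rep.nodes[c]["original"]] += 1
        observed = np.array(list(counts.values()), dtype=float)
        expected = np.full(10, n_rep)
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, df=9) > 0.001


class TestGlobalCI:
    def test_percentile_matches_independent_formula(self):
        values = np.arange(1.0, 1001.0)
        lo, hi, n = _percentile_ci(values, 0.95)
        # independent type-7 interpolation: h = (n-1)q + 1 (1-based rank)
        def type7(q):
            h = (len(values) - 1) * q
            f = int(np.floor(h))
            return values[f] + (h - f) * (values[min(f + 1, len(values) - 1)] - values[f])
        assert lo == pytest.approx(type7(0.025))
        assert hi == pytest.approx(type7(0.975))
        assert n == 1000

    def test_constant_replicates_give_degenerate_interval(self, rng):
        ci = bootstrap_global_ci(k4(), B=50, metrics={"density"}, rng=rng)
        row = ci.iloc[0]
        assert (row["lower"], row["upper"]) == (1.0, 1.0)

    def test_observed_density_inside_own_ci_usually(self):
        """Non-degenerate coverage on a homogeneous random network."""
        inside = 0
        n_runs = 10
        for seed in range(n_runs):
            g = random_weighted_network(40, 0.2, seed=seed)
            obs = global_metrics(g, {"density"})["density"]
            ci = bootstrap_global_ci(g, B=200, metrics={"density"},
                                     rng=np.random.default_rng(seed + 100))
            row = ci.iloc[0]
            if row["lower"] <= obs <= row["upper"]:
                inside += 1
        assert inside >= 0.8 * n_runs

    def test_na_replicates_excluded(self, rng):
        # 2-node single-edge network: transitivity undefined in most replicates
        ci = bootstrap_global_ci(two_node_edge(), B=30, metrics={"transitivity"}, rng=rng)
        assert ci["n_effective"].iloc[0] <= 30


class TestCIWidth:
    def test_size_equals_n_uses_whole_network(self, rng):
        g = random_weighted_network(15, 0.3, seed=4)
        tab = ci_width_vs_samplesize(g, sizes=[15], B=100, metrics={"density"},
                                     n_outer=3, rng=rng)
        assert len(tab) == 1
        assert tab["mean_width"].iloc[0] >= 0

    def test_table_shape(self, rng):
        g = random_weighted_network(20, 0.3, seed=5)
        tab = ci_width_vs_samplesize(g, sizes=[8, 20], B=50,
                                     metrics={"density", "transitivity"},
                                     n_outer=2, rng=rng)
        assert len(tab) == 4

    def test_scaled_variants_substituted(self, rng):
        g = random_weighted_network(12, 0.4, seed=6)
        tab = ci_width_vs_samplesize(g, sizes=[12], B=50,
                                     metrics={"mean_strength", "diameter"},
                                     n_outer=1, rng=rng)
        assert set(tab["metric"]) == {"scaled_mean_strength", "scaled_diameter"}


class TestSplitHalf:
    def test_single_trial_proportion_in_unit_set(self, rng):
        g = random_weighted_network(20, 0.4, seed=2)
        p = split_half_calibration(g, B=50, metric="density", n_trials=1, rng=rng)
        assert p in (0.0, 1.0)

    def test_needs_four_nodes(self, rng):
        with pytest.raises(ValueError):
            split_half_calibration(two_node_edge(), B=10, n_trials=1, rng=rng)

    def test_homogeneous_halves_mostly_overlap(self, rng):
        g = random_weighted_network(40, 0.2, seed=9)
        p = split_half_calibration(g, B=100, metric="density", n_trials=15, rng=rng)
        assert p >= 0.8


class TestNodeCI:
    def test_two_node_degree_ci_is_one_one(self, rng):
        """All replicates of a 2-node 1-edge network give each present
        node degree 1 ({A,B}: the edge; {A,A}/{B,B}: the drawn copy-pair
        edge), so the CI collapses to [1, 1]."""
        tab = bootstrap_node_ci(two_node_edge(), B=100, metrics={"degree"}, rng=rng)
        for _, row in tab.iterrows():
            assert (row["lower"], row["upper"]) == (1.0, 1.0)
            assert 0 < row["n_effective"] < 100

    def test_edgeless_network_strength_ci_zero(self, rng):
        g = nx.Graph()
        g.add_nodes_from("abcde")
        tab = bootstrap_node_ci(g, B=50, metrics={"strength"}, rng=rng)
        assert (tab["lower"] == 0).all() and (tab["upper"] == 0).all()

    def test_sorted_by_decreasing_observed(self, gnp40, rng):
        tab = bootstrap_node_ci(gnp40, B=30, metrics={"degree", "strength"}, rng=rng)
        for _, grp in tab.groupby("metric"):
            assert grp["observed"].is_monotonic_decreasing

    def test_absence_rate_near_expected(self, rng):
        """P(node absent from a replicate) = (1 - 1/N)^N ~ 0.37."""
        g = random_weighted_network(20, 0.3, seed=8)
        B = 300
        tab = bootstrap_node_ci(g, B=B, metrics={"degree"}, rng=rng)
        rate = 1 - tab["n_effective"].mean() / B
        assert rate == pytest.approx((1 - 1 / 20) ** 20, abs=0.06)
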
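import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from telesna import (
    Thresholds,
    build_network,
    compute_associations,
    find_joint_observations,
    make_dataset,
    network_from_associations,
    read_edgelist_csv,
    read_graphml,
    suggest_spatial_threshold,
    sweep_thresholds,
    write_edgelist_csv,
    write_graphml,
)

from _oracles import brute_force_sri
from conftest import ts


def dyad_dataset(times_a, times_b, coords_a=None, coords_b=None):
    """Two-animal dataset from lists of minute offsets (+ optional coords)."""
    base = pd.Timestamp("2024-01-01T09:00:00Z")
    coords_a = coords_a or [(0.0, 0.0)] * len(times_a)
    coords_b = coords_b or [(0.0, 0.0)] * len(times_b)
    rows = [("A", (base + pd.Timedelta(minutes=m)).isoformat(), x, y)
            for m, (x, y) in zip(times_a, coords_a)]
    rows += [("B", (base + pd.Timedelta(minutes=m)).isoformat(), x, y)
             for m, (x, y) in zip(times_b, coords_b)]
    return make_dataset(ts(*rows))


class TestJointObservations:
    def test_fix_at_edge_of_window_included(self):
        # a 09:57 fix is matched against the other animal's fixes up to 10:04
        ds = dyad_dataset([57], [64])
        jo = find_joint_observations(ds, t=7)
        assert len(jo) == 1
        assert jo["dt_min"].iloc[0] == pytest.approx(7.0)

    def test_fix_outside_window_excluded(self):
        ds = dyad_dataset([57], [65])
        assert find_joint_observations(ds, t=7).empty

    def test_one_to_one_matching_prefers_smallest_dt(self):
        # A at 10:00 & 10:10, B at 10:03: B's single fix pairs with 10:00 only
        ds = dyad_dataset([60, 70], [63])
        jo = find_joint_observations(ds, t=7)
        assert len(jo) == 1
        assert jo["dt_min"].iloc[0] == pytest.approx(3.0)
        assert jo["t_a"].iloc[0] == pd.Timestamp("2024-01-01T10:00:00Z")

    def test_all_pairs_matching_counts_every_candidate(self):
        ds = dyad_dataset([60, 70], [63])
        jo = find_joint_observations(ds, t=7, matching="all_pairs")
        assert len(jo) == 2

    def test_denominator_bounded_by_fix_counts(self, planted_sim):
        ds, _ = planted_sim
        jo = find_joint_observations(ds, t=7)
        counts = ds.fixes["animal_id"].value_counts()
        per_dyad = jo.groupby(["animal_a", "animal_b"]).size()
        for (a, b), n in per_dyad.items():
            assert n <= min(counts[a], counts[b])


class TestAssociations:
    def test_sri_direct_evaluation(self):
        ds = dyad_dataset(
            [0, 60, 120], [1, 61, 121],
            coords_b=[(5.0, 0.0), (20.0, 0.0), (400.0, 0.0)],
        )
        tab = compute_associations(find_joint_observations(ds, t=7), s=15)
        row = tab.iloc[0]
        assert (row["x_ab"], row["y_ab"]) == (1, 2)
        assert row["sri"] == pytest.approx(1 / 3)

    def test_never_together_gives_no_edge(self):
        ds = dyad_dataset([0, 60], [1, 61], coords_b=[(100, 0), (100, 0)])
        net = build_network(ds, Thresholds(s=15, t=7))
        assert net.number_of_edges() == 0
        assert net.number_of_nodes() == 2

    def test_always_together_gives_sri_one(self):
        ds = dyad_dataset([0, 60], [1, 61], coords_b=[(1, 0), (2, 0)])
        tab = compute_associations(find_joint_observations(ds, t=7), s=15)
        assert tab["sri"].iloc[0] == 1.0

    def test_min_denominator_filter(self):
        ds = dyad_dataset([0], [1])
        jo = find_joint_observations(ds, t=7)
        assert len(compute_associations(jo, s=15, min_denominator=2)) == 0


class TestBruteForceOracle:
    """Dyadic counts and SRI match an independent brute-force matcher
    on small random datasets (<= 4 animals x <= 12 fixes, coarse grids
    so that ties and duplicates occur)."""

    @pytest.mark.parametrize("seed", range(30))
    def test_counts_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_animals = int(rng.integers(2, 5))
        base = pd.Timestamp("2024-01-01T00:00:00Z")
        fixes = {}
        rows = []
        for i in range(n_animals):
            a = f"A{i}"
            n_fix = int(rng.integers(1, 13))
            times = sorted(set(rng.integers(0, 40, size=n_fix) * 5))  # 5-min grid
            pts = [(float(rng.integers(0, 6) * 10), float(rng.integers(0, 6) * 10))
                   for _ in times]
            fixes[a] = [(float(t), x, y) for t, (x, y) in zip(times, pts)]
            rows += [(a, (base + pd.Timedelta(minutes=int(t))).isoformat(), x, y)
                     for t, (x, y) in zip(times, pts)]
        ds = make_dataset(ts(*rows))
        t_thr, s_thr = 7.0, 15.0
        tab = compute_associations(find_joint_observations(ds, t_thr), s_thr)
        tab = tab.set_index(["animal_a", "animal_b"])
        for a, b in itertools.combinations(sorted(fixes), 2):
            x, y, sri = brute_force_sri(fixes[a], fixes[b], t_thr, s_thr)
            if x + y == 0:
                assert (a, b) not in tab.index
            else:
                row = tab.loc[(a, b)]
                assert (row["x_ab"], row["y_ab"]) == (x, y)
                assert row["sri"] == pytest.approx(sri)


class TestNetworkConstruction:
    def test_all_animals_are_nodes_even_if_isolated(self):
        base = "2024-01-01T10:0{}:00Z"
        ds = make_dataset(ts(
            ("A", base.format(0), 0, 0), ("B", base.format(1), 1, 0),
            ("C", "2024-06-01T00:00:00Z", 9999, 9999),
        ))
        net = build_network(ds, Thresholds())
        assert set(net.nodes()) == {"A", "B", "C"}
        assert net.number_of_edges() == 1
        assert net["A"]["B"]["weight"] == 1.0

    def test_edge_weights_in_unit_interval(self, planted_net):
        weights = [d["weight"] for _, _, d in planted_net.edges(data=True)]
        assert weights and all(0 < w <= 1 for w in weights)

    def test_relabelling_yields_isomorphic_network(self, planted_sim):
        ds, _ = planted_sim
        net = build_network(ds, Thresholds())
        relabel = {a: f"Z{a}" for a in ds.animals}
        renamed = ds.with_fixes(ds.fixes.assign(
            animal_id=ds.fixes["animal_id"].map(relabel)))
        net2 = build_network(renamed, Thresholds())
        for u, v, d in net.edges(data=True):
            assert net2[relabel[u]][relabel[v]]["weight"] == pytest.approx(d["weight"])
        assert net2.number_of_edges() == net.number_of_edges()

    def test_within_group_dyads_associate_more(self, planted_sim, planted_net):
        _, truth = planted_sim
        sri = {tuple(sorted((u, v))): d["weight"]
               for u, v, d in planted_net.edges(data=True)}
        classes = truth.dyad_classes()
        vals = {
            cls: [sri.get((r.animal_a, r.animal_b), 0.0)
                  for r in grp.itertuples(index=False)]
            for cls, grp in classes.groupby("dyad_class")
        }
        assert np.mean(vals["within"]) > np.mean(vals["between"])

    def test_isolated_planted_groups_form_separate_components(self):
        from telesna import SimulationConfig, simulate_population

        cfg = SimulationConfig(n_individuals=10, n_groups=2, duration_days=10,
                               group_spacing_m=10_000, group_switch_prob=0.0, seed=2)
        ds, truth = simulate_population(cfg)
        net = build_network(ds, Thresholds())
        for u, v in net.edges():
            assert truth.same_group(u, v)
        comps = list(nx.connected_components(net))
        assert len(comps) >= 2
        for comp in comps:
            assert len({truth.group_assignment[v] for v in comp}) == 1

    def test_single_animal_network(self):
        ds = make_dataset(ts(("A", "2024-01-01T00:00:00Z", 0, 0)))
        net = build_network(ds, Thresholds())
        assert net.number_of_nodes() == 1 and net.number_of_edges() == 0


class TestSpatialThresholdSuggestion:
    def test_mixture_first_mode_near_10(self):
        rng = np.random.default_rng(5)
        n = 400
        d = np.where(rng.random(n) < 0.8,
                     np.abs(rng.normal(10, 2, n)), rng.uniform(0, 500, n))
        # place dyad fixes at exactly those distances, one pair per minute-slot
        times = np.arange(n) * 20.0
        ds = dyad_dataset(times.tolist(), (times + 1).tolist(),
                          coords_a=[(0.0, 0.0)] * n,
                          coords_b=[(float(x), 0.0) for x in d])
        s = suggest_spatial_threshold(ds, t=7, max_distance=500, bin_width=5)
        assert 5 <= s <= 15

    def test_degenerate_unimodal(self):
        ds = dyad_dataset([0, 20, 40], [1, 21, 41],
                          coords_b=[(12.0, 0.0)] * 3)
        s = suggest_spatial_threshold(ds, t=7, max_distance=100, bin_width=5)
        assert 10 <= s <= 15  # centre of the bin containing 12 m

    def test_no_joint_observations_is_error(self):
        ds = dyad_dataset([0], [500])
        with pytest.raises(ValueError, match="threshold undefined"):
            suggest_spatial_threshold(ds, t=7)


class TestThresholdSweep:
    def test_edges_monotone_in_s(self, planted_sim):
        ds, _ = planted_sim
        tab = sweep_thresholds(ds, s_values=[5, 15, 50], t_values=[7])
        assert tab["n_edges"].is_monotonic_increasing

    def test_single_combination_matches_direct_build(self, planted_sim):
        ds, _ = planted_sim
        tab = sweep_thresholds(ds, [15], [7])
        net = build_network(ds, Thresholds(15, 7))
        assert tab["n_edges"].iloc[0] == net.number_of_edges()

    def test_joint_obs_non_decreasing_in_t(self):
        ds = dyad_dataset([0, 30, 60], [5, 42, 61])
        n5 = len(find_joint_observations(ds, t=5))
        n15 = len(find_joint_observations(ds, t=15))
        assert n5 <= n15
        assert n15 == 3


class TestNetworkIO:
    def test_graphml_roundtrip(self, tmp_path, planted_net):
        p = tmp_path / "net.graphml"
        write_graphml(planted_net, p)
        back = read_graphml(p)
        assert set(back.nodes()) == set(planted_net.nodes())
        for u, v, d in planted_net.edges(data=True):
            assert back[u][v]["weight"] == pytest.approx(d["weight"])

    def test_edgelist_roundtrip_keeps_isolates(self, tmp_path):
        net = nx.Graph()
        net.add_nodes_from(["A", "B", "C"])
        net.add_edge("A", "B", weight=0.5, x_ab=1, y_ab=1)
        write_edgelist_csv(net, tmp_path / "e.csv", tmp_path / "n.csv")
        back = read_edgelist_csv(tmp_path / "e.csv", tmp_path / "n.csv")
        assert set(back.nodes()) == {"A", "B", "C"}
        assert back["A"]["B"]["weight"] == 0.5
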
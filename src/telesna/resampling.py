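"""Node subsampling and node bootstrap for network metrics.

Three resampling schemes quantify how sampling effort affects inferred
network structure:

* **Subsampling** draws m of the N tagged animals without replacement
  and keeps the induced subnetwork — the network one would have obtained
  had only those m animals been tagged.  Repeating this across
  subsampling levels reveals which metrics are biased by incomplete
  tagging (induced-subgraph density is unbiased; mean strength shrinks
  linearly, with expectation (m-1)/(N-1) times the full value).
* **Node bootstrap** samples N nodes with replacement; each replicate
  network has exactly N node-copies.  Edges between copies of different
  originals are retained with their original weight; a pair of copies of
  the same original is connected by an edge drawn uniformly from the
  original edge list.  Percentile intervals over replicate metric values
  give confidence intervals for global and node-level metrics.
* **Split-half calibration** bootstraps two disjoint random halves of
  the node set; their confidence intervals should overlap almost always
  when the network is homogeneous, showing the bootstrap does not
  manufacture spurious significance.

A caveat applies to sparse networks: never-observed dyads are resampled
as zeros in every replicate, so bootstrap intervals can understate the
uncertainty of very sparse networks; a warning is logged when the
density falls below 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .association import Thresholds, build_network
from .io import TelemetryDataset
from .metrics import (
    DEFAULT_GLOBAL_METRICS,
    NODE_METRICS,
    global_metrics,
    node_metrics,
)
from .permutation import permute_datastream

logger = logging.getLogger(__name__)

DEFAULT_LEVELS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


# --- Subsampling ----------------------------------------------------------

def subsample_network(net: nx.Graph, m: int, rng: np.random.Generator) -> nx.Graph:
    """Induced subgraph on m nodes drawn uniformly without replacement."""
    n = net.number_of_nodes()
    if not (1 <= m <= n):
        raise ValueError(f"subsample size m={m} out of range [1, {n}]")
    nodes = sorted(net.nodes())
    keep = [nodes[i] for i in rng.choice(n, size=m, replace=False)]
    return net.subgraph(keep).copy()


def level_to_m(level: float, n: int) -> int:
    if not (0 < level <= 1):
        raise ValueError(f"subsampling level must be in (0, 1], got {level}")
    return max(1, int(round(level * n)))


def subsample_distribution(
    net: nx.Graph,
    levels=DEFAULT_LEVELS,
    n_rep: int = 100,
    metrics: set[str] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Global-metric distributions across subsampling levels.

    Returns a tidy table (level, m, replicate, metric, value, observed)
    with ``n_rep`` induced-subgraph values per level and metric;
    m = max(1, round(level * N)).
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    metrics = set(metrics) if metrics is not None else set(DEFAULT_GLOBAL_METRICS)
    rng = rng if rng is not None else np.random.default_rng()
    observed = global_metrics(net, metrics)
    n = net.number_of_nodes()
    rows = []
    for level in levels:
        m = level_to_m(level, n)
        for rep in range(n_rep):
            gm = global_metrics(subsample_network(net, m, rng), metrics)
            for metric in sorted(metrics):
                rows.append(
                    {
                        "level": level, "m": m, "replicate": rep,
                        "metric": metric, "value": gm[metric],
                        "observed": observed[metric],
                    }
                )
    return pd.DataFrame(rows)


def permuted_subsample_comparison(
    ds: TelemetryDataset,
    thresholds: Thresholds,
    levels=DEFAULT_LEVELS,
    n_perm: int = 1000,
    n_rep: int = 100,
    metrics: set[str] | None = None,
    rng: np.random.Generator | None = None,
    **network_kw,
) -> pd.DataFrame:
    """Observed vs permuted subsample distributions, side by side.

    One subsample is drawn per permuted network per level (``n_perm``
    permuted values per level/metric), paired with ``n_rep`` subsamples
    of the observed network, for plotting the minimum sampling effort at
    which the observed network separates from random.  Output is tidy:
    (source, level, metric, value) with source in {observed, permuted}.
    """
    metrics = set(metrics) if metrics is not None else set(DEFAULT_GLOBAL_METRICS)
    rng = rng if rng is not None else np.random.default_rng()
    net = build_network(ds, thresholds, **network_kw)
    n = net.number_of_nodes()
    obs_tab = subsample_distribution(net, levels, n_rep, metrics, rng)
    rows = [
        {"source": "observed", "level": r.level, "metric": r.metric, "value": r.value}
        for r in obs_tab.itertuples(index=False)
    ]
    for child in rng.spawn(n_perm):
        pnet = build_network(permute_datastream(ds, child), thresholds, **network_kw)
        for level in levels:
            sub = subsample_network(pnet, level_to_m(level, n), child)
            gm = global_metrics(sub, metrics)
            for metric in sorted(metrics):
                rows.append(
                    {"source": "permuted", "level": level, "metric": metric, "value": gm[metric]}
                )
    return pd.DataFrame(rows)


# --- Node bootstrap -------------------------------------------------------

def bootstrap_network(
    net: nx.Graph,
    rng: np.random.Generator,
    dup_edge_rule: str = "always_draw",
) -> nx.Graph:
    """One node-bootstrap replicate.

    N node ids are sampled with replacement; the replicate has one node
    per draw (copies of the same original are distinct nodes named
    ``(original, k)``).  Edges between copies of different originals are
    retained iff the originals were adjacent, with the original weight.
    A pair of copies of the same original gets an edge drawn uniformly
    from the original edge list (``always_draw``, the default) or, under
    ``density_bernoulli``, is connected with probability equal to the
    original edge density, again with a uniformly drawn original weight.
    """
    if dup_edge_rule not in ("always_draw", "density_bernoulli"):
        raise ValueError(f"unknown dup_edge_rule {dup_edge_rule!r}")
    n = net.number_of_nodes()
    if n < 2:
        raise ValueError("bootstrap needs at least 2 nodes")
    nodes = sorted(net.nodes())
    edges = list(net.edges(data="weight"))
    if not edges:
        logger.warning("bootstrapping an edgeless network: duplicate copies get no edge")
    density = nx.density(net)
    draws = rng.choice(n, size=n, replace=True)
    copies = []  # (copy_id, original)
    seen: dict = {}
    for d in draws:
        orig = nodes[int(d)]
        k = seen.get(orig, 0)
        seen[orig] = k + 1
        copies.append(((orig, k), orig))
    rep = nx.Graph()
    for cid, orig in copies:
        rep.add_node(cid, original=orig)
    for i in range(len(copies)):
        ci, oi = copies[i]
        for j in range(i + 1, len(copies)):
            cj, oj = copies[j]
            if oi == oj:
                if not edges:
                    continue
                if dup_edge_rule == "density_bernoulli" and rng.random() >= density:
                    continue
                _, _, w = edges[int(rng.integers(len(edges)))]
                rep.add_edge(ci, cj, weight=float(w if w is not None else 1.0))
            elif net.has_edge(oi, oj):
                rep.add_edge(ci, cj, weight=float(net[oi][oj].get("weight", 1.0)))
    return rep


def _percentile_ci(values: np.ndarray, conf: float) -> tuple[float, float, int]:
    """Linear-interpolation (type-7) percentile interval over finite values."""
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        return np.nan, np.nan, 0
    alpha = (1.0 - conf) / 2.0
    lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
    return float(lo), float(hi), int(len(vals))


def bootstrap_global_ci(
    net: nx.Graph,
    B: int = 1000,
    metrics: set[str] | None = None,
    conf: float = 0.95,
    rng: np.random.Generator | None = None,
    dup_edge_rule: str = "always_draw",
    return_replicates: bool = False,
):
    """Percentile bootstrap confidence intervals for global metrics.

    Returns a DataFrame (metric, observed, lower, upper, conf,
    n_effective); NA replicate values are excluded with a logged tally.
    With ``return_replicates`` the per-replicate value table is returned
    as well.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    metrics = set(metrics) if metrics is not None else set(DEFAULT_GLOBAL_METRICS)
    rng = rng if rng is not None else np.random.default_rng()
    if net.number_of_nodes() >= 2 and nx.density(net) < 0.05:
        logger.warning(
            "network density %.3f < 0.05: zero edges are resampled as zeros in every "
            "replicate; bootstrap intervals may understate uncertainty", nx.density(net)
        )
    observed = global_metrics(net, metrics)
    reps = {m: np.empty(B) for m in metrics}
    for b in range(B):
        gm = global_metrics(bootstrap_network(net, rng, dup_edge_rule), metrics)
        for m in metrics:
            reps[m][b] = gm[m]
    rows = []
    for m in sorted(metrics):
        lo, hi, n_eff = _percentile_ci(reps[m], conf)
        if n_eff < B:
            logger.info("metric %s undefined in %d/%d bootstrap replicates", m, B - n_eff, B)
        rows.append(
            {"metric": m, "observed": observed[m], "lower": lo, "upper": hi,
             "conf": conf, "n_effective": n_eff}
        )
    table = pd.DataFrame(rows)
    if return_replicates:
        rep_tab = pd.concat(
            [pd.DataFrame({"metric": m, "replicate": np.arange(B), "value": reps[m]})
             for m in sorted(metrics)],
            ignore_index=True,
        )
        return table, rep_tab
    return table


def ci_width_vs_samplesize(
    net: nx.Graph,
    sizes,
    B: int = 1000,
    metrics: set[str] | None = None,
    conf: float = 0.95,
    n_outer: int = 10,
    rng: np.random.Generator | None = None,
    dup_edge_rule: str = "always_draw",
) -> pd.DataFrame:
    """Mean bootstrap-CI width as a function of the number of tagged animals.

    For each size: draw an induced subsample of that many nodes,
    bootstrap it, record the CI width; average over ``n_outer`` outer
    draws.  Mean strength and diameter are replaced by their scaled
    versions (value / node count) so widths are comparable across sizes.
    """
    if n_outer < 1:
        raise ValueError("n_outer must be >= 1")
    metrics = set(metrics) if metrics is not None else set(DEFAULT_GLOBAL_METRICS)
    # size-dependent metrics -> scaled variants
    metrics = {
        {"mean_strength": "scaled_mean_strength", "diameter": "scaled_diameter"}.get(m, m)
        for m in metrics
    }
    rng = rng if rng is not None else np.random.default_rng()
    n = net.number_of_nodes()
    rows = []
    for size in sizes:
        if size > n:
            raise ValueError(f"size {size} exceeds network order {n}")
        widths = {m: [] for m in metrics}
        for _ in range(n_outer):
            sub = subsample_network(net, int(size), rng) if size < n else net
            ci = bootstrap_global_ci(sub, B, metrics, conf, rng, dup_edge_rule)
            for r in ci.itertuples(index=False):
                widths[r.metric].append(r.upper - r.lower)
        for m in sorted(metrics):
            w = np.asarray(widths[m], dtype=float)
            rows.append(
                {"size": int(size), "metric": m,
                 "mean_width": float(np.nanmean(w)) if np.isfinite(w).any() else np.nan,
                 "n_outer": n_outer}
            )
    return pd.DataFrame(rows)


def split_half_calibration(
    net: nx.Graph,
    B: int = 1000,
    metric: str = "density",
    n_trials: int = 50,
    conf: float = 0.95,
    rng: np.random.Generator | None = None,
    dup_edge_rule: str = "always_draw",
) -> float:
    """Proportion of disjoint-half CI pairs that overlap.

    Each trial partitions the nodes uniformly into two disjoint halves,
    bootstraps each induced half, and checks whether the two confidence
    intervals overlap.  Values near 1 indicate the bootstrap does not
    generate spurious statistically significant differences between two
    samples from the same population.
    """
    n = net.number_of_nodes()
    if n < 4:
        raise ValueError("split-half calibration needs at least 4 nodes")
    rng = rng if rng is not None else np.random.default_rng()
    nodes = sorted(net.nodes())
    n_overlap = 0
    n_valid = 0
    for _ in range(n_trials):
        perm = rng.permutation(n)
        half1 = [nodes[i] for i in perm[: n // 2]]
        half2 = [nodes[i] for i in perm[n // 2:]]
        cis = []
        ok = True
        for half in (half1, half2):
            ci = bootstrap_global_ci(
                net.subgraph(half).copy(), B, {metric}, conf, rng, dup_edge_rule
            )
            lo, hi = float(ci["lower"].iloc[0]), float(ci["upper"].iloc[0])
            if not (np.isfinite(lo) and np.isfinite(hi)):
                ok = False
                break
            cis.append((lo, hi))
        if not ok:
            logger.info("trial skipped: %s undefined in one half", metric)
            continue
        n_valid += 1
        (lo1, hi1), (lo2, hi2) = cis
        if lo1 <= hi2 and lo2 <= hi1:
            n_overlap += 1
    if n_valid == 0:
        return np.nan
    return n_overlap / n_valid


def bootstrap_node_ci(
    net: nx.Graph,
    B: int = 1000,
    metrics: set[str] | None = None,
    conf: float = 0.95,
    rng: np.random.Generator | None = None,
    dup_edge_rule: str = "always_draw",
) -> pd.DataFrame:
    """Percentile bootstrap confidence intervals for node-level metrics.

    Node metrics are computed on each replicate graph (copies are
    distinct nodes); a node's value in a replicate is the mean over its
    copies, and replicates not containing the node contribute nothing
    (``n_effective`` reports how many did).  Output is sorted by
    decreasing observed value within each metric.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    metrics = set(metrics) if metrics is not None else set(NODE_METRICS)
    rng = rng if rng is not None else np.random.default_rng()
    observed = node_metrics(net, metrics)
    nodes = sorted(net.nodes())
    samples: dict[str, dict] = {m: {v: [] for v in nodes} for m in metrics}
    for _ in range(B):
        rep = bootstrap_network(net, rng, dup_edge_rule)
        tab = node_metrics(rep, metrics)
        originals = pd.Series({c: rep.nodes[c]["original"] for c in tab.index})
        agg = tab.groupby(originals.reindex(tab.index).to_numpy()).mean()
        for m in metrics:
            for orig, val in agg[m].items():
                samples[m][orig].append(val)
    rows = []
    for m in sorted(metrics):
        for v in nodes:
            lo, hi, n_eff = _percentile_ci(np.asarray(samples[m][v], dtype=float), conf)
            if n_eff == 0:
                logger.warning("node %s absent from (or NA in) all replicates for %s", v, m)
            rows.append(
                {"metric": m, "node": v, "observed": observed.loc[v, m],
                 "lower": lo, "upper": hi, "conf": conf, "n_effective": n_eff}
            )
    out = pd.DataFrame(rows)
    return (
        out.sort_values(["metric", "observed"], ascending=[True, False], kind="mergesort")
        .reset_index(drop=True)
    )
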
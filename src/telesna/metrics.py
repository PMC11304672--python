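"""Node-level and global social-network metrics.

Node-level: degree, strength (weighted degree), betweenness centrality,
eigenvector centrality and local clustering coefficient.  Global: edge
density, transitivity, diameter, mean degree and mean strength, plus
scaled variants of mean strength and diameter (divided by the network
order N) whose confidence-interval widths are comparable across sample
sizes.

Path- and triangle-based metrics (degree, density, transitivity,
diameter, betweenness, clustering) use the binary topology; edge weights
(association indices) enter only through strength and eigenvector
centrality.  A weighted-paths variant is available for sensitivity
analysis, treating 1/weight as the edge length.
"""

from __future__ import annotations

import logging
import math

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NODE_METRICS = ("degree", "strength", "betweenness", "eigenvector", "clustering")
GLOBAL_METRICS = (
    "density", "transitivity", "diameter", "mean_degree", "mean_strength",
    "scaled_mean_strength", "scaled_diameter",
)

#: global metrics examined in the permutation / resampling analyses
DEFAULT_GLOBAL_METRICS = ("density", "mean_strength", "transitivity", "diameter")

_EIG_TOL = 1e-10
_EIG_MAXITER = 10_000


def eigenvector_centrality(net: nx.Graph) -> dict:
    """Weighted eigenvector centrality, max-normalised to 1.

    Computed per connected component by power iteration on that
    component's weighted adjacency (deterministic uniform start vector,
    tolerance 1e-10); each component's vector is scaled to unit maximum.
    Isolated nodes get 0.  An edgeless network yields all zeros.
    """
    if net.number_of_edges() == 0:
        logger.warning("eigenvector centrality of an edgeless network is identically 0")
        return {v: 0.0 for v in net.nodes()}
    out: dict = {v: 0.0 for v in net.nodes()}
    for comp in nx.connected_components(net):
        if len(comp) < 2:
            continue
        nodes = sorted(comp)
        sub = net.subgraph(nodes)
        a = nx.to_numpy_array(sub, nodelist=nodes, weight="weight")
        # spectrum shift (same eigenvectors) so bipartite components, whose
        # +/-lambda pair defeats plain power iteration, still converge
        a = a + (1.0 + a.sum(axis=1).max()) * np.eye(len(nodes))
        v = np.full(len(nodes), 1.0 / math.sqrt(len(nodes)))
        for _ in range(_EIG_MAXITER):
            w = a @ v
            norm = np.linalg.norm(w)
            if norm == 0:
                break
            w /= norm
            if np.abs(w - v).max() < _EIG_TOL:
                v = w
                break
            v = w
        v = np.abs(v)
        peak = v.max()
        if peak > 0:
            v = v / peak
        out.update(dict(zip(nodes, v.tolist())))
    return out


def node_metrics(net: nx.Graph, which: set[str] | None = None,
                 weighted_paths: bool = False) -> pd.DataFrame:
    """Per-node metric table (one row per node, one column per metric).

    ``degree``: unweighted edge count.  ``strength``: sum of incident
    edge weights.  ``betweenness``: unnormalised shortest-path
    betweenness.  ``clustering``: unweighted local clustering (NA for
    degree < 2).  ``eigenvector``: see :func:`eigenvector_centrality`.
    """
    which = set(which) if which is not None else set(NODE_METRICS)
    unknown = which - set(NODE_METRICS)
    if unknown:
        raise ValueError(f"unknown node metrics: {sorted(unknown)}")
    nodes = sorted(net.nodes())
    # tupleize_cols=False keeps tuple node labels (bootstrap copies) flat
    out = pd.DataFrame(index=pd.Index(nodes, name="node", tupleize_cols=False))
    if "degree" in which:
        out["degree"] = [net.degree(v) for v in nodes]
    if "strength" in which:
        out["strength"] = [float(net.degree(v, weight="weight")) for v in nodes]
    if "betweenness" in which:
        dist = _as_length(net) if weighted_paths else None
        bc = nx.betweenness_centrality(net, normalized=False, weight=dist)
        out["betweenness"] = [bc[v] for v in nodes]
    if "clustering" in which:
        cl = nx.clustering(net)
        out["clustering"] = [cl[v] if net.degree(v) >= 2 else np.nan for v in nodes]
    if "eigenvector" in which:
        ec = eigenvector_centrality(net)
        out["eigenvector"] = [ec[v] for v in nodes]
    return out


def _as_length(net: nx.Graph) -> str:
    """Attach `length` = 1/weight so strong associations are short paths."""
    for _, _, d in net.edges(data=True):
        d["length"] = 1.0 / d.get("weight", 1.0)
    return "length"


def global_metrics(net: nx.Graph, which: set[str] | None = None,
                   weighted_paths: bool = False,
                   scale_by_n_minus_1: bool = False) -> dict:
    """Scalar summaries of the whole network.

    density = 2|E| / (N(N-1)) (0 for N = 1); transitivity = 3 x triangles
    / connected triples (NA when the network has no connected triples);
    diameter = the maximum over connected components of the component
    diameter, so a partitioned network still yields a finite value; mean
    degree and mean strength average over all N nodes including isolates.
    Scaled variants divide by N (or N-1 if ``scale_by_n_minus_1``).
    """
    which = set(which) if which is not None else set(GLOBAL_METRICS)
    unknown = which - set(GLOBAL_METRICS)
    if unknown:
        raise ValueError(f"unknown global metrics: {sorted(unknown)}")
    n = net.number_of_nodes()
    if n < 1:
        raise ValueError("network must have at least one node")
    denom = (n - 1) if scale_by_n_minus_1 else n
    out: dict = {}
    needs_diam = which & {"diameter", "scaled_diameter"}
    needs_ms = which & {"mean_strength", "scaled_mean_strength"}
    if "density" in which:
        out["density"] = 0.0 if n < 2 else nx.density(net)
    if "transitivity" in which:
        triples = sum(d * (d - 1) // 2 for _, d in net.degree())
        out["transitivity"] = nx.transitivity(net) if triples > 0 else np.nan
    if needs_diam:
        dist = _as_length(net) if weighted_paths else None
        diam = 0.0
        for comp in nx.connected_components(net):
            if len(comp) > 1:
                diam = max(diam, nx.diameter(net.subgraph(comp), weight=dist)
                           if weighted_paths else nx.diameter(net.subgraph(comp)))
        if "diameter" in which:
            out["diameter"] = diam
        if "scaled_diameter" in which:
            out["scaled_diameter"] = diam / denom if denom > 0 else np.nan
    if "mean_degree" in which:
        out["mean_degree"] = 2.0 * net.number_of_edges() / n
    if needs_ms:
        ms = sum(float(net.degree(v, weight="weight")) for v in net.nodes()) / n
        if "mean_strength" in which:
            out["mean_strength"] = ms
        if "scaled_mean_strength" in which:
            out["scaled_mean_strength"] = ms / denom if denom > 0 else np.nan
    return out


def global_metric_series(net: nx.Graph, which, **kw) -> pd.Series:
    """`global_metrics` as a Series in a stable metric order."""
    vals = global_metrics(net, set(which), **kw)
    order = [m for m in GLOBAL_METRICS if m in vals]
    return pd.Series({m: vals[m] for m in order})
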
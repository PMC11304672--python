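"""Association network construction from relocation streams.

Two animals are considered to be associating when they are observed
within ``s`` metres of each other within a time frame of ``t`` minutes.
Because a GPS observation of animal A without B is only informative when
B is observed elsewhere at (nearly) the same time, the association index
uses a modified Simple Ratio Index whose denominator counts only events
where fixes are simultaneously available for both animals:

    SRI = x_AB / (x_AB + y_AB)

where x_AB counts joint observations within the spatial threshold and
y_AB those within the temporal threshold but farther apart.  The index
is 0 when a dyad is never observed together and 1 when always together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .io import TelemetryDataset, distance_matrix_m

logger = logging.getLogger(__name__)

JOINT_OBS_COLUMNS = [
    "animal_a", "animal_b", "t_a", "t_b", "dt_min", "distance_m",
]


@dataclass(frozen=True)
class Thresholds:
    """Spatio-temporal association thresholds.

    ``s``: spatial threshold in metres (default 15 m; 10 m is a common
    alternative for more loosely social species).  ``t``: temporal
    threshold in minutes (default 7 min, allowing for scheduled-fix
    reception jitter: a fix at 09:57 is matched against the other
    animal's fixes up to 10:04).
    """

    s: float = 15.0
    t: float = 7.0

    def __post_init__(self) -> None:
        if not (self.s > 0 and self.t > 0):
            raise ValueError(f"thresholds must be positive, got s={self.s}, t={self.t}")


def _greedy_match(dt: np.ndarray, ia: np.ndarray, ib: np.ndarray,
                  ta: np.ndarray) -> np.ndarray:
    """Greedy one-to-one matching of candidate fix pairs by ascending |dt|.

    Ties broken by earlier fix_a timestamp, then by fix_b index.  Returns
    the indices of selected candidate pairs.
    """
    order = np.lexsort((ib, ta, dt))
    used_a: set[int] = set()
    used_b: set[int] = set()
    chosen = []
    for k in order:
        a, b = int(ia[k]), int(ib[k])
        if a in used_a or b in used_b:
            continue
        used_a.add(a)
        used_b.add(b)
        chosen.append(k)
    return np.asarray(chosen, dtype=int)


def find_joint_observations(
    ds: TelemetryDataset,
    t: float,
    matching: str = "greedy_one_to_one",
    window: str = "symmetric",
) -> pd.DataFrame:
    """Pair up temporally close fixes for every dyad.

    For each unordered pair of animals, fixes within ``t`` minutes of one
    another are matched one-to-one, greedily by ascending |dt| (ties:
    earlier first-animal timestamp, then earlier second-animal
    timestamp), so that each fix enters at most one joint observation per
    dyad.  This prevents double counting when the fix interval is shorter
    than the temporal threshold.

    Parameters
    ----------
    t
        Temporal threshold in minutes (> 0).
    matching
        ``"greedy_one_to_one"`` (default) or ``"all_pairs"`` (every
        candidate pair within the window counts — no matching).
    window
        ``"symmetric"``: |t_B - t_A| <= t (default).  ``"forward"``:
        0 <= t_B - t_A <= t, where A is the lexicographically smaller id.

    Returns
    -------
    DataFrame with one row per joint observation: animal_a < animal_b,
    the two timestamps, |dt| in minutes and the inter-fix distance in
    metres.
    """
    if t <= 0:
        raise ValueError(f"temporal threshold must be > 0, got {t}")
    if matching not in ("greedy_one_to_one", "all_pairs"):
        raise ValueError(f"unknown matching {matching!r}")
    if window not in ("symmetric", "forward"):
        raise ValueError(f"unknown window {window!r}")

    per_animal: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for animal, grp in ds.fixes.groupby("animal_id", sort=True):
        ns = grp["timestamp"].astype("int64").to_numpy()  # exact integer nanoseconds
        per_animal[animal] = (ns, grp["x"].to_numpy(), grp["y"].to_numpy())
    t_ns = int(round(t * 60e9))

    animals = sorted(per_animal)
    frames: list[pd.DataFrame] = []
    for i, a in enumerate(animals):
        na_all, xa_all, ya_all = per_animal[a]
        for b in animals[i + 1:]:
            nb_all, xb_all, yb_all = per_animal[b]
            # candidate pairs within the window, via searchsorted on b's sorted times
            if window == "symmetric":
                lo = np.searchsorted(nb_all, na_all - t_ns, side="left")
                hi = np.searchsorted(nb_all, na_all + t_ns, side="right")
            else:  # forward: b fixes at or after a's fix
                lo = np.searchsorted(nb_all, na_all, side="left")
                hi = np.searchsorted(nb_all, na_all + t_ns, side="right")
            counts = hi - lo
            if counts.sum() == 0:
                continue
            ia = np.repeat(np.arange(len(na_all)), counts)
            ib = np.concatenate([np.arange(l, h) for l, h in zip(lo, hi) if h > l])
            dt_ns = np.abs(nb_all[ib] - na_all[ia])
            if matching == "greedy_one_to_one":
                sel = _greedy_match(dt_ns, ia, ib, na_all[ia])
                ia, ib, dt_ns = ia[sel], ib[sel], dt_ns[sel]
            dist = distance_matrix_m(
                xa_all[ia], ya_all[ia], xb_all[ib], yb_all[ib], ds.coordinate_mode
            )
            frames.append(
                pd.DataFrame(
                    {
                        "animal_a": a,
                        "animal_b": b,
                        "t_a": pd.to_datetime(na_all[ia], utc=True),
                        "t_b": pd.to_datetime(nb_all[ib], utc=True),
                        "dt_min": dt_ns / 60e9,
                        "distance_m": dist,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=JOINT_OBS_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def compute_associations(
    joint_obs: pd.DataFrame, s: float, min_denominator: int = 0
) -> pd.DataFrame:
    """Dyadic co-observation counts and SRI weights.

    Per dyad: ``x_ab`` = joint observations with distance <= s,
    ``y_ab`` = joint observations farther than s, ``sri`` = x/(x+y).
    Dyads with no joint observations are absent.  ``min_denominator``
    optionally drops dyads with fewer than that many joint observations.
    """
    if joint_obs.empty:
        return pd.DataFrame(columns=["animal_a", "animal_b", "x_ab", "y_ab", "sri"])
    close = (joint_obs["distance_m"] <= s).astype(int)
    tab = (
        joint_obs.assign(_close=close)
        .groupby(["animal_a", "animal_b"], sort=True)
        .agg(x_ab=("_close", "sum"), y_ab=("_close", lambda c: int((1 - c).sum())))
        .reset_index()
    )
    tab["x_ab"] = tab["x_ab"].astype(int)
    tab["y_ab"] = tab["y_ab"].astype(int)
    if min_denominator > 0:
        n_drop = int((tab["x_ab"] + tab["y_ab"] < min_denominator).sum())
        if n_drop:
            logger.info("dropping %d dyads below min denominator %d", n_drop, min_denominator)
        tab = tab[tab["x_ab"] + tab["y_ab"] >= min_denominator]
    tab["sri"] = tab["x_ab"] / (tab["x_ab"] + tab["y_ab"])
    return tab.reset_index(drop=True)


def network_from_associations(
    table: pd.DataFrame, nodes: Iterable[str]
) -> nx.Graph:
    """Weighted undirected network from an association table.

    Every animal is a node even if isolated (the network order equals the
    number of animals tagged); an edge exists iff sri > 0, with weight =
    sri and the raw counts kept as edge attributes.
    """
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for row in table.itertuples(index=False):
        if row.sri > 0:
            g.add_edge(row.animal_a, row.animal_b, weight=float(row.sri),
                       x_ab=int(row.x_ab), y_ab=int(row.y_ab))
    return g


def build_network(
    ds: TelemetryDataset,
    thresholds: Thresholds,
    matching: str = "greedy_one_to_one",
    window: str = "symmetric",
    min_denominator: int = 0,
) -> nx.Graph:
    """Full pipeline: relocations -> joint observations -> SRI network."""
    if ds.n_animals < 2:
        logger.warning("dataset has %d animal(s); network has no possible edges", ds.n_animals)
    jo = find_joint_observations(ds, thresholds.t, matching=matching, window=window)
    table = compute_associations(jo, thresholds.s, min_denominator=min_denominator)
    return network_from_associations(table, ds.animals)


def suggest_spatial_threshold(
    ds: TelemetryDataset,
    t: float,
    max_distance: float = 500.0,
    bin_width: float = 5.0,
) -> float:
    """First mode of the inter-individual distance distribution.

    Histogram joint-observation distances up to ``max_distance`` in bins
    of ``bin_width`` and return the centre of the first local-maximum bin
    (a bin whose count strictly exceeds both neighbours; the leading bin
    qualifies if it exceeds its right neighbour).  The first mode likely
    represents socially associating individuals and is a data-driven
    choice for the spatial threshold.
    """
    if ds.n_animals < 2:
        raise ValueError("need at least 2 animals to suggest a spatial threshold")
    jo = find_joint_observations(ds, t)
    d = jo["distance_m"].to_numpy() if not jo.empty else np.array([])
    d = d[d <= max_distance]
    if d.size == 0:
        raise ValueError("no joint observations within max_distance; threshold undefined")
    edges = np.arange(0.0, max_distance + bin_width, bin_width)
    counts, _ = np.histogram(d, bins=edges)
    padded = np.concatenate([[-np.inf], counts, [-np.inf]])
    for i in range(len(counts)):
        if padded[i + 1] > padded[i] and padded[i + 1] > padded[i + 2]:
            return float((edges[i] + edges[i + 1]) / 2.0)
    # monotone histogram: fall back to the global-maximum bin
    i = int(np.argmax(counts))
    return float((edges[i] + edges[i + 1]) / 2.0)


def sweep_thresholds(
    ds: TelemetryDataset,
    s_values: Iterable[float],
    t_values: Iterable[float],
    matching: str = "greedy_one_to_one",
) -> pd.DataFrame:
    """Sensitivity of the network to the spatio-temporal thresholds.

    One row per (s, t) combination with edge count, edge density and mean
    strength.  For a fixed t the edge count is non-decreasing in s.
    """
    from .metrics import global_metrics

    s_values = list(s_values)
    t_values = list(t_values)
    if not s_values or not t_values:
        raise ValueError("s_values and t_values must be non-empty")
    rows = []
    for t in t_values:
        jo = find_joint_observations(ds, t, matching=matching)
        for s in s_values:
            net = network_from_associations(compute_associations(jo, s), ds.animals)
            gm = global_metrics(net, {"density", "mean_strength"})
            rows.append(
                {
                    "s": s, "t": t,
                    "n_edges": net.number_of_edges(),
                    "density": gm["density"],
                    "mean_strength": gm["mean_strength"],
                }
            )
    return pd.DataFrame(rows)


# --- network I/O ---------------------------------------------------------

def write_graphml(net: nx.Graph, path: str | Path) -> None:
    """GraphML writer; the SRI weight is stored as both `weight` and `sri`."""
    g = net.copy()
    for _, _, d in g.edges(data=True):
        d["sri"] = float(d.get("weight", 1.0))
    nx.write_graphml(g, str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    g = nx.read_graphml(str(path))
    net = nx.Graph()
    net.add_nodes_from(g.nodes())
    for u, v, d in g.edges(data=True):
        w = float(d.get("weight", d.get("sri", 1.0)))
        net.add_edge(u, v, weight=w)
    return net


def write_edgelist_csv(net: nx.Graph, edge_path: str | Path,
                       node_path: str | Path | None = None) -> None:
    """Weighted edge-list CSV (`from,to,x_ab,y_ab,weight`) + node list for isolates."""
    rows = [
        {
            "from": u, "to": v,
            "x_ab": d.get("x_ab", ""), "y_ab": d.get("y_ab", ""),
            "weight": d["weight"],
        }
        for u, v, d in sorted(net.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["from", "to", "x_ab", "y_ab", "weight"]).to_csv(
        edge_path, index=False
    )
    if node_path is not None:
        pd.DataFrame({"node": sorted(net.nodes())}).to_csv(node_path, index=False)


def read_edgelist_csv(edge_path: str | Path,
                      node_path: str | Path | None = None) -> nx.Graph:
    df = pd.read_csv(edge_path)
    net = nx.Graph()
    if node_path is not None:
        net.add_nodes_from(pd.read_csv(node_path)["node"].astype(str))
    for u, v, w in zip(df["from"], df["to"], df["weight"]):
        net.add_edge(str(u), str(v), weight=float(w))
    return net
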
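"""Independent brute-force implementations used only as test oracles.

Everything here is deliberately naive pure Python (explicit pair
enumeration, BFS/DFS path search) and shares no code path with the
package implementation it checks.
"""

from __future__ import annotations

import itertools
import math


# --- distances ------------------------------------------------------------

def spherical_law_of_cosines_m(lon1, lat1, lon2, lat2, radius=6_371_000.0):
    """Great-circle distance via the spherical law of cosines."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    c = math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl)
    return radius * math.acos(min(1.0, max(-1.0, c)))


# --- joint-observation matching -------------------------------------------

def brute_force_joint_obs(fixes_a, fixes_b, t_minutes):
    """Greedy one-to-one matching over an explicitly enumerated pair list.

    fixes_a / fixes_b: lists of (time_minutes, x, y), any order.
    Returns list of (i, j, dt) index pairs into the time-sorted lists,
    selected greedily by ascending |dt|, ties by earlier a-fix time then
    earlier b-fix time.
    """
    fa = sorted(fixes_a)
    fb = sorted(fixes_b)
    candidates = []
    for i, (ta, *_unused) in enumerate(fa):
        for j, (tb, *_unused2) in enumerate(fb):
            dt = abs(tb - ta)
            if dt <= t_minutes:
                candidates.append((dt, ta, tb, i, j))
    candidates.sort()
    used_a, used_b, out = set(), set(), []
    for dt, _ta, _tb, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        out.append((i, j, dt))
    return out


def brute_force_sri(fixes_a, fixes_b, t_minutes, s_metres):
    """(x_ab, y_ab, sri) for one dyad via the brute-force matcher."""
    fa = sorted(fixes_a)
    fb = sorted(fixes_b)
    x = y = 0
    for i, j, _dt in brute_force_joint_obs(fa, fb, t_minutes):
        (_, xa, ya), (_, xb, yb) = fa[i], fb[j]
        d = math.hypot(xb - xa, yb - ya)
        if d <= s_metres:
            x += 1
        else:
            y += 1
    sri = x / (x + y) if (x + y) else None
    return x, y, sri


# --- graph metrics ---------------------------------------------------------

def _shortest_path_lengths(adj, source):
    """BFS distances from source; adj = {node: set(neighbours)}."""
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def _adjacency(nodes, edges):
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def bf_density(nodes, edges):
    n = len(nodes)
    return 0.0 if n < 2 else 2.0 * len(edges) / (n * (n - 1))


def bf_transitivity(nodes, edges):
    """3 x triangles / connected triples; None when no triples exist."""
    adj = _adjacency(nodes, edges)
    triangles = sum(
        1 for a, b, c in itertools.combinations(nodes, 3)
        if b in adj[a] and c in adj[a] and c in adj[b]
    )
    triples = sum(len(adj[v]) * (len(adj[v]) - 1) // 2 for v in nodes)
    return None if triples == 0 else 3.0 * triangles / triples


def bf_diameter(nodes, edges):
    """Max over connected components of the component diameter."""
    adj = _adjacency(nodes, edges)
    best = 0
    for v in nodes:
        dist = _shortest_path_lengths(adj, v)
        best = max(best, max(dist.values()))
    return best


def bf_betweenness(nodes, edges):
    """Unnormalised betweenness by exhaustive simple-path enumeration."""
    adj = _adjacency(nodes, edges)
    score = {v: 0.0 for v in nodes}

    def all_paths(s, t):
        out = []

        def dfs(u, path):
            if u == t:
                out.append(list(path))
                return
            for w in adj[u]:
                if w not in path:
                    path.append(w)
                    dfs(w, path)
                    path.pop()

        dfs(s, [s])
        return out

    for s, t in itertools.combinations(nodes, 2):
        paths = all_paths(s, t)
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        geodesics = [p for p in paths if len(p) == shortest]
        for p in geodesics:
            for v in p[1:-1]:
                score[v] += 1.0 / len(geodesics)
    return score
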
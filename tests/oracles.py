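"""Independent brute-force oracles used to freeze expected values.

Everything here is deliberately naive (enumeration, closed forms, tiny
least squares) and shares no code with the implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# Delaunay via circumcircle test
# ---------------------------------------------------------------------------

def delaunay_edges_bruteforce(points: np.ndarray) -> set[tuple[int, int]]:
    """Edges of all triangles whose circumcircle is empty of other points."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    edges = set()
    for i, j, k in itertools.combinations(range(n), 3):
        center, r = _circumcircle(pts[i], pts[j], pts[k])
        if center is None:
            continue
        ok = True
        for m in range(n):
            if m in (i, j, k):
                continue
            if np.hypot(*(pts[m] - center)) < r - 1e-9:
                ok = False
                break
        if ok:
            for a, b in ((i, j), (j, k), (i, k)):
                edges.add((min(a, b), max(a, b)))
    return edges


def _circumcircle(a, b, c):
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12:
        return None, None
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
          + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
          + (cx**2 + cy**2) * (bx - ax)) / d
    center = np.array([ux, uy])
    return center, np.hypot(*(a - center))


# ---------------------------------------------------------------------------
# Unrooted tree enumeration + least-squares scoring (small n)
# ---------------------------------------------------------------------------

def enumerate_unrooted_topologies(n: int):
    """All unrooted binary topologies on taxa 0..n-1 as edge lists.

    Built by sequential taxon insertion; nodes >= n are internal.
    """
    assert 3 <= n <= 7
    base = [(0, n), (1, n), (2, n)]  # star on first three taxa
    topologies = [base]
    next_internal = n + 1
    for taxon in range(3, n):
        new_topos = []
        for topo in topologies:
            for ei, (u, v) in enumerate(topo):
                inner = next_internal + (taxon - 3)
                t2 = [e for k, e in enumerate(topo) if k != ei]
                t2 += [(u, inner), (v, inner), (taxon, inner)]
                new_topos.append(t2)
        topologies = new_topos
    return topologies


def ls_branch_fit(topology, dist: np.ndarray):
    """Non-negative least-squares branch lengths for a topology; returns
    (sum of squared residuals, leaf-pair path design solution)."""
    from scipy.optimize import nnls

    n = dist.shape[0]
    edges = list(topology)
    n_edges = len(edges)
    adj: dict[int, list[tuple[int, int]]] = {}
    for ei, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, ei))
        adj.setdefault(v, []).append((u, ei))

    def path_edges(src, dst):
        stack = [(src, -1, [])]
        while stack:
            node, prev, path = stack.pop()
            if node == dst:
                return path
            for nxt, ei in adj[node]:
                if nxt != prev:
                    stack.append((nxt, node, path + [ei]))
        raise RuntimeError("disconnected topology")

    rows, y = [], []
    for i in range(n):
        for j in range(i + 1, n):
            row = np.zeros(n_edges)
            for ei in path_edges(i, j):
                row[ei] = 1.0
            rows.append(row)
            y.append(dist[i, j])
    A = np.array(rows)
    y = np.array(y)
    x, _ = nnls(A, y)
    resid = float(((A @ x - y) ** 2).sum())
    return resid, x


def best_topology_bipartitions(dist: np.ndarray) -> set[frozenset[int]]:
    """Non-trivial splits of the least-squares-best topology."""
    n = dist.shape[0]
    best = None
    for topo in enumerate_unrooted_topologies(n):
        resid, _ = ls_branch_fit(topo, dist)
        if best is None or resid < best[0] - 1e-12:
            best = (resid, topo)
    return topology_bipartitions(best[1], n)


def topology_bipartitions(topology, n: int) -> set[frozenset[int]]:
    adj: dict[int, list[int]] = {}
    for u, v in topology:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    def leaves_beyond(u, v):  # leaves reachable from v without u
        seen, stack, out = {u, v}, [v], set()
        while stack:
            node = stack.pop()
            if node < n:
                out.add(node)
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return out

    splits = set()
    for u, v in topology:
        side = leaves_beyond(u, v)
        if 2 <= len(side) <= n - 2:
            splits.add(frozenset(side if 0 not in side else
                                 set(range(n)) - side))
    return splits


def random_additive_matrix(n: int, rng: np.random.Generator):
    """A random unrooted binary tree and its exact additive distances."""
    topos = enumerate_unrooted_topologies(n)
    topo = topos[rng.integers(0, len(topos))]
    lengths = {e: float(rng.uniform(0.5, 3.0)) for e in topo}
    adj: dict[int, list[tuple[int, float]]] = {}
    for (u, v), w in lengths.items():
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    dist = np.zeros((n, n))
    for i in range(n):
        stack = [(i, -1, 0.0)]
        while stack:
            node, prev, acc = stack.pop()
            if node < n:
                dist[i, node] = acc
            for nxt, w in adj[node]:
                if nxt != prev:
                    stack.append((nxt, node, acc + w))
    return topo, dist


# ---------------------------------------------------------------------------
# Minimum spanning network / spanning tree enumeration
# ---------------------------------------------------------------------------

def msn_edges_bruteforce(dist: np.ndarray) -> set[tuple[int, int]]:
    """Union of all minimum spanning trees, by full spanning-tree enumeration."""
    n = dist.shape[0]
    all_edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best_w = None
    union: set[tuple[int, int]] = set()
    for combo in itertools.combinations(all_edges, n - 1):
        if not _spans(combo, n):
            continue
        w = sum(dist[i, j] for i, j in combo)
        if best_w is None or w < best_w - 1e-9:
            best_w, union = w, set(combo)
        elif abs(w - best_w) <= 1e-9:
            union |= set(combo)
    return union


def _spans(edges, n) -> bool:
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri == rj:
            return False
        parent[rj] = ri
    return True


def min_spanning_weight_per_component(units: list[str],
                                      edges: list[tuple[str, str, float]]):
    """(event count, minimal total weight) by exhaustive enumeration over
    spanning forests of a unit graph with <= 6 units."""
    idx = {u: i for i, u in enumerate(units)}
    n = len(units)
    # connected components of the evidence graph
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, _ in edges:
        ra, rb = find(idx[a]), find(idx[b])
        if ra != rb:
            parent[rb] = ra
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)

    total_edges = 0
    total_weight = 0.0
    for comp in comps.values():
        k = len(comp)
        if k == 1:
            continue
        sub = [(idx[a], idx[b], w) for a, b, w in edges
               if idx[a] in comp and idx[b] in comp]
        local = {g: i for i, g in enumerate(comp)}
        best = None
        for combo in itertools.combinations(sub, k - 1):
            if not _spans([(local[i], local[j]) for i, j, _ in combo], k):
                continue
            w = sum(t[2] for t in combo)
            if best is None or w < best:
                best = w
        total_edges += k - 1
        total_weight += best
    return total_edges, total_weight


# ---------------------------------------------------------------------------
# Misc small oracles
# ---------------------------------------------------------------------------

def max_uncorrelated_subset_bruteforce(corr: np.ndarray, r_max: float):
    """All maximum-cardinality subsets with pairwise |r| < r_max (2^k scan)."""
    k = corr.shape[0]
    best_size, best = 0, []
    for mask in range(1, 2 ** k):
        subset = [i for i in range(k) if mask >> i & 1]
        ok = all(abs(corr[a, b]) < r_max
                 for a, b in itertools.combinations(subset, 2))
        if not ok:
            continue
        if len(subset) > best_size:
            best_size, best = len(subset), [tuple(subset)]
        elif len(subset) == best_size:
            best.append(tuple(subset))
    return best_size, best


def maxsss_scan(presence: np.ndarray, background: np.ndarray):
    """Exhaustive threshold scan; lowest threshold among the maxima."""
    cands = sorted(set(np.concatenate([presence, background]).tolist()))
    results = []
    for t in cands:
        sens = float((presence >= t).mean())
        spec = float((background < t).mean())
        results.append((sens + spec, t))
    best_v = max(v for v, _ in results)
    return min(t for v, t in results if v >= best_v - 1e-12)


def auc_pair_count(presence: np.ndarray, background: np.ndarray) -> float:
    """AUC by direct pair counting with 0.5 for ties."""
    wins = 0.0
    for p in presence:
        for b in background:
            if p > b:
                wins += 1.0
            elif p == b:
                wins += 0.5
    return wins / (len(presence) * len(background))
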
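"""Independent brute-force oracles, sharing no code with the package.

Everything here is written as plain loops over definitions so it can serve
as the reference against the vectorized implementations.
"""

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# Mapper, end to end, by naive enumeration

def brute_distance(X):
    """1 - Pearson correlation between rows, by the textbook formula."""
    n, p = X.shape
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            xi, xj = X[i], X[j]
            mi, mj = sum(xi) / p, sum(xj) / p
            num = sum((a - mi) * (b - mj) for a, b in zip(xi, xj))
            den = math.sqrt(sum((a - mi) ** 2 for a in xi)) * math.sqrt(
                sum((b - mj) ** 2 for b in xj))
            d = 1.0 - num / den
            D[i, j] = min(max(d, 0.0), 2.0)
        D[i, i] = 0.0
    return (D + D.T) / 2


def brute_mds(D, k):
    """Torgerson MDS via the explicit centering matrix J = I - 11'/n."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    idx = np.argsort(vals)[::-1]
    vals, vecs = vals[idx], vecs[:, idx]
    coords = np.zeros((n, k))
    for a in range(k):
        coords[:, a] = vecs[:, a] * math.sqrt(max(vals[a], 0.0))
        i_max = max(range(n), key=lambda i: abs(coords[i, a]))
        if coords[i_max, a] < 0:
            coords[:, a] = -coords[:, a]
    return coords


def _ranks_average(x):
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and x[order[j]] == x[order[i]]:
            j += 1
        avg = (i + 1 + j) / 2  # average of ranks i+1 .. j
        for t in range(i, j):
            ranks[order[t]] = avg
        i = j
    return ranks


def brute_cover(lens, resolution, gain, equalized):
    """All non-empty cover cells as (index tuple, sorted member list)."""
    n, k = lens.shape
    pos = np.zeros((n, k))
    for a in range(k):
        col = lens[:, a]
        if equalized:
            ranks = _ranks_average(list(col))
            for i in range(n):
                pos[i, a] = (ranks[i] - 0.5) / n
        else:
            lo, hi = min(col), max(col)
            for i in range(n):
                pos[i, a] = 0.5 if hi == lo else (col[i] - lo) / (hi - lo)
    half = 0.5 * gain / resolution
    cells = []
    for idx in itertools.product(range(resolution), repeat=k):
        members = []
        for i in range(n):
            ok = True
            for a in range(k):
                center = (idx[a] + 0.5) / resolution
                if abs(pos[i, a] - center) > half + 1e-12:
                    ok = False
                    break
            if ok:
                members.append(i)
        if members:
            cells.append((idx, members))
    return cells


def brute_single_linkage_heights(D, members):
    """Naive agglomeration: returns merge heights in order."""
    clusters = [{m} for m in members]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = min(D[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] | clusters[b]
        clusters = [c for t, c in enumerate(clusters) if t not in (a, b)] + [merged]
    return heights


def brute_cluster_cell(members, D, bins=10):
    """Single linkage cut at the first empty histogram bin after an occupied one."""
    members = list(members)
    if len(members) == 1:
        return [set(members)]
    heights = brute_single_linkage_heights(D, members)
    h_max = max(heights)
    if h_max <= 0:
        return [set(members)]
    width = h_max / bins
    counts = [0] * bins
    for h in heights:
        b = min(int(h / width), bins - 1)
        counts[b] += 1
    first_occupied = next(b for b in range(bins) if counts[b] > 0)
    gap = next((b for b in range(first_occupied + 1, bins) if counts[b] == 0), None)
    if gap is None:
        return [set(members)]
    threshold = gap * width
    # connected components of the graph with edges d <= threshold
    out = []
    todo = set(members)
    while todo:
        seed = todo.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            u = frontier.pop()
            for v in list(todo):
                if D[u, v] <= threshold:
                    todo.discard(v)
                    comp.add(v)
                    frontier.append(v)
        out.append(comp)
    return out


def brute_mapper(X, resolution, gain, equalized, k=2, bins=10):
    """Full naive Mapper: set of node member-frozensets and the edge set.

    Returns (nodes, edges) where nodes is a list of (cell index, frozenset)
    in cell-major order and edges a set of index pairs into that list.
    """
    D = brute_distance(X)
    lens = brute_mds(D, k)
    cells = brute_cover(lens, resolution, gain, equalized)
    nodes = []
    for idx, members in cells:
        for cluster in sorted(brute_cluster_cell(members, D, bins), key=min):
            nodes.append((idx, frozenset(cluster)))
    edges = set()
    for a, b in itertools.combinations(range(len(nodes)), 2):
        if nodes[a][1] & nodes[b][1]:
            edges.add((a, b))
    return nodes, edges


# ---------------------------------------------------------------------------
# survival oracles

def hand_km(times, events):
    """Product-limit estimate as a list of (time, survival)."""
    pts = sorted(set(t for t, e in zip(times, events) if e == 1))
    s = 1.0
    out = []
    for t in pts:
        n_t = sum(1 for tt in times if tt >= t)
        d_t = sum(1 for tt, e in zip(times, events) if tt == t and e == 1)
        s *= 1 - d_t / n_t
        out.append((t, s))
    return out


def brute_modularity_best(G):
    """Exhaustive modularity maximization over all partitions (small graphs)."""
    import networkx as nx

    nodes = list(G.nodes)

    def partitions(seq):
        if not seq:
            yield []
            return
        head, rest = seq[0], seq[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [part[i] | {head}] + part[i + 1:]
            yield part + [{head}]

    best, best_q = None, -np.inf
    for part in partitions(nodes):
        q = nx.community.modularity(G, part)
        if q > best_q:
            best, best_q = part, q
    return best, best_q
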
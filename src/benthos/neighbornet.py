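"""Neighbor-net: circular split systems from distance matrices.

The agglomerative stage generalizes neighbor joining: clusters holding one
or two active nodes are merged by an NJ-style adjusted-distance criterion,
and 3-node paths are reduced to 2 nodes with fixed convex weights
(2/3, 1/3), yielding a circular ordering of the samples.  Non-negative
split weights for all interval splits of that ordering are then estimated
by least squares, and the resulting weighted split system is realized as a
planar splits graph whose shortest paths reproduce the split metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import nnls
from skbio.stats.distance import DistanceMatrix

__all__ = [
    "CircularSplitSystem",
    "nnet_ordering",
    "nnls_split_weights",
    "neighbor_net",
    "build_splits_graph",
    "graph_distance_submatrix",
]


@dataclass
class CircularSplitSystem:
    """Weighted splits that are intervals of one circular ordering.

    Each split is stored as ``(a, b, weight)`` where positions ``a..b`` of
    ``ordering`` (0-based, never containing position 0) form one side.
    """

    ordering: list[str]
    splits: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.ordering)

    def separates(self, a: int, b: int, p: int, q: int) -> bool:
        return (a <= p <= b) != (a <= q <= b)

    def split_sides(self, a: int, b: int) -> tuple[list[str], list[str]]:
        inside = [self.ordering[i] for i in range(a, b + 1)]
        outside = [self.ordering[i] for i in range(self.n)
                   if not a <= i <= b]
        return inside, outside

    def split_metric(self) -> DistanceMatrix:
        """Distance matrix induced by the weighted splits."""
        n = self.n
        d = np.zeros((n, n))
        for a, b, w in self.splits:
            inside = np.zeros(n, dtype=bool)
            inside[a:b + 1] = True
            sep = inside[:, None] != inside[None, :]
            d[sep] += w
        return DistanceMatrix(d, ids=self.ordering)

    def total_weight(self) -> float:
        return sum(w for *_, w in self.splits)


# --------------------------------------------------------------------------
# agglomerative circular ordering
# --------------------------------------------------------------------------

def nnet_ordering(dm: DistanceMatrix) -> list[str]:
    """Circular sample ordering by neighbor-net agglomeration.

    Deterministic: all ties break on node index, and the returned cycle is
    canonicalized to start at the first sample with its smaller-indexed
    neighbor second.
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor-net needs at least 3 samples")

    cap = 6 * n
    D = np.zeros((cap, cap))
    D[:n, :n] = dm.data
    nxt = n  # next fresh node id
    clusters: list[list[int]] = [[i] for i in range(n)]
    reductions: list[tuple[int, int, tuple[int, int, int]]] = []

    def cluster_dist(A: list[int], B: list[int]) -> float:
        return float(np.mean([[D[x, y] for y in B] for x in A]))

    def node_cluster_dist(x: int, B: list[int]) -> float:
        return float(np.mean([D[x, y] for y in B]))

    def reduce_triple(a: int, b: int, c: int, others: list[int]) -> tuple[int, int]:
        """Replace path a-b-c by two fresh nodes (canonical 2/3:1/3 weights)."""
        nonlocal nxt
        u, v = nxt, nxt + 1
        nxt += 2
        for z in others:
            D[u, z] = D[z, u] = (2 / 3) * D[a, z] + (1 / 3) * D[b, z]
            D[v, z] = D[z, v] = (2 / 3) * D[c, z] + (1 / 3) * D[b, z]
        D[u, v] = D[v, u] = (D[a, b] + D[b, c] + D[a, c]) / 3
        reductions.append((u, v, (a, b, c)))
        return u, v

    while len(clusters) > 1:
        N = len(clusters)
        if N == 2:
            ai, bi = 0, 1
            A, B = clusters[ai], clusters[bi]
            best = None
            for x in A:
                for y in B:
                    key = (D[x, y], x, y)
                    if best is None or key < best:
                        best = key
            x, y = best[1], best[2]
        else:
            # cluster-pair selection (NJ-style Q on mean cluster distances)
            Dcl = np.zeros((N, N))
            for i in range(N):
                for j in range(i + 1, N):
                    Dcl[i, j] = Dcl[j, i] = cluster_dist(clusters[i], clusters[j])
            R = Dcl.sum(axis=1)
            best = None
            for i in range(N):
                for j in range(i + 1, N):
                    q = (N - 2) * Dcl[i, j] - R[i] - R[j]
                    key = (q, i, j)
                    if best is None or key < best:
                        best = key
            ai, bi = best[1], best[2]
            A, B = clusters[ai], clusters[bi]
            # node-pair selection: nodes of A and B act as singleton clusters
            m = (N - 2) + len(A) + len(B)
            other_cl = [clusters[k] for k in range(N) if k not in (ai, bi)]
            both = A + B

            def rhat(x: int) -> float:
                s = sum(node_cluster_dist(x, C) for C in other_cl)
                s += sum(D[x, z] for z in both if z != x)
                return s

            best = None
            for x in A:
                for y in B:
                    q = (m - 2) * D[x, y] - rhat(x) - rhat(y)
                    key = (q, x, y)
                    if best is None or key < best:
                        best = key
            x, y = best[1], best[2]

        pa = list(A) if A[-1] == x else list(reversed(A))
        pb = list(B) if B[0] == y else list(reversed(B))
        path = pa + pb
        clusters = [clusters[k] for k in range(len(clusters)) if k not in (ai, bi)]
        while len(path) > 2:
            others = [z for C in clusters for z in C] + path[3:]
            u, v = reduce_triple(path[0], path[1], path[2], others)
            path = [u, v] + path[3:]
        clusters.append(path)

    # expand the reductions back into a full cycle
    cycle = list(clusters[0])
    for u, v, (a, b, c) in reversed(reductions):
        i = cycle.index(u)
        m = len(cycle)
        if cycle[(i + 1) % m] == v:
            cycle = cycle[:i] + [a, b, c] + cycle[i + 2:] if i + 1 < m \
                else [b, c] + cycle[1:i] + [a]
        elif cycle[(i - 1) % m] == v:
            j = (i - 1) % m
            if j < i:
                cycle = cycle[:j] + [c, b, a] + cycle[i + 1:]
            else:  # v at end, u at position 0
                cycle = [b, a] + cycle[1:j] + [c]
        else:
            raise AssertionError("reduction pair not adjacent during expansion")

    assert sorted(cycle) == list(range(n))
    # canonical rotation/direction
    i = cycle.index(0)
    cycle = cycle[i:] + cycle[:i]
    if len(cycle) > 2 and cycle[-1] < cycle[1]:
        cycle = [cycle[0]] + cycle[1:][::-1]
    return [ids[i] for i in cycle]


# --------------------------------------------------------------------------
# split-weight estimation
# --------------------------------------------------------------------------

def _interval_splits(n: int) -> list[tuple[int, int]]:
    """All n(n-1)/2 interval splits of a circular order, sides excluding 0."""
    return [(a, b) for a in range(1, n) for b in range(a, n)]


def nnls_split_weights(dm: DistanceMatrix, ordering: list[str],
                       weight_floor: float = 1e-9) -> CircularSplitSystem:
    """Non-negative least-squares split weights for a circular ordering.

    Solves ``min ||d - A w||^2, w >= 0`` over all interval splits of the
    ordering (A is the split-metric incidence matrix); splits below
    ``weight_floor`` are dropped.
    """
    ids = list(dm.ids)
    if sorted(ordering) != sorted(ids):
        raise ValueError("ordering must cover exactly the samples of d")
    n = len(ordering)
    pos = {s: i for i, s in enumerate(ordering)}
    perm = [pos[s] for s in ids]
    # distances indexed by circular position
    dmat = np.zeros((n, n))
    data = dm.data
    for i in range(n):
        for j in range(n):
            dmat[perm[i], perm[j]] = data[i, j]

    splits = _interval_splits(n)
    iu = np.triu_indices(n, k=1)
    y = dmat[iu]
    inside = np.zeros((len(splits), n), dtype=bool)
    for k, (a, b) in enumerate(splits):
        inside[k, a:b + 1] = True
    # column k of A: 1 where the split separates the pair
    A = (inside[:, iu[0]] != inside[:, iu[1]]).T.astype(float)
    w, _ = nnls(A, y)
    kept = [(a, b, float(wk)) for (a, b), wk in zip(splits, w)
            if wk > weight_floor]
    return CircularSplitSystem(ordering=list(ordering), splits=kept)


def neighbor_net(dm: DistanceMatrix,
                 weight_floor: float = 1e-9) -> CircularSplitSystem:
    """Full neighbor-net: ordering plus non-negative split weights."""
    return nnls_split_weights(dm, nnet_ordering(dm), weight_floor)


# --------------------------------------------------------------------------
# splits-graph realization
# --------------------------------------------------------------------------

def build_splits_graph(css: CircularSplitSystem) -> nx.Graph:
    """Realize a circular split system as a planar splits graph.

    Splits are drawn as chords of a circle through the sample positions;
    the graph is the planar dual of the chord arrangement: nodes are cells,
    and each split contributes a band of parallel edges carrying its
    weight.  Shortest paths between sample nodes equal the split metric.

    The returned :class:`networkx.Graph` has node attribute ``taxa`` (list
    of sample ids mapped to the node, possibly empty), edge attributes
    ``weight`` and ``split`` (index into ``css.splits``), and graph
    attribute ``taxon_node`` mapping each sample id to its node.
    """
    n = css.n
    for a, b, w in css.splits:
        if not (1 <= a <= b <= n - 1) or w < 0:
            raise ValueError(f"malformed split ({a}, {b}, {w})")
    theta = 2 * math.pi * np.arange(n) / n

    # chord endpoints live in the gaps between consecutive positions;
    # within a gap, endpoints are ordered by the circular distance to the
    # chord's other endpoint so nested chords never cross
    gap_entries: dict[int, list[tuple[int, int, int]]] = {}
    for k, (a, b, _) in enumerate(css.splits):
        g1, g2 = a - 1, b  # gap g sits between positions g and g+1 (mod n)
        gap_entries.setdefault(g1, []).append((k, 0, (g2 - g1) % n))
        gap_entries.setdefault(g2, []).append((k, 1, (g1 - g2) % n))
    end_angle = {}
    width = 2 * math.pi / n
    for g, entries in gap_entries.items():
        entries.sort(key=lambda e: (e[2], e[0]))
        step = width / (len(entries) + 1)
        base = theta[(g + 1) % n] if g < n - 1 else 2 * math.pi
        for r, (k, which, _) in enumerate(entries):
            end_angle[(k, which)] = base - (r + 1) * step

    def xy(angle: float) -> tuple[float, float]:
        return (math.cos(angle), math.sin(angle))

    # vertices: boundary points (taxa + chord endpoints) and chord crossings
    verts: list[tuple[float, float]] = []

    def add_vertex(p) -> int:
        verts.append(p)
        return len(verts) - 1

    taxon_vert = [add_vertex(xy(t)) for t in theta]
    end_vert = {key: add_vertex(xy(ang)) for key, ang in end_angle.items()}

    def crosses(s1, s2) -> bool:
        a1, b1, _ = css.splits[s1]
        a2, b2, _ = css.splits[s2]
        return (a1 < a2 <= b1 < b2) or (a2 < a1 <= b2 < b1)

    def seg_intersection(p1, p2, p3, p4):
        x1, y1 = p1; x2, y2 = p2; x3, y3 = p3; x4, y4 = p4
        den = (x2 - x1) * (y4 - y3) - (y2 - y1) * (x4 - x3)
        t = ((x3 - x1) * (y4 - y3) - (y3 - y1) * (x4 - x3)) / den
        return (x1 + t * (x2 - x1), y1 + t * (y2 - y1))

    m = len(css.splits)
    chord_pts: dict[int, list[tuple[float, int]]] = {k: [] for k in range(m)}
    for k in range(m):
        p1 = verts[end_vert[(k, 0)]]
        chord_pts[k].append((0.0, end_vert[(k, 0)]))
        chord_pts[k].append((1.0, end_vert[(k, 1)]))
    for k1 in range(m):
        p1, p2 = verts[end_vert[(k1, 0)]], verts[end_vert[(k1, 1)]]
        for k2 in range(k1 + 1, m):
            if not crosses(k1, k2):
                continue
            p3, p4 = verts[end_vert[(k2, 0)]], verts[end_vert[(k2, 1)]]
            pt = seg_intersection(p1, p2, p3, p4)
            vi = add_vertex(pt)
            t1 = math.hypot(pt[0] - p1[0], pt[1] - p1[1])
            t2 = math.hypot(pt[0] - p3[0], pt[1] - p3[1])
            chord_pts[k1].append((t1 / math.hypot(p2[0] - p1[0], p2[1] - p1[1]), vi))
            chord_pts[k2].append((t2 / math.hypot(p4[0] - p3[0], p4[1] - p3[1]), vi))

    # primal edges: chord segments (tagged by split) + boundary arcs
    edges: list[tuple[int, int, int]] = []  # (u, v, split or -1)
    for k in range(m):
        pts = sorted(chord_pts[k])
        for (_, u), (_, v) in zip(pts, pts[1:]):
            edges.append((u, v, k))
    boundary = sorted(range(len(verts)),
                      key=lambda vi: math.atan2(verts[vi][1], verts[vi][0]))
    boundary = [vi for vi in boundary
                if abs(math.hypot(*verts[vi]) - 1.0) < 1e-9]
    for u, v in zip(boundary, boundary[1:] + boundary[:1]):
        edges.append((u, v, -1))

    # planar face traversal (next edge = clockwise-next from the reverse)
    adj: dict[int, list[tuple[float, int]]] = {}
    for u, v, _ in edges:
        au = math.atan2(verts[v][1] - verts[u][1], verts[v][0] - verts[u][0])
        av = math.atan2(verts[u][1] - verts[v][1], verts[u][0] - verts[v][0])
        adj.setdefault(u, []).append((au, v))
        adj.setdefault(v, []).append((av, u))
    for u in adj:
        adj[u].sort()

    def next_dedge(u: int, v: int) -> tuple[int, int]:
        back = math.atan2(verts[u][1] - verts[v][1], verts[u][0] - verts[v][0])
        angles = adj[v]
        lo = [a for a in angles if a[0] < back - 1e-12]
        a, w = lo[-1] if lo else angles[-1]
        return v, w

    face_of: dict[tuple[int, int], int] = {}
    faces: list[list[int]] = []
    for u0, v0, _ in edges:
        for start in ((u0, v0), (v0, u0)):
            if start in face_of:
                continue
            cyc = []
            e = start
            while e not in face_of:
                face_of[e] = len(faces)
                cyc.append(e[0])
                e = next_dedge(*e)
            faces.append(cyc)

    def signed_area(cyc: list[int]) -> float:
        s = 0.0
        for i, u in enumerate(cyc):
            v = cyc[(i + 1) % len(cyc)]
            s += verts[u][0] * verts[v][1] - verts[v][0] * verts[u][1]
        return s / 2

    outer = min(range(len(faces)), key=lambda f: signed_area(faces[f]))

    g = nx.Graph()
    for f in range(len(faces)):
        if f != outer:
            g.add_node(f, taxa=[])
    for u, v, k in edges:
        if k < 0:
            continue
        f1, f2 = face_of[(u, v)], face_of[(v, u)]
        if f1 == outer or f2 == outer:
            raise AssertionError("chord edge on the outer face")
        w = css.splits[k][2]
        if g.has_edge(f1, f2) and g[f1][f2]["split"] != k:
            raise AssertionError("two splits between one face pair")
        g.add_edge(f1, f2, weight=w, split=k)

    taxon_node = {}
    bpos = {vi: i for i, vi in enumerate(boundary)}
    for i, sid in enumerate(css.ordering):
        tv = taxon_vert[i]
        nxt_b = boundary[(bpos[tv] + 1) % len(boundary)]
        f = face_of[(tv, nxt_b)]
        g.nodes[f]["taxa"].append(sid)
        taxon_node[sid] = f
    g.graph["taxon_node"] = taxon_node
    g.graph["n_splits"] = m
    return g


def graph_distance_submatrix(g: nx.Graph, ids: list[str] | None = None,
                             weighted: bool = True) -> DistanceMatrix:
    """Shortest-path distances between the sample nodes of a splits graph."""
    taxon_node = g.graph["taxon_node"]
    if ids is None:
        ids = sorted(taxon_node)
    nodes = [taxon_node[s] for s in ids]
    n = len(ids)
    d = np.zeros((n, n))
    weight = "weight" if weighted else None
    for i, src in enumerate(nodes):
        lengths = nx.single_source_dijkstra_path_length(g, src, weight=weight)
        for j, dst in enumerate(nodes):
            if i < j:
                d[i, j] = d[j, i] = lengths[dst]
    return DistanceMatrix(d, ids=ids)
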
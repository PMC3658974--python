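"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (exhaustive enumeration, least
squares over all topologies, subset search) and shares no code with the
package's algorithms.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# motif scanning: brute force over all His triples


def brute_force_triads(sequence: str, kind: str, params) -> list[tuple]:
    his = [i for i, ch in enumerate(sequence) if ch == "H"]
    out = []
    for h1, h2, h3 in itertools.combinations(his, 3):
        s12, s23 = h2 - h1 - 1, h3 - h2 - 1
        if kind == "A":
            lo, hi = params.cuA_h1_h2_range
            blo, bhi = params.cuA_h2_h3_beta_range
            ok = (lo <= s12 <= hi
                  and (s23 == params.cuA_h2_h3_fixed or blo <= s23 <= bhi))
        else:
            lo, hi = params.cuB_h2_h3_range
            ok = s12 == params.cuB_h1_h2_fixed and lo <= s23 <= hi
        if ok:
            out.append((h1, h2, h3))
    return sorted(out)


def brute_force_pairs(triadsA, triadsB, params) -> list[tuple]:
    """All (A, B) index pairs with the intersite gap in range."""
    lo, hi = params.intersite_gap_range
    return [(a, b) for a in triadsA for b in triadsB
            if lo <= b[0] - a[2] - 1 <= hi]


# ---------------------------------------------------------------------------
# unrooted tree topologies, for the minimum-evolution oracle
#
# A topology is an adjacency map {node: set(neighbours)}; tips are the
# string-labelled nodes, internal nodes are ints.


def _copy(adj):
    return {k: set(v) for k, v in adj.items()}


def all_unrooted_topologies(taxa: list[str]):
    """Every unrooted binary topology over the taxa (3 -> 1, 6 -> 105)."""
    assert len(taxa) >= 3
    base = {0: {taxa[0], taxa[1], taxa[2]},
            taxa[0]: {0}, taxa[1]: {0}, taxa[2]: {0}}
    trees = [base]
    next_internal = 1
    for tip in taxa[3:]:
        grown = []
        for adj in trees:
            edges = {frozenset((a, b)) for a in adj for b in adj[a]}
            for edge in edges:
                a, b = tuple(edge)
                new = _copy(adj)
                mid = next_internal
                new[a].remove(b)
                new[b].remove(a)
                new[mid] = {a, b, tip}
                new[a].add(mid)
                new[b].add(mid)
                new[tip] = {mid}
                grown.append(new)
        trees = grown
        next_internal += 1
    return trees


def topology_bipartitions(adj, taxa) -> frozenset:
    """Non-trivial bipartitions, canonicalized to the side without the
    smallest taxon."""
    anchor = min(taxa)
    parts = set()
    edges = {frozenset((a, b)) for a in adj for b in adj[a]}
    for edge in edges:
        a, b = tuple(edge)
        # tips reachable from a without crossing the edge
        seen, stack = {a}, [a]
        while stack:
            node = stack.pop()
            for nb in adj[node]:
                if nb == b and node == a:
                    continue
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        side = frozenset(t for t in taxa if t in seen)
        if 2 <= len(side) <= len(taxa) - 2:
            if anchor in side:
                side = frozenset(taxa) - side
            parts.add(side)
    return frozenset(parts)


def _paths_matrix(adj, taxa):
    """0/1 incidence of taxon pairs over edges, plus the edge list."""
    edges = sorted({frozenset((a, b)) for a in adj for b in adj[a]},
                   key=lambda e: sorted(map(str, e)))
    pairs = list(itertools.combinations(sorted(taxa), 2))
    A = np.zeros((len(pairs), len(edges)))

    def path(src, dst):
        prev = {src: None}
        stack = [src]
        while stack:
            node = stack.pop()
            if node == dst:
                break
            for nb in adj[node]:
                if nb not in prev:
                    prev[nb] = node
                    stack.append(nb)
        out = []
        node = dst
        while prev[node] is not None:
            out.append(frozenset((node, prev[node])))
            node = prev[node]
        return out

    for r, (x, y) in enumerate(pairs):
        for edge in path(x, y):
            A[r, edges.index(edge)] = 1
    return A, pairs


def minimum_evolution_topology(dist: dict, taxa: list[str]) -> frozenset:
    """Exhaustive search: OLS branch lengths per topology, pick the
    topology with the smallest total tree length."""
    best = None
    for adj in all_unrooted_topologies(taxa):
        A, pairs = _paths_matrix(adj, taxa)
        d = np.array([dist[p] for p in pairs])
        lengths, *_ = np.linalg.lstsq(A, d, rcond=None)
        total = lengths.sum()
        key = (round(total, 9), sorted(map(sorted, topology_bipartitions(
            adj, taxa))))
        if best is None or key < best[0]:
            best = (key, topology_bipartitions(adj, taxa))
    return best[1]


def random_additive_tree(taxa: list[str], rng) -> dict:
    """A random binary topology with uniform branch lengths; returns the
    additive pairwise distance dict plus the true bipartitions."""
    adj = {0: {taxa[0], taxa[1], taxa[2]},
           taxa[0]: {0}, taxa[1]: {0}, taxa[2]: {0}}
    nxt = 1
    for tip in taxa[3:]:
        edges = sorted({frozenset((a, b)) for a in adj for b in adj[a]},
                       key=lambda e: sorted(map(str, e)))
        a, b = tuple(edges[rng.integers(len(edges))])
        adj[a].remove(b)
        adj[b].remove(a)
        adj[nxt] = {a, b, tip}
        adj[a].add(nxt)
        adj[b].add(nxt)
        adj[tip] = {nxt}
        nxt += 1
    edges = sorted({frozenset((a, b)) for a in adj for b in adj[a]},
                   key=lambda e: sorted(map(str, e)))
    lengths = {e: float(rng.uniform(0.1, 1.0)) for e in edges}
    A, pairs = _paths_matrix(adj, taxa)
    dvals = A @ np.array([lengths[e] for e in edges])
    dist = {p: float(v) for p, v in zip(pairs, dvals)}
    return dist, topology_bipartitions(adj, taxa)


# ---------------------------------------------------------------------------
# Dollo loss minimization: exhaustive subset search


def exhaustive_min_losses(tree, present: set[str], origin_name: str) -> int:
    """Smallest number of lost branches explaining the absent tips.

    Candidate branches are nodes below (or at) the origin whose subtrees
    contain no present tip; search all subsets for exact cover of the
    absent tips.
    """
    origin = tree.find(origin_name)
    below = tree.tipset_below()
    scope = below[id(origin)]
    absent = scope - present
    if not absent:
        return 0
    if not (scope & present):
        return 1
    candidates = []
    stack = [origin]
    while stack:
        node = stack.pop()
        tips = below[id(node)]
        if tips and not (tips & present):
            candidates.append(tips)
        stack.extend(node.children)
    for size in range(1, len(candidates) + 1):
        for combo in itertools.combinations(candidates, size):
            covered = set().union(*combo)
            if covered == absent:
                return size
    raise AssertionError("no cover found")  # pragma: no cover


def random_rooted_tree(n_tips: int, rng):
    """Random rooted binary tree with tips t0..t(n-1), unit lengths."""
    from type3copper.trees import Node, Tree
    tips = [Node(name=f"t{i}", length=1.0) for i in range(n_tips)]
    nodes = list(tips)
    while len(nodes) > 1:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        b = nodes.pop(j)
        parent = Node(length=1.0)
        parent.add(a)
        parent.add(b)
        nodes.append(parent)
    root = nodes[0]
    root.name = "root"
    root.length = 0.0
    return Tree(root, rooted=True)
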
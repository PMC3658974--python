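"""Motif-anchored alignment, distances, neighbor joining, bootstrap.

The copper-binding region is aligned by pinning the six histidine
positions of each record's binuclear site into shared anchor columns and
gap-padding the intervening blocks; distances are p-distances (optionally
Poisson-corrected) with pairwise deletion of gap/X columns; trees come
from Saitou-Nei neighbor joining with deterministic tie-breaking,
midpoint rooting, and nonparametric bootstrap support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DataError, TreeError
from .motif_engine import BinuclearSite
from .seqio import ProteinRecord
from .trees import Node, Tree, _reverse_chain, _suppress_unifurcations

log = logging.getLogger(__name__)

GAP = "-"


@dataclass(frozen=True)
class AnchoredAlignment:
    """Equal-length rows with six pinned histidine anchor columns."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    anchor_columns: tuple[int, ...]     # the six His columns
    region_starts: tuple[int, ...]      # original 0-based start per row

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, record_id: str) -> str:
        return self.rows[self.ids.index(record_id)]


def anchor_align(records: list[ProteinRecord],
                 sites: dict[str, BinuclearSite],
                 flank: int = 10) -> AnchoredAlignment:
    """Align copper-binding regions on their six histidine anchors.

    Each record contributes the region from ``flank`` residues before the
    Cu(A) H1 to ``flank`` after the Cu(B) H3 (clipped at the sequence
    ends), split into seven blocks around the six His anchors.  Blocks
    are left-justified and right-padded with gaps to the block maximum.
    Rows are ordered by record id.
    """
    if not records:
        raise DataError("anchor_align needs at least one record")
    ordered = sorted(records, key=lambda r: r.id)
    pieces = []
    for rec in ordered:
        site = sites.get(rec.id)
        if site is None:
            raise DataError(f"record {rec.id!r} has no binuclear site")
        seq = rec.sequence
        a, b = site.cuA, site.cuB
        start = max(0, a.h1 - flank)
        end = min(len(seq), b.h3 + 1 + flank)
        blocks = [
            seq[start:a.h1],
            seq[a.h1 + 1:a.h2],
            seq[a.h2 + 1:a.h3],
            seq[a.h3 + 1:b.h1],
            seq[b.h1 + 1:b.h2],
            seq[b.h2 + 1:b.h3],
            seq[b.h3 + 1:end],
        ]
        anchors = [seq[p] for p in (a.h1, a.h2, a.h3, b.h1, b.h2, b.h3)]
        pieces.append((rec.id, blocks, start, anchors))

    widths = [max(len(p[1][k]) for p in pieces) for k in range(7)]
    rows, ids, starts = [], [], []
    for rec_id, blocks, start, anchors in pieces:
        cells = []
        for k in range(7):
            cells.append(blocks[k].ljust(widths[k], GAP))
            if k < 6:
                cells.append(anchors[k])
        rows.append("".join(cells))
        ids.append(rec_id)
        starts.append(start)

    anchor_cols = []
    offset = 0
    for k in range(6):
        offset += widths[k]
        anchor_cols.append(offset)
        offset += 1
    return AnchoredAlignment(ids=tuple(ids), rows=tuple(rows),
                             anchor_columns=tuple(anchor_cols),
                             region_starts=tuple(starts))


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    matrix: np.ndarray          # symmetric, zero diagonal
    model: str = "p"

    def value(self, a: str, b: str) -> float:
        return float(self.matrix[self.ids.index(a), self.ids.index(b)])


def distances(aln: AnchoredAlignment, model: str = "p") -> DistanceMatrix:
    """Pairwise p-distances (or Poisson-corrected −ln(1−p)).

    Columns where either row carries a gap or X are deleted pairwise.
    A pair with no comparable columns, or p = 1 under the Poisson model,
    is a structured error.
    """
    if model not in ("p", "poisson"):
        raise DataError(f"unknown distance model {model!r}")
    n = len(aln.ids)
    if n < 2:
        raise DataError("distance matrix needs at least 2 rows")
    arr = np.array([list(row) for row in aln.rows])
    valid = (arr != GAP) & (arr != "X")
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                raise DataError(
                    f"no comparable columns between {aln.ids[i]!r} "
                    f"and {aln.ids[j]!r}")
            p = float((arr[i, both] != arr[j, both]).sum()) / m
            if model == "poisson":
                if p >= 1.0:
                    raise DataError(
                        f"p-distance 1.0 between {aln.ids[i]!r} and "
                        f"{aln.ids[j]!r}: Poisson correction undefined, "
                        "use model 'p'")
                d = -np.log(1.0 - p)
            else:
                d = p
            out[i, j] = out[j, i] = d
    return DistanceMatrix(ids=aln.ids, matrix=out, model=model)


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Q-criterion agglomeration; ties on Q are broken by the
    lexicographically smallest joined pair (clusters labelled by their
    smallest member id).  Negative branch-length estimates are clamped to
    zero with a logged note.  The result is unrooted (trifurcating
    anchor node).
    """
    n = len(dm.ids)
    if n < 3:
        raise DataError("neighbor joining needs at least 3 taxa")
    d = dm.matrix.astype(float).copy()
    nodes = [Node(name=name) for name in dm.ids]
    labels = list(dm.ids)          # smallest member id per cluster

    def clamp(x: float) -> float:
        if x < 0:
            log.info("clamped negative NJ branch length %.4g to 0", x)
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        totals = d.sum(axis=1)
        q = (m - 2) * d - totals[:, None] - totals[None, :]
        q = np.minimum(q, q.T)       # exact symmetry despite float rounding
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        candidates = [(i, j) for i in range(m) for j in range(i + 1, m)
                      if q[i, j] == qmin]
        i, j = min(candidates,
                   key=lambda ij: tuple(sorted((labels[ij[0]],
                                                labels[ij[1]]))))
        li = 0.5 * d[i, j] + (totals[i] - totals[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        parent = Node()
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = clamp(li)
        child_j.length = clamp(lj)
        parent.add(child_i)
        parent.add(child_j)

        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = new_d[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]

    root = Node()
    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = clamp(0.5 * (dab + dac - dbc))
    b.length = clamp(0.5 * (dab + dbc - dac))
    c.length = clamp(0.5 * (dac + dbc - dab))
    for node in (a, b, c):
        root.add(node)
    return Tree(root, rooted=False)


def midpoint_root(tree: Tree) -> Tree:
    """Root at the midpoint of the longest tip-to-tip path.

    Ties on the path length are broken by the lexicographically smallest
    tip pair; a midpoint falling exactly on a node roots the tree there.
    """
    dist = tree.tip_distances()
    if not dist or max(dist.values()) <= 0:
        raise TreeError("midpoint rooting needs positive path lengths")
    dmax = max(dist.values())
    a, b = min(pair for pair, v in dist.items() if v == dmax)
    half = dmax / 2.0

    # walk from tip a towards tip b accumulating branch length
    work = tree.copy()
    node_a = work.find(a)
    path = _path_between(work, node_a, work.find(b))
    walked = 0.0
    for step, edge_len, child_side in path:
        if walked + edge_len >= half - 1e-12:
            want = half - walked
            if child_side:
                # moving rootward along edge above `step`
                dist_from_child = want
                target = step
            else:
                # moving tipward: edge above `step`, from the parent end
                dist_from_child = edge_len - want
                target = step
            if abs(dist_from_child) < 1e-12 and not target.is_tip:
                # midpoint exactly on the child node
                return _root_at_node(work, target)
            if abs(dist_from_child - target.length) < 1e-12 \
                    and target.parent is not None \
                    and not target.parent.is_tip:
                return _root_at_node(work, target.parent)
            return work.rooted_at_edge(target, dist_from_child)
        walked += edge_len
    raise TreeError("midpoint not found on path")  # pragma: no cover


def _path_between(tree: Tree, a: Node, b: Node):
    """Edges along the a->b path as (edge-child-node, length, rootward)."""
    anc_a = []
    node = a
    while node is not None:
        anc_a.append(node)
        node = node.parent
    anc_set = {id(n): k for k, n in enumerate(anc_a)}
    # climb from b to the common ancestor
    up_b = []
    node = b
    while id(node) not in anc_set:
        up_b.append(node)
        node = node.parent
    common_idx = anc_set[id(node)]
    path = []
    for k in range(common_idx):
        path.append((anc_a[k], anc_a[k].length, True))    # rootward steps
    for node in reversed(up_b):
        path.append((node, node.length, False))           # tipward steps
    return path


def _root_at_node(tree: Tree, node: Node) -> Tree:
    """Make ``node`` (a node of ``tree``, which may be mutated) the root."""
    if node.parent is None:
        out = tree.copy()
        out.rooted = True
        return out
    parent = node.parent
    parent.children.remove(node)
    length = node.length
    node.parent = None
    node.length = 0.0
    flipped = _reverse_chain(parent)
    node.add(flipped)
    flipped.length = length
    return Tree(_suppress_unifurcations(node), rooted=True)


def bootstrap_support(aln: AnchoredAlignment, model: str = "p",
                      replicates: int = 1000, seed: int = 0) -> Tree:
    """NJ tree with bootstrap support percentages on internal nodes.

    Columns are resampled with replacement; each replicate tree is rebuilt
    with the same distance model; support is the percentage of replicates
    containing each original bipartition.  Fully reproducible for a fixed
    seed.  Replicates whose resampled columns leave a pair with no
    comparable data are counted as not supporting any bipartition.
    """
    if replicates < 1:
        raise DataError("need at least one bootstrap replicate")
    base = nj_tree(distances(aln, model))
    target = base.bipartitions()
    hits = {part: 0 for part in target}
    rng = np.random.default_rng(seed)
    arr = np.array([list(row) for row in aln.rows])
    ncol = arr.shape[1]
    for _ in range(replicates):
        cols = rng.integers(0, ncol, size=ncol)
        sub = arr[:, cols]
        rep_aln = AnchoredAlignment(
            ids=aln.ids,
            rows=tuple("".join(row) for row in sub),
            anchor_columns=(), region_starts=aln.region_starts)
        try:
            rep_tree = nj_tree(distances(rep_aln, model))
        except DataError:
            continue
        found = rep_tree.bipartitions()
        for part in target:
            if part in found:
                hits[part] += 1

    out = base.copy()
    below = out.tipset_below()
    all_tips = frozenset(out.tip_names())
    anchor_tip = min(all_tips)
    for node in out.preorder():
        if node is out.root or node.is_tip:
            continue
        side = below[id(node)]
        if anchor_tip in side:
            side = all_tips - side
        if side in hits:
            node.support = 100.0 * hits[side] / replicates
    return out


def is_monophyletic(tree: Tree, tip_subset) -> bool:
    """True iff a bipartition of the unrooted tree isolates the subset."""
    subset = frozenset(tip_subset)
    if not subset:
        raise DataError("empty tip subset")
    all_tips = frozenset(tree.tip_names())
    unknown = subset - all_tips
    if unknown:
        raise DataError(f"unknown tips: {sorted(unknown)}")
    if subset == all_tips:
        return True
    below = tree.tipset_below()
    for node in tree.preorder():
        if node is tree.root:
            continue
        side = below[id(node)]
        if side == subset or side == all_tips - subset:
            return True
    return False


def clade_support(tree: Tree, tip_subset) -> float | None:
    """Support of the bipartition isolating the subset, if present."""
    subset = frozenset(tip_subset)
    all_tips = frozenset(tree.tip_names())
    anchor_tip = min(all_tips)
    canonical = all_tips - subset if anchor_tip in subset else subset
    below = tree.tipset_below()
    for node in tree.preorder():
        if node is tree.root or node.is_tip:
            continue
        side = below[id(node)]
        if anchor_tip in side:
            side = all_tips - side
        if side == canonical:
            return node.support
    return None


def mean_interclass_divergence(dm: DistanceMatrix,
                               labels: dict[str, str]) -> dict[str, float]:
    """Per class: mean distance from its members to all other classes."""
    missing = [i for i in dm.ids if i not in labels]
    if missing:
        raise DataError(f"unlabelled taxa: {missing}")
    classes = sorted(set(labels.values()))
    members = {c: [k for k, i in enumerate(dm.ids) if labels[i] == c]
               for c in classes}
    for c, idx in members.items():
        if not idx:
            raise DataError(f"class {c!r} has no members")
    out = {}
    for c in classes:
        inside = members[c]
        outside = [k for k in range(len(dm.ids)) if k not in inside]
        if not outside:
            raise DataError("need at least two classes")
        out[c] = float(dm.matrix[np.ix_(inside, outside)].mean())
    return out
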
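"""A small rooted/unrooted tree structure with deterministic newick I/O.

The phylogenetics here (neighbor joining, midpoint rooting, bootstrap,
Dollo loss mapping) needs full control over tie-breaking and formatting,
so the tree container is owned by the package; newick *parsing* is
delegated to dendropy and converted into this structure.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import dendropy

from .errors import TreeError


@dataclass
class Node:
    name: str | None = None
    length: float = 0.0           # branch length to parent; 0 at the root
    support: float | None = None  # bootstrap percentage in [0, 100]
    children: list["Node"] = field(default_factory=list)
    parent: "Node | None" = field(default=None, repr=False)

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child


class Tree:
    """A tree over uniquely named tips.

    ``rooted`` marks whether the root is a true root (midpoint-rooted or a
    species tree) or merely the trifurcating anchor of an unrooted tree.
    """

    def __init__(self, root: Node, rooted: bool = False):
        self.root = root
        self.rooted = rooted
        names = [t.name for t in self.tips()]
        if len(set(names)) != len(names):
            raise TreeError("tip names are not unique")

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    def tip_names(self) -> list[str]:
        return [n.name for n in self.tips()]

    def find(self, name: str) -> Node:
        for node in self.preorder():
            if node.name == name:
                return node
        raise TreeError(f"no node named {name!r}")

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            new = Node(name=node.name, length=node.length,
                       support=node.support)
            for child in node.children:
                new.add(clone(child))
            return new
        return Tree(clone(self.root), rooted=self.rooted)

    # -- structure queries -------------------------------------------------

    def tipset_below(self) -> dict[int, frozenset[str]]:
        """Map id(node) -> frozenset of tip names under that node."""
        below: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_tip:
                below[id(node)] = frozenset([node.name])
            else:
                acc: set[str] = set()
                for child in node.children:
                    acc |= below[id(child)]
                below[id(node)] = frozenset(acc)
        return below

    def bipartitions(self, include_trivial: bool = False
                     ) -> set[frozenset[str]]:
        """Bipartitions of the *unrooted* tree, each given as the tip set
        on the child side of an edge (canonicalized to the side not
        containing the lexicographically smallest tip name)."""
        all_tips = frozenset(self.tip_names())
        anchor = min(all_tips)
        below = self.tipset_below()
        parts: set[frozenset[str]] = set()
        for node in self.preorder():
            if node is self.root:
                continue
            raw = below[id(node)]
            if not raw or raw == all_tips:
                continue
            trivial = min(len(raw), len(all_tips) - len(raw)) < 2
            if trivial and not include_trivial:
                continue
            side = all_tips - raw if anchor in raw else raw
            parts.add(side)
        return parts

    def tip_distances(self) -> dict[tuple[str, str], float]:
        """All pairwise tip-to-tip path lengths."""
        # distances from each node down to tips, merged at internal nodes
        dist: dict[tuple[str, str], float] = {}
        down: dict[int, dict[str, float]] = {}
        for node in self.postorder():
            if node.is_tip:
                down[id(node)] = {node.name: 0.0}
            else:
                merged: dict[str, float] = {}
                buckets = []
                for child in node.children:
                    bucket = {name: d + child.length
                              for name, d in down[id(child)].items()}
                    buckets.append(bucket)
                for i in range(len(buckets)):
                    for j in range(i + 1, len(buckets)):
                        for a, da in buckets[i].items():
                            for b, db in buckets[j].items():
                                key = (a, b) if a < b else (b, a)
                                dist[key] = da + db
                for bucket in buckets:
                    merged.update(bucket)
                down[id(node)] = merged
        return dist

    # -- rerooting ---------------------------------------------------------

    def rooted_at_edge(self, child: Node, dist_from_child: float) -> "Tree":
        """Return a new tree rooted on the edge above ``child``, at
        ``dist_from_child`` along that edge towards the parent."""
        if child.parent is None:
            raise TreeError("cannot root above the root node")
        if dist_from_child < -1e-12 or dist_from_child > child.length + 1e-12:
            raise TreeError("root position outside the edge")
        tree = self.copy()
        # relocate child in the copy by path of child indices
        path = []
        node = child
        while node.parent is not None:
            path.append(node.parent.children.index(node))
            node = node.parent
        target = tree.root
        for idx in reversed(path):
            target = target.children[idx]

        dist_from_child = min(max(dist_from_child, 0.0), target.length)
        upper = target.length - dist_from_child
        old_parent = target.parent
        old_parent.children.remove(target)
        target.parent = None

        new_root = Node(name=None)
        new_root.add(target)
        target.length = dist_from_child

        # reverse the chain of ancestors of target
        flipped = _reverse_chain(old_parent)
        new_root.add(flipped)
        flipped.length = upper
        return Tree(_suppress_unifurcations(new_root), rooted=True)


def _reverse_chain(node: Node) -> Node:
    """Reverse parent pointers so ``node`` becomes a child-side subtree."""
    parent = node.parent
    node.parent = None
    if parent is not None:
        parent.children.remove(node)
        sub = _reverse_chain(parent)
        node.add(sub)
        sub.length = node.length
    return node


def _suppress_unifurcations(root: Node) -> Node:
    """Collapse internal nodes with a single child (root kept)."""
    def walk(node: Node):
        for child in list(node.children):
            walk(child)
        if len(node.children) == 1 and node.parent is not None:
            only = node.children[0]
            only.length += node.length
            only.support = only.support or node.support
            parent = node.parent
            idx = parent.children.index(node)
            parent.children[idx] = only
            only.parent = parent
    walk(root)
    if len(root.children) == 1:
        only = root.children[0]
        only.length = 0.0
        only.parent = None
        return only
    return root


# -- newick I/O -------------------------------------------------------------


def _fmt_length(x: float) -> str:
    if x == int(x):
        return f"{x:.1f}"
    return format(x, ".10g")


def to_newick(tree: Tree) -> str:
    """Serialize with branch lengths and supports as internal labels."""
    for tip in tree.tips():
        if not tip.name:
            raise TreeError("tree has unnamed tips")

    def render(node: Node) -> str:
        if node.is_tip:
            return f"{node.name}:{_fmt_length(node.length)}"
        inner = ",".join(render(c) for c in node.children)
        label = ""
        if node.support is not None:
            label = _fmt_support(node.support)
        elif node.name:
            label = node.name
        if node is tree.root:
            return f"({inner}){label}"
        return f"({inner}){label}:{_fmt_length(node.length)}"

    return render(tree.root) + ";"


def _fmt_support(s: float) -> str:
    return str(int(s)) if float(s) == int(s) else format(s, ".4g")


def write_newick(tree: Tree, path: str | Path) -> None:
    if len(tree.tips()) < 2:
        raise TreeError("refusing to write a tree with < 2 tips")
    for node in tree.preorder():
        if node is not tree.root and node.length < 0:
            raise TreeError("negative branch length")
    Path(path).write_text(to_newick(tree) + "\n", encoding="utf-8")


def parse_newick(source: str | Path, internal_labels: str = "name",
                 rooted: bool = True) -> Tree:
    """Parse newick via dendropy into a :class:`Tree`.

    ``internal_labels`` is ``"name"`` for species trees with named clades
    or ``"support"`` for phylogram output with bootstrap labels.
    """
    text = source if isinstance(source, str) and "(" in str(source) \
        else Path(source).read_text(encoding="utf-8")
    dtree = dendropy.Tree.get(data=text, schema="newick",
                              suppress_internal_node_taxa=True)

    def convert(dnode) -> Node:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = Node(length=dnode.edge.length or 0.0)
        if dnode.is_leaf():
            node.name = label
        elif label:
            if internal_labels == "support":
                node.support = float(label)
            else:
                node.name = label
        for dchild in dnode.child_nodes():
            node.add(convert(dchild))
        return node

    return Tree(convert(dtree.seed_node), rooted=rooted)
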
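"""Dollo-style subclass loss reconstruction and expansion flagging.

Each subclass is assumed to have arisen exactly once, at a fixed node of
the species tree (α at the root, β on the unikont stem, γ on the
metazoan stem), after which it can only be lost.  Given a
presence/absence matrix, the minimal set of branches whose loss explains
every absent tip inside the origin subtree is the set of maximal
all-absent subtrees — computed bottom-up.  Species whose per-subclass
gene counts reach a threshold are flagged as lineage-specific
expansions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .classify import SUBCLASSES, CensusTable
from .errors import DataError
from .trees import Node, Tree

DEFAULT_ORIGINS = {"alpha": "root", "beta": "unikonta", "gamma": "metazoa"}


@dataclass(frozen=True)
class PresenceMatrix:
    """Boolean presence per (species, subclass)."""

    table: pd.DataFrame      # index species, columns alpha/beta/gamma

    @classmethod
    def from_census(cls, census: CensusTable) -> "PresenceMatrix":
        return cls((census.counts[list(SUBCLASSES)] > 0))

    def present_species(self, subclass: str) -> set[str]:
        col = self.table[subclass]
        return set(col.index[col])


def infer_losses(tree: Tree, presence: PresenceMatrix,
                 origins: Mapping[str, str], subclass: str) -> list[str]:
    """Minimal Dollo loss branches for one subclass.

    Returns the names of the nodes whose parent branch was lost: every
    such node's subtree contains only absent tips, the set covers every
    absent tip inside the origin subtree, and no smaller branch set does.
    A species present *outside* the origin subtree contradicts the
    single-origin hypothesis and is a structured error.
    """
    if subclass not in origins:
        raise DataError(f"no origin node for subclass {subclass!r}")
    origin = tree.find(origins[subclass])
    tips_under = tree.tipset_below()
    in_scope = tips_under[id(origin)]
    present = presence.present_species(subclass)
    unknown = present - set(tree.tip_names())
    if unknown:
        raise DataError(f"species not in tree: {sorted(unknown)}")
    outside = present - in_scope
    if outside:
        raise DataError(
            f"subclass {subclass!r} present outside its origin subtree "
            f"({origins[subclass]!r}): {sorted(outside)} conflict with "
            "the single-origin hypothesis")

    # bottom-up: a branch is a loss iff its subtree is all-absent and its
    # parent's subtree is not (maximal all-absent subtrees)
    losses: list[str] = []

    def all_absent(node: Node) -> bool:
        return not (tips_under[id(node)] & present)

    if all_absent(origin):
        return [_node_name(origin)]

    stack = [origin]
    while stack:
        node = stack.pop()
        for child in node.children:
            if all_absent(child):
                losses.append(_node_name(child))
            else:
                stack.append(child)
    return sorted(losses)


def _node_name(node: Node) -> str:
    if node.name:
        return node.name
    # stable synthetic name for unnamed internal nodes
    tips = sorted(t.name for t in _tips_below(node))
    return "mrca(" + ",".join(tips) + ")"


def _tips_below(node: Node) -> list[Node]:
    out, stack = [], [node]
    while stack:
        n = stack.pop()
        if n.is_tip:
            out.append(n)
        stack.extend(n.children)
    return out


def flag_expansions(census: CensusTable, threshold: int = 4
                    ) -> list[tuple[str, str, int]]:
    """(species, subclass, count) with count >= threshold, largest first."""
    hits = []
    for species in census.counts.index:
        for subclass in SUBCLASSES:
            count = int(census.counts.loc[species, subclass])
            if count >= threshold:
                hits.append((species, subclass, count))
    hits.sort(key=lambda t: (-t[2], t[0], t[1]))
    return hits


@dataclass(frozen=True)
class EvolutionReport:
    losses: dict[str, list[str]]                  # subclass -> branches
    expansions: list[tuple[str, str, int]]
    species_without_proteins: list[str]

    def to_rows(self) -> list[dict]:
        rows = []
        for subclass in SUBCLASSES:
            for branch in self.losses.get(subclass, []):
                rows.append({"event": "loss", "subclass": subclass,
                             "where": branch, "count": ""})
        for species, subclass, count in self.expansions:
            rows.append({"event": "expansion", "subclass": subclass,
                         "where": species, "count": count})
        for species in self.species_without_proteins:
            rows.append({"event": "no_type3_proteins", "subclass": "",
                         "where": species, "count": 0})
        return rows


def evolution_report(tree: Tree, census: CensusTable,
                     origins: Mapping[str, str] = DEFAULT_ORIGINS,
                     expansion_threshold: int = 4) -> EvolutionReport:
    """Per-subclass loss branches, expansion flags, and empty genomes."""
    presence = PresenceMatrix.from_census(census)
    losses = {}
    for subclass in SUBCLASSES:
        if len(tree.tips()) < 2:
            losses[subclass] = []
            continue
        losses[subclass] = infer_losses(tree, presence, origins, subclass)
    return EvolutionReport(
        losses=losses,
        expansions=flag_expansions(census, expansion_threshold),
        species_without_proteins=census.species_with_none(),
    )
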
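"""Tandem gene-cluster detection from genomic coordinates.

Lineage-specific subclass expansions tend to leave physically linked
paralogs on one scaffold; this module chains loci along each scaffold by
single linkage on the intergenic distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .errors import DataError
from .seqio import GeneLocus


@dataclass(frozen=True)
class GeneCluster:
    """Two or more linked genes on one scaffold."""

    members: tuple[GeneLocus, ...]    # ordered by start
    scaffold: str
    subclass: str                     # homogeneous tag or "mixed"

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def max_intergenic_gap(self) -> int:
        gaps = [b.start - a.end
                for a, b in zip(self.members, self.members[1:])]
        return max(gaps) if gaps else 0


def find_clusters(loci: Iterable[GeneLocus],
                  calls: Optional[Mapping[str, str]] = None,
                  max_gap: int = 50_000,
                  same_subclass_only: bool = True) -> list[GeneCluster]:
    """Single-linkage chaining of loci along scaffolds.

    Consecutive loci (sorted by start) join one cluster iff the gap
    ``next.start - prev.end`` is <= ``max_gap`` and, when
    ``same_subclass_only``, their subclass calls match.  Singletons are
    discarded.  Strand never affects membership.  Output is sorted by
    (scaffold, start), independent of input ordering.
    """
    loci = list(loci)
    if same_subclass_only:
        if calls is None:
            raise DataError("same_subclass_only needs subclass calls")
        missing = sorted({loc.protein_id for loc in loci} - set(calls))
        if missing:
            raise DataError(f"loci reference unclassified proteins: "
                            f"{missing}")

    def subclass_of(loc: GeneLocus) -> str:
        return calls.get(loc.protein_id, "") if calls else ""

    by_scaffold: dict[str, list[GeneLocus]] = {}
    for loc in loci:
        by_scaffold.setdefault(loc.scaffold, []).append(loc)

    clusters: list[GeneCluster] = []
    for scaffold in sorted(by_scaffold):
        chain: list[GeneLocus] = []
        for loc in sorted(by_scaffold[scaffold],
                          key=lambda l: (l.start, l.end, l.protein_id)):
            if chain:
                prev = chain[-1]
                joined = loc.start - prev.end <= max_gap
                if joined and same_subclass_only:
                    joined = subclass_of(loc) == subclass_of(prev)
                if joined:
                    chain.append(loc)
                    continue
                _flush(chain, clusters, subclass_of)
            chain = [loc]
        _flush(chain, clusters, subclass_of)
    return clusters


def _flush(chain, clusters, subclass_of):
    if len(chain) < 2:
        return
    tags = {subclass_of(loc) for loc in chain}
    tag = tags.pop() if len(tags) == 1 else "mixed"
    clusters.append(GeneCluster(members=tuple(chain),
                                scaffold=chain[0].scaffold,
                                subclass=tag))
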
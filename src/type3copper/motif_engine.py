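"""Detection of binuclear copper-binding sites by motif grammar.

Type-3 copper proteins coordinate two copper atoms, Cu(A) and Cu(B), each
through three histidines.  In sequence, the Cu(A) site follows an
H1(n)-H2(8)-H3 pattern and the Cu(B) site an H1(3)-H2(n)-H3 pattern,
where the parenthesised number counts residues strictly between the two
histidines and *n* is variable.  β-subclass proteins carry the Cu(A)
second histidine at a shifted position.  A conserved Phe sits four
residues upstream of H3 in both sites and a conserved Asp four residues
downstream of the Cu(B) H3; the residue covering the Cu(A) pocket (the
"placeholder", Phe in β, Val in γ, variable in α) gates monophenolase
activity.  This module finds histidine triads, pairs them into candidate
binuclear sites, and evaluates those diagnostic residues.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from .errors import DataError
from .seqio import ProteinRecord


@dataclass(frozen=True)
class ScanParams:
    """Spacing grammar and diagnostic offsets for the site scanner.

    Spacings count residues strictly between two histidines; offsets are
    index distances (upstream 4 means position ``h3 - 4``).
    """

    cuA_h1_h2_range: tuple[int, int] = (2, 40)
    cuA_h2_h3_fixed: int = 8
    cuA_h2_h3_beta_range: tuple[int, int] = (6, 12)
    cuB_h1_h2_fixed: int = 3
    cuB_h2_h3_range: tuple[int, int] = (2, 40)
    intersite_gap_range: tuple[int, int] = (10, 400)
    phe_offset: int = 4
    asp_offset: int = 4
    cys_his_window: int = 2
    cys_region_pad: int = 20

    def __post_init__(self):
        for lo, hi in (self.cuA_h1_h2_range, self.cuA_h2_h3_beta_range,
                       self.cuB_h2_h3_range, self.intersite_gap_range):
            if lo > hi:
                raise DataError(f"empty range ({lo}, {hi}) in scan params")
        if self.cuA_h2_h3_fixed < 1 or self.cuB_h1_h2_fixed < 1:
            raise DataError("fixed spacings must be >= 1")
        if self.phe_offset < 1 or self.asp_offset < 1:
            raise DataError("diagnostic offsets must be >= 1")


@dataclass(frozen=True)
class CopperSite:
    """One histidine triad: kind 'A' or 'B', 0-based His positions."""

    kind: str
    h1: int
    h2: int
    h3: int

    @property
    def spacing12(self) -> int:
        return self.h2 - self.h1 - 1

    @property
    def spacing23(self) -> int:
        return self.h3 - self.h2 - 1


@dataclass(frozen=True)
class PlaceholderConvention:
    """Sequence-level stand-in for the structurally defined placeholder:
    the residue at ``anchor + offset`` where anchor is one of the six His
    positions (named ``cuA.h1`` ... ``cuB.h3``)."""

    anchor: str = "cuB.h1"
    offset: int = -6


@dataclass(frozen=True)
class BinuclearSite:
    """A paired Cu(A)/Cu(B) site with its diagnostic evaluation."""

    cuA: CopperSite
    cuB: CopperSite
    shifted_h2: bool = False
    phe_A_ok: bool = False
    phe_B_ok: bool = False
    asp_B_ok: bool = False
    placeholder_residue: Optional[str] = None
    placeholder_position: Optional[int] = None
    cys_his_bond_candidate: bool = False
    disulfide_candidate_count: int = 0

    @property
    def intersite_gap(self) -> int:
        return self.cuB.h1 - self.cuA.h3 - 1

    @property
    def score(self) -> int:
        """2 − shifted + #diagnostics present; higher is better."""
        return (2 - (1 if self.shifted_h2 else 0)
                + int(self.phe_A_ok) + int(self.phe_B_ok)
                + int(self.asp_B_ok))


def scan_his_triads(record: ProteinRecord, kind: str,
                    params: ScanParams = ScanParams()) -> list[CopperSite]:
    """Every His triple satisfying the spacing grammar for ``kind``.

    Exhaustive over all histidine triples, ordered by h1 (then h2, h3)
    ascending.  Sequences with fewer than three histidines yield [].
    """
    if kind not in ("A", "B"):
        raise DataError(f"site kind must be 'A' or 'B', got {kind!r}")
    seq = record.sequence
    his = [i for i, ch in enumerate(seq) if ch == "H"]
    sites: list[CopperSite] = []
    if kind == "A":
        lo12, hi12 = params.cuA_h1_h2_range
        blo, bhi = params.cuA_h2_h3_beta_range
        allowed23 = set(range(blo, bhi + 1)) | {params.cuA_h2_h3_fixed}
        for h1 in his:
            for h2 in his:
                s12 = h2 - h1 - 1
                if s12 < lo12:
                    continue
                if s12 > hi12:
                    break
                for h3 in his:
                    if h3 <= h2:
                        continue
                    if h3 - h2 - 1 in allowed23:
                        sites.append(CopperSite("A", h1, h2, h3))
                    elif h3 - h2 - 1 > max(allowed23):
                        break
    else:
        lo23, hi23 = params.cuB_h2_h3_range
        for h1 in his:
            h2 = h1 + params.cuB_h1_h2_fixed + 1
            if seq[h2:h2 + 1] != "H":
                continue
            for h3 in his:
                s23 = h3 - h2 - 1
                if s23 < lo23:
                    continue
                if s23 > hi23:
                    break
                sites.append(CopperSite("B", h1, h2, h3))
    sites.sort(key=lambda s: (s.h1, s.h2, s.h3))
    return sites


def check_diagnostics(record: ProteinRecord, site: BinuclearSite,
                      params: ScanParams = ScanParams()) -> BinuclearSite:
    """Fill the conserved Phe/Asp flags.  Out-of-bounds probes are False."""
    seq = record.sequence

    def at(pos: int) -> str:
        return seq[pos] if 0 <= pos < len(seq) else ""

    return replace(
        site,
        phe_A_ok=at(site.cuA.h3 - params.phe_offset) == "F",
        phe_B_ok=at(site.cuB.h3 - params.phe_offset) == "F",
        asp_B_ok=at(site.cuB.h3 + params.asp_offset) == "D",
    )


def extract_placeholder(record: ProteinRecord, site: BinuclearSite,
                        convention: PlaceholderConvention =
                        PlaceholderConvention()
                        ) -> tuple[Optional[str], Optional[int]]:
    """Residue at the placeholder convention position, or (None, None)."""
    anchors = {
        "cuA.h1": site.cuA.h1, "cuA.h2": site.cuA.h2, "cuA.h3": site.cuA.h3,
        "cuB.h1": site.cuB.h1, "cuB.h2": site.cuB.h2, "cuB.h3": site.cuB.h3,
    }
    if convention.anchor not in anchors:
        raise DataError(f"unknown placeholder anchor {convention.anchor!r}")
    pos = anchors[convention.anchor] + convention.offset
    if pos < 0 or pos >= len(record.sequence):
        return None, None
    residue = record.sequence[pos]
    if residue == "X":
        return None, None
    return residue, pos


def flag_cys_features(record: ProteinRecord, site: BinuclearSite,
                      params: ScanParams = ScanParams()) -> BinuclearSite:
    """Sequence-level cysteine proxies for Table-style features.

    A Cys within ±cys_his_window of the Cu(A) H2 (excluding H2 itself)
    marks a thioether Cys-His bond candidate; remaining cysteines inside
    the padded active-site region are counted in pairs as disulfide-bridge
    candidates.
    """
    seq = record.sequence
    h2 = site.cuA.h2
    w = params.cys_his_window
    bond_positions = [i for i in range(max(0, h2 - w),
                                       min(len(seq), h2 + w + 1))
                      if i != h2 and seq[i] == "C"]
    lo = max(0, site.cuA.h1 - params.cys_region_pad)
    hi = min(len(seq) - 1, site.cuB.h3 + params.cys_region_pad)
    region_cys = [i for i in range(lo, hi + 1)
                  if seq[i] == "C" and i not in bond_positions]
    return replace(site,
                   cys_his_bond_candidate=bool(bond_positions),
                   disulfide_candidate_count=len(region_cys) // 2)


def pair_sites(record: ProteinRecord, sitesA: list[CopperSite],
               sitesB: list[CopperSite],
               params: ScanParams = ScanParams(),
               convention: PlaceholderConvention = PlaceholderConvention()
               ) -> list[BinuclearSite]:
    """All compatible Cu(A)/Cu(B) pairings, fully evaluated and scored.

    A pairing requires Cu(A) strictly before Cu(B) with the intersite gap
    (residues strictly between Cu(A) H3 and Cu(B) H1) inside the allowed
    range.  Output sorted by score descending, then leftmost Cu(A), then
    leftmost Cu(B).
    """
    lo, hi = params.intersite_gap_range
    out: list[BinuclearSite] = []
    for a in sitesA:
        for b in sitesB:
            gap = b.h1 - a.h3 - 1
            if gap < lo or gap > hi:
                continue
            site = BinuclearSite(
                cuA=a, cuB=b,
                shifted_h2=(a.spacing23 != params.cuA_h2_h3_fixed))
            site = check_diagnostics(record, site, params)
            residue, pos = extract_placeholder(record, site, convention)
            site = replace(site, placeholder_residue=residue,
                           placeholder_position=pos)
            site = flag_cys_features(record, site, params)
            out.append(site)
    out.sort(key=lambda s: (-s.score, s.cuA.h1, s.cuB.h1,
                            s.cuA.h2, s.cuA.h3, s.cuB.h2, s.cuB.h3))
    return out


def best_binuclear_site(record: ProteinRecord,
                        params: ScanParams = ScanParams(),
                        convention: PlaceholderConvention =
                        PlaceholderConvention()
                        ) -> Optional[BinuclearSite]:
    """Top-scoring binuclear site (ties: leftmost), or None."""
    sitesA = scan_his_triads(record, "A", params)
    sitesB = scan_his_triads(record, "B", params)
    paired = pair_sites(record, sitesA, sitesB, params, convention)
    return paired[0] if paired else None
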
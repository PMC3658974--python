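"""α/β/γ subclass assignment, functional compatibility, and census.

Subclass membership is architectural: a secreted form with a signal
peptide but no membrane anchor is α, a cytosolic form without a signal
peptide is β, and a membrane-bound form with both signal peptide and
transmembrane segment is γ.  Sequence-level features of the copper site
(shifted Cu(A) H2, placeholder identity, cysteine features) are treated
as supporting evidence that adjusts confidence but never overrides the
architecture.  The functional-feature table maps (subclass, lineage,
placeholder, Cys-His bond, disulfide count) to the compatible functional
classes (tyrosinase / catechol oxidase / hemocyanin); where the features
do not separate functions the full compatible set is returned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .architecture_scan import (ArchitectureParams, DomainArchitecture,
                                build_architecture)
from .errors import DataError
from .motif_engine import (BinuclearSite, PlaceholderConvention, ScanParams,
                           best_binuclear_site)
from .seqio import ProteinRecord

SUBCLASSES = ("alpha", "beta", "gamma")

#: Controlled vocabulary of lineage tags (phylogenetic colour-code groups).
VALID_LINEAGES = frozenset({
    "eubacteria", "archaebacteria", "plantae", "chromalveolata",
    "amoebozoa", "fungi", "choanoflagellata", "filasterea",
    "porifera", "placozoa", "cnidaria",
    "mollusca", "annelida", "platyhelminthes", "nematoda", "arthropoda",
    "onychophora", "hemichordata", "echinodermata", "cephalochordata",
    "urochordata", "vertebrata",
})


@dataclass(frozen=True)
class FeatureRow:
    """One row of the active-site feature table."""

    subclass: str
    lineage: str
    label: str                       # functional class
    placeholders: frozenset[str]     # allowed placeholder residues
    cys_his_bond: bool
    disulfide_bridges: int


#: Active-site structural differences per subclass and lineage group:
#: allowed placeholder residue(s), Cys-His thioether bond, and number of
#: disulfide bridges, for each functionally annotated group.
FEATURE_TABLE: tuple[FeatureRow, ...] = (
    # α subclass
    FeatureRow("alpha", "eubacteria", "tyrosinase",
               frozenset("V"), False, 0),
    FeatureRow("alpha", "archaebacteria", "tyrosinase",
               frozenset("V"), False, 0),
    FeatureRow("alpha", "plantae", "catechol_oxidase",
               frozenset("FL"), True, 2),
    FeatureRow("alpha", "chromalveolata", "tyrosinase",
               frozenset("V"), False, 0),
    FeatureRow("alpha", "amoebozoa", "tyrosinase",
               frozenset("V"), False, 0),
    FeatureRow("alpha", "fungi", "tyrosinase",
               frozenset("VLI"), True, 0),
    FeatureRow("alpha", "cnidaria", "tyrosinase",
               frozenset("V"), False, 0),
    FeatureRow("alpha", "mollusca", "hemocyanin",
               frozenset("L"), True, 2),
    FeatureRow("alpha", "mollusca", "tyrosinase",
               frozenset("VI"), False, 0),
    FeatureRow("alpha", "nematoda", "tyrosinase",
               frozenset("I"), False, 0),
    FeatureRow("alpha", "urochordata", "hemocyanin",
               frozenset("L"), True, 2),
    # β subclass
    FeatureRow("beta", "amoebozoa", "tyrosinase",
               frozenset("F"), False, 0),
    FeatureRow("beta", "fungi", "tyrosinase",
               frozenset("F"), False, 0),
    FeatureRow("beta", "porifera", "tyrosinase",
               frozenset("F"), False, 1),
    FeatureRow("beta", "arthropoda", "tyrosinase",
               frozenset("F"), False, 2),
    FeatureRow("beta", "arthropoda", "hemocyanin",
               frozenset("F"), False, 2),
    FeatureRow("beta", "hemichordata", "hemocyanin",
               frozenset("F"), False, 0),
    FeatureRow("beta", "urochordata", "tyrosinase",
               frozenset("F"), False, 0),
    # γ subclass
    FeatureRow("gamma", "porifera", "tyrosinase",
               frozenset("V"), False, 0),
    FeatureRow("gamma", "platyhelminthes", "tyrosinase",
               frozenset("V"), False, 0),
    FeatureRow("gamma", "annelida", "tyrosinase",
               frozenset("V"), False, 0),
    FeatureRow("gamma", "hemichordata", "tyrosinase",
               frozenset("V"), False, 0),
    FeatureRow("gamma", "cephalochordata", "tyrosinase",
               frozenset("V"), False, 0),
    FeatureRow("gamma", "urochordata", "tyrosinase",
               frozenset("V"), False, 0),
    FeatureRow("gamma", "vertebrata", "tyrosinase",
               frozenset("V"), False, 0),
)


@dataclass(frozen=True)
class SubclassCall:
    subclass: str                      # alpha | beta | gamma | unclassified
    evidence: tuple[str, ...] = ()
    discordant: tuple[str, ...] = ()
    confidence: int = 0
    functional_compat: frozenset[str] = frozenset()


def assign_subclass(arch: DomainArchitecture,
                    site: Optional[BinuclearSite]) -> SubclassCall:
    """Architecture-first subclass rule with evidence accounting.

    No binuclear site -> unclassified.  Otherwise: SP and TM -> gamma;
    SP without TM -> alpha; no SP -> beta.  Cys-rich region, shifted
    Cu(A) H2 and placeholder identity are supporting evidence: concordant
    items raise confidence, discordant items lower it (floor 1), and
    neither can flip the architectural call.
    """
    if site is None:
        return SubclassCall("unclassified")

    if arch.has_sp and arch.has_tm:
        subclass = "gamma"
        evidence = ["sp_present", "tm_present"]
    elif arch.has_sp:
        subclass = "alpha"
        evidence = ["sp_present", "tm_absent"]
    else:
        subclass = "beta"
        evidence = ["sp_absent"]

    support = {
        "cys_rich_present": "gamma",
        "shifted_h2": "beta",
        "placeholder_F": "beta",
        "placeholder_V": "gamma",
    }
    observed = []
    if arch.cys_rich_regions:
        observed.append("cys_rich_present")
    if site.shifted_h2:
        observed.append("shifted_h2")
    if site.placeholder_residue == "F":
        observed.append("placeholder_F")
    elif site.placeholder_residue == "V":
        observed.append("placeholder_V")

    discordant = []
    for item in observed:
        if support[item] == subclass:
            evidence.append(item)
        else:
            discordant.append(item)
    # tm_absent is a rule precondition, not a counted evidence item
    concordant = [e for e in evidence if e != "tm_absent"]
    confidence = max(1, len(concordant) - len(discordant))
    return SubclassCall(subclass, evidence=tuple(evidence),
                        discordant=tuple(discordant), confidence=confidence)


def functional_compatibility(call: SubclassCall, site: BinuclearSite,
                             lineage: str,
                             table: Iterable[FeatureRow] = FEATURE_TABLE
                             ) -> frozenset[str]:
    """Functional classes compatible with the observed active site.

    Matches every feature-table row for (subclass, lineage) whose
    placeholder set contains the observed placeholder and whose Cys-His
    bond flag and disulfide count equal the observed ones.  Several rows
    may match (the table does not always separate tyrosinase from
    hemocyanin); none matching yields the empty set.
    """
    if lineage not in VALID_LINEAGES:
        raise DataError(
            f"unknown lineage tag {lineage!r}; valid tags: "
            + ", ".join(sorted(VALID_LINEAGES)))
    if call.subclass not in SUBCLASSES:
        raise DataError("functional compatibility needs a classified record")
    labels = set()
    for row in table:
        if row.subclass != call.subclass or row.lineage != lineage:
            continue
        if (site.placeholder_residue in row.placeholders
                and site.cys_his_bond_candidate == row.cys_his_bond
                and site.disulfide_candidate_count == row.disulfide_bridges):
            labels.add(row.label)
    return frozenset(labels)


@dataclass
class CensusTable:
    """Per-species, per-subclass classified gene counts."""

    counts: pd.DataFrame        # index species, columns alpha/beta/gamma
    species_meta: pd.DataFrame  # index species, columns lineage, metazoan

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def count(self, species: str, subclass: str) -> int:
        if species not in self.counts.index:
            return 0
        return int(self.counts.loc[species, subclass])

    def n_species_with_protein(self, metazoan: bool) -> int:
        mask = self.species_meta["metazoan"] == metazoan
        species = self.species_meta.index[mask]
        present = self.counts.reindex(species).fillna(0).sum(axis=1) > 0
        return int(present.sum())

    def species_with_all_three(self) -> list[str]:
        mask = (self.counts[list(SUBCLASSES)] > 0).all(axis=1)
        return sorted(self.counts.index[mask])

    def species_with_none(self) -> list[str]:
        totals = self.counts.sum(axis=1)
        return sorted(totals.index[totals == 0])


def build_census(rows: Iterable[dict]) -> CensusTable:
    """Aggregate per-record classification rows into a census.

    Each row needs: species, lineage, metazoan (bool), subclass.  Species
    listed with zero classified records (subclass 'unclassified' or an
    explicit species-only row with subclass None) appear with zero counts.
    """
    rows = list(rows)
    species_meta: dict[str, dict] = {}
    counts: dict[str, dict[str, int]] = {}
    for row in rows:
        sp = row["species"]
        species_meta.setdefault(sp, {
            "lineage": row.get("lineage", ""),
            "metazoan": bool(row.get("metazoan", False)),
        })
        cell = counts.setdefault(sp, {s: 0 for s in SUBCLASSES})
        subclass = row.get("subclass")
        if subclass in SUBCLASSES:
            cell[subclass] += 1

    if not species_meta:
        empty = pd.DataFrame(columns=list(SUBCLASSES))
        meta = pd.DataFrame(columns=["lineage", "metazoan"])
        return CensusTable(empty, meta)

    species = sorted(species_meta)
    counts_df = pd.DataFrame(
        [[counts[sp][s] for s in SUBCLASSES] for sp in species],
        index=species, columns=list(SUBCLASSES))
    meta_df = pd.DataFrame(
        [[species_meta[sp]["lineage"], species_meta[sp]["metazoan"]]
         for sp in species],
        index=species, columns=["lineage", "metazoan"])
    return CensusTable(counts_df, meta_df)


# ---------------------------------------------------------------------------
# end-to-end per-record pipeline


@dataclass(frozen=True)
class ClassifiedRecord:
    record: ProteinRecord
    site: Optional[BinuclearSite]
    arch: DomainArchitecture
    call: SubclassCall

    def to_row(self, metazoan: Optional[bool] = None) -> dict:
        site = self.site
        return {
            "id": self.record.id,
            "species": self.record.species,
            "lineage": self.record.lineage,
            "metazoan": metazoan if metazoan is not None else "",
            "subclass": self.call.subclass,
            "confidence": self.call.confidence,
            "evidence": ",".join(self.call.evidence),
            "compat": ",".join(sorted(self.call.functional_compat)),
            "placeholder": site.placeholder_residue if site else "",
            "cys_his_bond": site.cys_his_bond_candidate if site else "",
            "disulfide_bridges": (site.disulfide_candidate_count
                                  if site else ""),
            "score": site.score if site else "",
        }


def classify_record(record: ProteinRecord,
                    scan_params: ScanParams = ScanParams(),
                    arch_params: ArchitectureParams = ArchitectureParams(),
                    convention: PlaceholderConvention =
                    PlaceholderConvention()) -> ClassifiedRecord:
    """Motif scan, architecture prediction, subclass call, compatibility."""
    site = best_binuclear_site(record, scan_params, convention)
    arch = build_architecture(record, arch_params)
    call = assign_subclass(arch, site)
    if site is not None and call.subclass in SUBCLASSES \
            and record.lineage in VALID_LINEAGES:
        compat = functional_compatibility(call, site, record.lineage)
        call = SubclassCall(call.subclass, call.evidence, call.discordant,
                            call.confidence, compat)
    return ClassifiedRecord(record=record, site=site, arch=arch, call=call)


def classify_records(records: Iterable[ProteinRecord],
                     scan_params: ScanParams = ScanParams(),
                     arch_params: ArchitectureParams = ArchitectureParams(),
                     convention: PlaceholderConvention =
                     PlaceholderConvention()) -> list[ClassifiedRecord]:
    return [classify_record(r, scan_params, arch_params, convention)
            for r in records]
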
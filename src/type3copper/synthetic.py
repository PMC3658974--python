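"""Synthetic protein, coordinate and census fixtures.

The generator is the constructive inverse of the classifier: it plants a
canonical binuclear copper site (His triads with the subclass spacing
grammar, conserved Phe/Asp diagnostics, the placeholder residue, and the
cysteine features of the per-lineage profile) into a background sequence
with the domain architecture of the requested subclass, then adds
substitution noise outside the planted (protected) positions.

The packaged census emulates a genome survey: 179 proteins across 35
metazoan and 17 non-metazoan species, with the named lineage-specific
expansions, exactly one species carrying all three subclasses, and four
species with no type-3 copper proteins at all.  Counts are fixed by the
census spec and therefore seed-invariant; only the residue-level noise
varies with the seed.

Background residues are drawn from a hydrophilic-biased frequency
profile; near the active site H, C, F and D are excluded so planted
motifs and diagnostics stay unique.  α- and γ-subclass templates share
their copper-binding region background (γ is then diverged at a fixed
rate), while β templates draw an independent background — reproducing
the observed pattern that the cytosolic β form is the most divergent of
the three subclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Optional

import numpy as np
import pandas as pd

from .architecture_scan import build_architecture
from .classify import SUBCLASSES, assign_subclass
from .errors import DataError
from .motif_engine import best_binuclear_site
from .seqio import AMINO_ACIDS, GeneLocus, ProteinRecord
from .trees import Node, Tree

# ---------------------------------------------------------------------------
# background residue profiles

#: General background: hydrophilic-biased so hydrophobic stretches never
#: arise by chance; a little His so spurious-triad handling is exercised.
_BG = {
    "A": 0.080, "G": 0.080, "S": 0.100, "T": 0.080, "N": 0.060,
    "Q": 0.060, "E": 0.100, "K": 0.090, "R": 0.070, "P": 0.060,
    "D": 0.060, "Y": 0.040, "W": 0.010, "M": 0.010, "L": 0.030,
    "V": 0.020, "I": 0.010, "F": 0.020, "C": 0.005, "H": 0.020,
}
#: Near the active site: no H (spurious triads), no C/F/D (spurious
#: cysteine features and diagnostics).
_SAFE = {k: v for k, v in _BG.items() if k not in "HCFD"}
#: Strictly polar letters for the β N-terminal cap (no signal peptide can
#: emerge under any mutation because the cap is protected).
_POLAR = {k: _BG[k] for k in "DEKRNQSTGP"}


def _draw(rng: np.random.Generator, profile: dict, n: int) -> str:
    letters = sorted(profile)
    probs = np.array([profile[k] for k in letters])
    probs = probs / probs.sum()
    return "".join(rng.choice(letters, size=n, p=probs))


# ---------------------------------------------------------------------------
# feature profiles (active-site structural differences per lineage)


@dataclass(frozen=True)
class FeatureProfile:
    """Planted active-site features: placeholder residue, Cys-His bond,
    disulfide bridge count, and the functional label they encode."""

    placeholder: str
    cys_his_bond: bool
    disulfide_bridges: int
    label: str


#: Default feature profile per (lineage, subclass); molluscan/urochordate
#: hemocyanin entries override the lineage default per species.
DEFAULT_PROFILES: dict[tuple[str, str], FeatureProfile] = {
    ("eubacteria", "alpha"): FeatureProfile("V", False, 0, "tyrosinase"),
    ("archaebacteria", "alpha"): FeatureProfile("V", False, 0, "tyrosinase"),
    ("plantae", "alpha"): FeatureProfile("F", True, 2, "catechol_oxidase"),
    ("chromalveolata", "alpha"): FeatureProfile("V", False, 0, "tyrosinase"),
    ("amoebozoa", "alpha"): FeatureProfile("V", False, 0, "tyrosinase"),
    ("fungi", "alpha"): FeatureProfile("V", True, 0, "tyrosinase"),
    ("cnidaria", "alpha"): FeatureProfile("V", False, 0, "tyrosinase"),
    ("mollusca", "alpha"): FeatureProfile("V", False, 0, "tyrosinase"),
    ("nematoda", "alpha"): FeatureProfile("I", False, 0, "tyrosinase"),
    ("urochordata", "alpha"): FeatureProfile("L", True, 2, "hemocyanin"),
    ("amoebozoa", "beta"): FeatureProfile("F", False, 0, "tyrosinase"),
    ("fungi", "beta"): FeatureProfile("F", False, 0, "tyrosinase"),
    ("porifera", "beta"): FeatureProfile("F", False, 1, "tyrosinase"),
    ("arthropoda", "beta"): FeatureProfile("F", False, 2, "tyrosinase"),
    ("hemichordata", "beta"): FeatureProfile("F", False, 0, "hemocyanin"),
    ("urochordata", "beta"): FeatureProfile("F", False, 0, "tyrosinase"),
    ("porifera", "gamma"): FeatureProfile("V", False, 0, "tyrosinase"),
    ("platyhelminthes", "gamma"): FeatureProfile("V", False, 0,
                                                 "tyrosinase"),
    ("annelida", "gamma"): FeatureProfile("V", False, 0, "tyrosinase"),
    ("hemichordata", "gamma"): FeatureProfile("V", False, 0, "tyrosinase"),
    ("cephalochordata", "gamma"): FeatureProfile("V", False, 0,
                                                 "tyrosinase"),
    ("urochordata", "gamma"): FeatureProfile("V", False, 0, "tyrosinase"),
    ("vertebrata", "gamma"): FeatureProfile("V", False, 0, "tyrosinase"),
}

MOLLUSC_HEMOCYANIN = FeatureProfile("L", True, 2, "hemocyanin")


# ---------------------------------------------------------------------------
# template specification and construction


@dataclass(frozen=True)
class TemplateSpec:
    """Blueprint for one subclass template.

    Spacings follow the motif grammar (residues strictly between
    histidines).  ``divergence`` mutates the unprotected copper-binding
    region once at template-construction time (used to separate γ from
    its α-like background).
    """

    subclass: str
    profile: FeatureProfile
    cuA_s12: int = 16
    cuA_s23: int = 8              # β templates use the shifted value
    linker: int = 40
    cuB_s12: int = 3
    cuB_s23: int = 18
    divergence: float = 0.0

    def __post_init__(self):
        if self.subclass not in SUBCLASSES:
            raise DataError(f"unknown subclass {self.subclass!r}")
        if self.subclass == "beta" and self.cuA_s23 == 8:
            object.__setattr__(self, "cuA_s23", 10)
        if self.subclass != "beta" and self.cuA_s23 != 8:
            raise DataError("shifted Cu(A) H2 is a beta-subclass feature")


#: SP construct: Met + Arg, a Ser-rich n-region, a 20-residue Ile core at
#: offset 12, then Ala shoulders.  The core is found by the SP detector
#: (first qualifying window starts at 8), shows up as a TM-length
#: hydrophobic run when SP exclusion is off, and the post-exclusion
#: leftover stays below the TM run-length threshold.
_SP_BLOCK = "MR" + "S" * 10 + "I" * 20 + "A" * 4          # positions 0..35
_TM_BLOCK = "A" * 5 + "IL" * 11 + "I" + "A" * 4           # 23-residue core
_TM_TAIL = "KKRRKKRR"


@dataclass(frozen=True)
class Template:
    """A realized template: sequence plus planted truth."""

    record: ProteinRecord
    subclass: str
    profile: FeatureProfile
    his_positions: tuple[int, ...]            # the six His, N->C
    protected: frozenset[int]


def make_template(spec: TemplateSpec, seed: int = 0,
                  record_id: str = "template") -> Template:
    """Deterministically realize a template from its blueprint.

    The same ``seed`` gives α and γ identical backgrounds in the shared
    copper-binding region (γ is then diverged by ``spec.divergence``);
    β backgrounds are drawn from an independent stream.
    """
    group = "b" if spec.subclass == "beta" else "ag"

    def rng_for(tag: int) -> np.random.Generator:
        return np.random.default_rng(
            [seed, tag, 0 if group == "ag" else 1])

    seq: list[str] = []
    protected: set[int] = set()

    def put(text: str, protect: bool = False):
        start = len(seq)
        seq.extend(text)
        if protect:
            protected.update(range(start, start + len(text)))

    # N-terminal block (0..35)
    if spec.subclass == "beta":
        put("M" + _draw(rng_for(1), _POLAR, 35), protect=True)
    else:
        put(_SP_BLOCK, protect=True)

    put(_draw(rng_for(2), _SAFE, 13))                   # pre-Cu(A)

    h = {}
    h["a1"] = len(seq); put("H", protect=True)
    a12 = list(_draw(rng_for(3), _SAFE, spec.cuA_s12))
    put("".join(a12))
    h["a2"] = len(seq); put("H", protect=True)
    a23 = list(_draw(rng_for(4), _SAFE, spec.cuA_s23))
    put("".join(a23))
    h["a3"] = len(seq); put("H", protect=True)
    linker = list(_draw(rng_for(5), _SAFE, spec.linker))
    put("".join(linker))
    h["b1"] = len(seq); put("H", protect=True)
    b12 = list(_draw(rng_for(6), _SAFE, spec.cuB_s12))
    put("".join(b12))
    h["b2"] = len(seq); put("H", protect=True)
    b23 = list(_draw(rng_for(7), _SAFE, spec.cuB_s23))
    put("".join(b23))
    h["b3"] = len(seq); put("H", protect=True)

    # post-Cu(B): safe region up to +25, then general background
    put(_draw(rng_for(8), _SAFE, 25))
    if spec.subclass == "gamma":
        put(_draw(rng_for(9), _BG, 25))
        cys_rich = list(_draw(rng_for(10), _SAFE, 30))
        for k in range(0, 30, 4):                       # 8 planted Cys
            if k // 4 < 8:
                cys_rich[k] = "C"
        start = len(seq)
        put("".join(cys_rich))
        protected.update(start + k for k in range(0, 30, 4))
        put(_TM_BLOCK, protect=True)
        put(_TM_TAIL, protect=True)
        put(_draw(rng_for(11), _BG, 6))
    else:
        put(_draw(rng_for(9), _BG, 35))

    # plant diagnostics and profile features (all protected)
    def plant(pos: int, residue: str):
        seq[pos] = residue
        protected.add(pos)

    plant(h["a3"] - 4, "F")
    plant(h["b3"] - 4, "F")
    plant(h["b3"] + 4, "D")
    plant(h["b1"] - 6, spec.profile.placeholder)
    if spec.profile.cys_his_bond:
        plant(h["a2"] - 1, "C")
    for k in range(spec.profile.disulfide_bridges * 2):
        plant(h["a3"] + 17 + 5 * k, "C")

    # template-level divergence (γ), never touching planted features
    sequence = "".join(seq)
    if spec.divergence > 0:
        rec = ProteinRecord(id="tmp", sequence=sequence)
        rec = mutate(rec, spec.divergence, protected,
                     seed=_child_seed(seed, 999))
        sequence = rec.sequence

    record = ProteinRecord(id=record_id, sequence=sequence)
    return Template(record=record, subclass=spec.subclass,
                    profile=spec.profile,
                    his_positions=(h["a1"], h["a2"], h["a3"],
                                   h["b1"], h["b2"], h["b3"]),
                    protected=frozenset(protected))


def _child_seed(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0]
               % (2 ** 31))


def mutate(record: ProteinRecord, rate: float, protected,
           seed: int = 0) -> ProteinRecord:
    """Substitution noise: each unprotected site mutates with probability
    ``rate`` to a uniformly chosen *different* residue.

    Draws are coupled across rates (a per-site uniform is compared to the
    rate), so the mutated position sets are nested as the rate grows.
    """
    if not 0 <= rate < 1:
        raise DataError("mutation rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = len(record.sequence)
    u = rng.random(n)
    picks = rng.integers(0, 19, size=n)
    protected = set(protected)
    out = list(record.sequence)
    for i in range(n):
        if u[i] < rate and i not in protected:
            others = AMINO_ACIDS.replace(out[i], "")
            out[i] = others[picks[i] % len(others)]
    return dc_replace(record, sequence="".join(out))


# ---------------------------------------------------------------------------
# template registry with construction-time validation

_TEMPLATE_SEED = 1729
_template_cache: dict[tuple, Template] = {}


def subclass_template(subclass: str, profile: FeatureProfile,
                      seed: int = _TEMPLATE_SEED) -> Template:
    """Validated template for a subclass/profile pair (cached).

    Construction is verified end-to-end (motif -> architecture ->
    subclass -> functional compatibility); a failing background draw is
    deterministically redrawn.
    """
    key = (subclass, profile, seed)
    if key in _template_cache:
        return _template_cache[key]
    spec = TemplateSpec(subclass=subclass, profile=profile,
                        divergence=0.20 if subclass == "gamma" else 0.0)
    for attempt in range(25):
        template = make_template(spec, seed=seed + 1000 * attempt)
        if _template_ok(template):
            template = _guard_his_mimics(template)
            _template_cache[key] = template
            return template
    raise DataError(
        f"could not realize a valid {subclass} template")  # pragma: no cover


def _guard_his_mimics(template: Template) -> Template:
    """Extend the protected set to positions where a single His
    substitution would displace the planted site.

    The scanner breaks score ties towards the leftmost site, so a mutated
    His that completes an earlier triad (often reusing planted histidines
    and their planted diagnostics) could outrank the planted site; the
    planted-site-recovery guarantee requires such positions to stay
    protected from noise.
    """
    seq = template.record.sequence
    guarded = set(template.protected)
    for i in range(len(seq)):
        if i in guarded or seq[i] == "H":
            continue
        probe = ProteinRecord(id="probe",
                              sequence=seq[:i] + "H" + seq[i + 1:])
        site = best_binuclear_site(probe)
        found = None if site is None else (
            site.cuA.h1, site.cuA.h2, site.cuA.h3,
            site.cuB.h1, site.cuB.h2, site.cuB.h3)
        if found != template.his_positions:
            guarded.add(i)
    return dc_replace(template, protected=frozenset(guarded))


def _template_ok(template: Template) -> bool:
    rec = template.record
    site = best_binuclear_site(rec)
    if site is None:
        return False
    found = (site.cuA.h1, site.cuA.h2, site.cuA.h3,
             site.cuB.h1, site.cuB.h2, site.cuB.h3)
    if found != template.his_positions:
        return False
    arch = build_architecture(rec)
    call = assign_subclass(arch, site)
    if call.subclass != template.subclass:
        return False
    prof = template.profile
    if (site.placeholder_residue != prof.placeholder
            or site.cys_his_bond_candidate != prof.cys_his_bond
            or site.disulfide_candidate_count != prof.disulfide_bridges):
        return False
    return True


# ---------------------------------------------------------------------------
# census specification


@dataclass(frozen=True)
class SpeciesEntry:
    name: str
    abbrev: str
    lineage: str
    metazoan: bool
    counts: dict = field(default_factory=dict)      # subclass -> n genes
    profiles: dict = field(default_factory=dict)    # subclass -> override


@dataclass(frozen=True)
class CensusSpec:
    species: tuple[SpeciesEntry, ...]

    @property
    def total_proteins(self) -> int:
        return sum(sum(e.counts.values()) for e in self.species)

    def profile_for(self, entry: SpeciesEntry,
                    subclass: str) -> FeatureProfile:
        if subclass in entry.profiles:
            return entry.profiles[subclass]
        key = (entry.lineage, subclass)
        if key not in DEFAULT_PROFILES:
            raise DataError(
                f"no feature profile for {entry.lineage}/{subclass}")
        return DEFAULT_PROFILES[key]


def _sp(name, abbrev, lineage, metazoan, **counts) -> SpeciesEntry:
    profiles = counts.pop("profiles", {})
    return SpeciesEntry(name=name, abbrev=abbrev, lineage=lineage,
                        metazoan=metazoan, counts=counts,
                        profiles=profiles)


def default_census_spec() -> CensusSpec:
    """The packaged census: 179 proteins, 35 metazoan + 17 non-metazoan
    species, the named expansions, one all-three species, four species
    with no type-3 copper proteins.  Species counts not fixed by the
    survey aggregates are synthetic fillers (1-3 genes)."""
    hemo = {"alpha": MOLLUSC_HEMOCYANIN}
    species = (
        # non-metazoan (17)
        _sp("Bacillus megaterium", "Bme", "eubacteria", False, alpha=2),
        _sp("Streptomyces griseus", "Sgr", "eubacteria", False, alpha=1),
        _sp("Halobacterium salinarum", "Hsl", "archaebacteria", False,
            alpha=1),
        _sp("Sulfolobus solfataricus", "Sso", "archaebacteria", False,
            alpha=1),
        _sp("Glycine max", "Gma", "plantae", False, alpha=12),
        _sp("Oryza sativa", "Osa", "plantae", False, alpha=3),
        _sp("Ipomoea batatas", "Iba", "plantae", False, alpha=2),
        _sp("Arabidopsis thaliana", "Ath", "plantae", False, alpha=2),
        _sp("Ectocarpus siliculosus", "Esi", "chromalveolata", False,
            alpha=18),
        _sp("Dictyostelium discoideum", "Ddi", "amoebozoa", False,
            alpha=1, beta=1),
        _sp("Polysphondylium pallidum", "Ppa", "amoebozoa", False, beta=2),
        _sp("Aspergillus aculeatus", "Aac", "fungi", False,
            alpha=1, beta=1),
        _sp("Neurospora tetrasperma", "Nte", "fungi", False, beta=2),
        _sp("Agaricus bisporus", "Abi", "fungi", False, alpha=2),
        _sp("Coprinopsis cinerea", "Cci", "fungi", False, beta=1),
        _sp("Monosiga brevicollis", "Mbr", "choanoflagellata", False),
        _sp("Capsaspora owczarzaki", "Cow", "filasterea", False),
        # metazoan (35)
        _sp("Amphimedon queenslandica", "Aqu", "porifera", True,
            beta=1, gamma=2),
        _sp("Oscarella carmela", "Oca", "porifera", True, beta=2, gamma=1),
        _sp("Trichoplax adhaerens", "Tad", "placozoa", True),
        _sp("Nematostella vectensis", "Nve", "cnidaria", True, alpha=3),
        _sp("Hydra magnipapillata", "Hma", "cnidaria", True, alpha=3),
        _sp("Acropora digitifera", "Adi", "cnidaria", True, alpha=3),
        _sp("Lottia gigantea", "Lgi", "mollusca", True, alpha=3),
        _sp("Crassostrea gigas", "Cgi", "mollusca", True, alpha=3),
        _sp("Megathura crenulata", "Mcr", "mollusca", True, alpha=3,
            profiles=hemo),
        _sp("Octopus dofleini", "Odo", "mollusca", True, alpha=3,
            profiles=hemo),
        _sp("Capitella teleta", "Cte", "annelida", True, gamma=3),
        _sp("Helobdella robusta", "Hro", "annelida", True, gamma=3),
        _sp("Schistosoma mansoni", "Sma", "platyhelminthes", True, gamma=3),
        _sp("Schmidtea mediterranea", "Sme", "platyhelminthes", True,
            gamma=2),
        _sp("Caenorhabditis elegans", "Cel", "nematoda", True, alpha=5),
        _sp("Caenorhabditis briggsae", "Cbr", "nematoda", True, alpha=6),
        _sp("Caenorhabditis remanei", "Cre", "nematoda", True, alpha=5),
        _sp("Brugia malayi", "Bma", "nematoda", True, alpha=4),
        _sp("Pristionchus pacificus", "Ppc", "nematoda", True, alpha=3),
        _sp("Anopheles gambiae", "Aga", "arthropoda", True, beta=9),
        _sp("Drosophila melanogaster", "Dme", "arthropoda", True, beta=3),
        _sp("Tribolium castaneum", "Tca", "arthropoda", True, beta=3),
        _sp("Daphnia pulex", "Dpu", "arthropoda", True, beta=3),
        _sp("Apis mellifera", "Ame", "arthropoda", True, beta=3),
        _sp("Ixodes scapularis", "Isc", "arthropoda", True, beta=3),
        _sp("Limulus polyphemus", "Lpo", "arthropoda", True, beta=3),
        _sp("Strongylocentrotus purpuratus", "Spu", "echinodermata", True),
        _sp("Saccoglossus kowalevskii", "Sko", "hemichordata", True,
            beta=1, gamma=2),
        _sp("Branchiostoma floridae", "Bfl", "cephalochordata", True,
            gamma=18),
        _sp("Ciona intestinalis", "Cin", "urochordata", True,
            alpha=1, beta=1, gamma=1),
        _sp("Ciona savignyi", "Csa", "urochordata", True, alpha=1, beta=1),
        _sp("Danio rerio", "Dre", "vertebrata", True, gamma=3),
        _sp("Xenopus tropicalis", "Xtr", "vertebrata", True, gamma=3),
        _sp("Gallus gallus", "Gga", "vertebrata", True, gamma=3),
        _sp("Mus musculus", "Mmu", "vertebrata", True, gamma=3),
    )
    return CensusSpec(species=species)


_SUBCLASS_LETTER = {"alpha": "a", "beta": "b", "gamma": "g"}


@dataclass(frozen=True)
class CensusDataset:
    records: tuple[ProteinRecord, ...]
    truth: pd.DataFrame          # planted labels per record id
    spec: CensusSpec


def generate_census(spec: Optional[CensusSpec] = None,
                    noise_rate: float = 0.05,
                    seed: int = 0) -> CensusDataset:
    """Realize the census spec as noised protein records plus truth.

    Record ids are ``<abbrev>_<s><nn>`` (s in a/b/g).  Counts and ids are
    seed-invariant; sequences vary with the seed through the noise.
    """
    spec = spec or default_census_spec()
    records: list[ProteinRecord] = []
    rows: list[dict] = []
    counter = 0
    for entry in spec.species:
        for subclass in SUBCLASSES:
            n = entry.counts.get(subclass, 0)
            if n == 0:
                continue
            profile = spec.profile_for(entry, subclass)
            template = subclass_template(subclass, profile)
            for i in range(1, n + 1):
                rec_id = f"{entry.abbrev}_{_SUBCLASS_LETTER[subclass]}{i:02d}"
                counter += 1
                noised = mutate(template.record, noise_rate,
                                template.protected,
                                seed=_child_seed(seed, counter))
                records.append(dc_replace(noised, id=rec_id,
                                          species=entry.name,
                                          lineage=entry.lineage))
                rows.append({
                    "id": rec_id, "species": entry.name,
                    "lineage": entry.lineage, "metazoan": entry.metazoan,
                    "subclass": subclass,
                    "placeholder": profile.placeholder,
                    "cys_his_bond": profile.cys_his_bond,
                    "disulfide_bridges": profile.disulfide_bridges,
                    "label": profile.label,
                })
        if not entry.counts:
            rows.append({
                "id": "", "species": entry.name, "lineage": entry.lineage,
                "metazoan": entry.metazoan, "subclass": "",
                "placeholder": "", "cys_his_bond": "",
                "disulfide_bridges": "", "label": "",
            })
    truth = pd.DataFrame(rows)
    return CensusDataset(records=tuple(records), truth=truth, spec=spec)


# ---------------------------------------------------------------------------
# coordinate fixture


@dataclass(frozen=True)
class ClusterPlanEntry:
    scaffold: str
    protein_ids: tuple[str, ...]
    gap: int                    # intergenic distance within the scaffold
    gene_length: int = 1000


def default_cluster_plan() -> list[ClusterPlanEntry]:
    """Linked-gene layout over the census ids: cluster sizes 2-7 for the
    expanded species (plus singletons and one adjacent α/β pair)."""
    def ids(abbrev, letter, lo, hi):
        return tuple(f"{abbrev}_{letter}{i:02d}" for i in range(lo, hi + 1))

    plan = [
        ClusterPlanEntry("Bfl_sc1", ids("Bfl", "g", 1, 7), 10_000),
        ClusterPlanEntry("Bfl_sc2", ids("Bfl", "g", 8, 11), 15_000),
        ClusterPlanEntry("Bfl_sc3", ids("Bfl", "g", 12, 14), 8_000),
        ClusterPlanEntry("Aga_sc1", ids("Aga", "b", 1, 5), 12_000),
        ClusterPlanEntry("Aga_sc2", ids("Aga", "b", 6, 7), 50_000),
        ClusterPlanEntry("Gma_sc1", ids("Gma", "a", 1, 3), 20_000),
        ClusterPlanEntry("Gma_sc2", ids("Gma", "a", 4, 5), 30_000),
        ClusterPlanEntry("Esi_sc1", ids("Esi", "a", 1, 6), 10_000),
        ClusterPlanEntry("Esi_sc2", ids("Esi", "a", 7, 8), 25_000),
        # adjacent α and β genes: not a cluster under same-subclass rule
        ClusterPlanEntry("Cin_sc1", ("Cin_a01", "Cin_b01"), 1_000),
    ]
    singles = (list(f"Bfl_g{i:02d}" for i in range(15, 19))
               + ["Aga_b08", "Aga_b09"]
               + list(f"Gma_a{i:02d}" for i in range(6, 13))
               + list(f"Esi_a{i:02d}" for i in range(9, 19)))
    for k, pid in enumerate(singles, start=1):
        plan.append(ClusterPlanEntry(f"single_sc{k}", (pid,), 10_000))
    return plan


def generate_coords(plan: Optional[list[ClusterPlanEntry]] = None,
                    seed: int = 0) -> list[GeneLocus]:
    """Lay out the cluster plan as gene loci (0-based half-open)."""
    plan = plan if plan is not None else default_cluster_plan()
    rng = np.random.default_rng(seed)
    loci: list[GeneLocus] = []
    for entry in plan:
        if entry.gap <= 0:
            raise DataError(
                f"scaffold {entry.scaffold}: gap must be positive "
                "(overlapping loci)")
        pos = int(rng.integers(1_000, 5_000))
        for k, pid in enumerate(entry.protein_ids):
            strand = "+" if k % 2 == 0 else "-"
            loci.append(GeneLocus(protein_id=pid, scaffold=entry.scaffold,
                                  start=pos, end=pos + entry.gene_length,
                                  strand=strand))
            pos += entry.gene_length + entry.gap
    return loci


# ---------------------------------------------------------------------------
# species tree

#: parent relation among named clades (child -> parent)
_CLADE_PARENT = {
    "eubacteria": "root", "archaebacteria": "root", "eukaryota": "root",
    "bikonta": "eukaryota", "plantae": "bikonta",
    "chromalveolata": "bikonta",
    "unikonta": "eukaryota", "amoebozoa": "unikonta",
    "opisthokonta": "unikonta", "fungi": "opisthokonta",
    "holozoa": "opisthokonta", "metazoa": "holozoa",
    "porifera": "metazoa", "placozoa": "metazoa", "eumetazoa": "metazoa",
    "cnidaria": "eumetazoa", "bilateria": "eumetazoa",
    "protostomia": "bilateria", "mollusca": "protostomia",
    "annelida": "protostomia", "platyhelminthes": "protostomia",
    "nematoda": "protostomia", "arthropoda": "protostomia",
    "deuterostomia": "bilateria", "echinodermata": "deuterostomia",
    "hemichordata": "deuterostomia", "chordata": "deuterostomia",
    "cephalochordata": "chordata", "olfactores": "chordata",
    "urochordata": "olfactores", "vertebrata": "olfactores",
}

#: lineage tags whose species hang directly off a non-lineage clade
_LINEAGE_ATTACH = {"choanoflagellata": "holozoa", "filasterea": "holozoa"}


def generate_species_tree(spec: Optional[CensusSpec] = None
                          ) -> tuple[Tree, "pd.DataFrame"]:
    """The packaged species tree (named internal clades, polytomies
    allowed, unit branch lengths) and the presence matrix the census
    spec implies."""
    spec = spec or default_census_spec()
    nodes = {"root": Node(name="root")}
    for child, parent in _CLADE_PARENT.items():
        nodes[child] = Node(name=child, length=1.0)
    for child, parent in _CLADE_PARENT.items():
        nodes[parent].add(nodes[child])

    for entry in spec.species:
        attach = entry.lineage
        if attach in _LINEAGE_ATTACH:
            attach = _LINEAGE_ATTACH[attach]
        if attach not in nodes:
            raise DataError(f"no clade for lineage {entry.lineage!r}")
        nodes[attach].add(Node(name=entry.name, length=1.0))

    tree = Tree(nodes["root"], rooted=True)
    presence = pd.DataFrame(
        [[entry.counts.get(s, 0) > 0 for s in SUBCLASSES]
         for entry in spec.species],
        index=[e.name for e in spec.species], columns=list(SUBCLASSES))
    return tree, presence


# ---------------------------------------------------------------------------
# phylogenetics fixture


def make_phylo_dataset(n_per_class: int = 6, noise: float = 0.02,
                       seed: int = 0
                       ) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Records from the three subclass templates with light noise, for
    tree inference: within-subclass variation ~ noise, α/γ moderately
    diverged, β strongly diverged (the most divergent subclass)."""
    profiles = {
        "alpha": DEFAULT_PROFILES[("cnidaria", "alpha")],
        "beta": DEFAULT_PROFILES[("urochordata", "beta")],
        "gamma": DEFAULT_PROFILES[("vertebrata", "gamma")],
    }
    records, labels = [], {}
    counter = 0
    for subclass in SUBCLASSES:
        template = subclass_template(subclass, profiles[subclass])
        for i in range(1, n_per_class + 1):
            counter += 1
            rec_id = f"{subclass}{i:02d}"
            rec = mutate(template.record, noise, template.protected,
                         seed=_child_seed(seed, 10_000 + counter))
            records.append(dc_replace(rec, id=rec_id))
            labels[rec_id] = subclass
    return records, labels
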
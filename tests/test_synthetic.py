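import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import type3copper as t3
from type3copper.classify import SUBCLASSES
from type3copper.errors import DataError
from type3copper.synthetic import (DEFAULT_PROFILES, TemplateSpec,
                                   default_census_spec, make_template)


def test_templates_classify_to_their_planted_subclass(templates):
    for sub, tpl in templates.items():
        cr = t3.classify_record(tpl.record)
        assert cr.call.subclass == sub


def test_beta_template_shows_shifted_h2(templates):
    site = t3.best_binuclear_site(templates["beta"].record)
    assert site.shifted_h2 is True
    assert site.cuA.spacing23 == 10


def test_make_template_is_deterministic():
    spec = TemplateSpec("alpha", DEFAULT_PROFILES[("cnidaria", "alpha")])
    a = make_template(spec, seed=12)
    b = make_template(spec, seed=12)
    c = make_template(spec, seed=13)
    assert a.record.sequence == b.record.sequence
    assert a.record.sequence != c.record.sequence


def test_inconsistent_spec_rejected():
    with pytest.raises(DataError):
        TemplateSpec("alpha", DEFAULT_PROFILES[("cnidaria", "alpha")],
                     cuA_s23=10)   # shifted H2 is a beta feature


def test_every_packaged_profile_round_trips():
    """Constructive inverse over every (lineage, subclass) profile: the
    template is recovered end-to-end with zero errors at noise 0."""
    for (lineage, subclass), profile in DEFAULT_PROFILES.items():
        tpl = t3.subclass_template(subclass, profile)
        cr = t3.classify_record(tpl.record)
        assert cr.call.subclass == subclass, (lineage, subclass)
        assert cr.site.placeholder_residue == profile.placeholder
        assert cr.site.cys_his_bond_candidate == profile.cys_his_bond
        assert cr.site.disulfide_candidate_count == \
            profile.disulfide_bridges


# -- mutate ----------------------------------------------------------------


def test_mutate_rate_zero_is_identity(templates):
    rec = templates["alpha"].record
    assert t3.mutate(rec, 0.0, set(), seed=1).sequence == rec.sequence


def test_mutate_rate_near_one_changes_every_unprotected_site():
    rec = t3.ProteinRecord("r", "A" * 10)
    out = t3.mutate(rec, 0.999999, set(), seed=1)
    assert all(ch != "A" for ch in out.sequence)


def test_mutate_respects_protected_positions():
    rec = t3.ProteinRecord("r", "A" * 50)
    protected = set(range(0, 50, 2))
    out = t3.mutate(rec, 0.999999, protected, seed=1)
    assert all(out.sequence[i] == "A" for i in protected)
    assert all(out.sequence[i] != "A" for i in range(1, 50, 2))


def test_mutate_fraction_matches_rate_within_three_se():
    n, rate = 1000, 0.1
    rec = t3.ProteinRecord("r", "A" * n)
    out = t3.mutate(rec, rate, set(), seed=7)
    changed = sum(a != b for a, b in zip(rec.sequence, out.sequence))
    se = (rate * (1 - rate) * n) ** 0.5
    assert abs(changed - rate * n) <= 3 * se


@settings(derandomize=True, max_examples=30)
@given(st.integers(0, 2 ** 20),
       st.floats(0.0, 0.45), st.floats(0.0, 0.45))
def test_mutation_sets_are_nested_across_rates(seed, r1, r2):
    low, high = sorted((r1, r2))
    rec = t3.ProteinRecord("r", "A" * 200)
    lo = t3.mutate(rec, low, set(), seed=seed).sequence
    hi = t3.mutate(rec, high, set(), seed=seed).sequence
    for i in range(200):
        if lo[i] != "A":
            assert hi[i] == lo[i]


# -- census spec -----------------------------------------------------------


def test_census_spec_aggregates():
    spec = default_census_spec()
    assert spec.total_proteins == 179
    assert sum(e.metazoan for e in spec.species) == 35
    assert sum(not e.metazoan for e in spec.species) == 17
    all_three = [e.name for e in spec.species
                 if all(e.counts.get(s, 0) > 0 for s in SUBCLASSES)]
    assert all_three == ["Ciona intestinalis"]
    empty = [e.name for e in spec.species if not e.counts]
    assert len(empty) == 4


def test_census_counts_are_seed_invariant():
    a = t3.generate_census(seed=1)
    b = t3.generate_census(seed=2)
    assert [r.id for r in a.records] == [r.id for r in b.records]
    assert any(x.sequence != y.sequence
               for x, y in zip(a.records, b.records))


def test_census_record_count(census_dataset):
    assert len(census_dataset.records) == 179


# -- coordinates fixture ---------------------------------------------------


def test_default_plan_detects_max_cluster_of_seven(census_results):
    loci = t3.generate_coords(seed=0)
    calls = {cr.record.id: cr.call.subclass for cr in census_results}
    clusters = t3.find_clusters(loci, calls)
    assert max(c.size for c in clusters) == 7


def test_singleton_plan_yields_no_clusters():
    from type3copper.synthetic import ClusterPlanEntry
    plan = [ClusterPlanEntry(f"s{i}", (f"g{i}",), 10_000)
            for i in range(5)]
    loci = t3.generate_coords(plan, seed=0)
    assert t3.find_clusters(loci, {f"g{i}": "alpha" for i in range(5)}) \
        == []


def test_nonpositive_gap_rejected():
    from type3copper.synthetic import ClusterPlanEntry
    with pytest.raises(DataError):
        t3.generate_coords([ClusterPlanEntry("s", ("a", "b"), 0)], seed=0)


# -- species tree ----------------------------------------------------------


def test_species_tree_covers_all_census_species():
    spec = default_census_spec()
    tree, presence = t3.generate_species_tree(spec)
    assert sorted(tree.tip_names()) == sorted(e.name for e in spec.species)


def test_gamma_restricted_to_metazoa():
    spec = default_census_spec()
    tree, presence = t3.generate_species_tree(spec)
    metazoa = tree.tipset_below()[id(tree.find("metazoa"))]
    gamma_species = set(presence.index[presence["gamma"]])
    assert gamma_species <= metazoa
    beta_species = set(presence.index[presence["beta"]])
    assert beta_species <= tree.tipset_below()[id(tree.find("unikonta"))]


def test_non_unikonts_carry_only_alpha():
    spec = default_census_spec()
    tree, presence = t3.generate_species_tree(spec)
    unikonta = tree.tipset_below()[id(tree.find("unikonta"))]
    outside = set(presence.index) - unikonta
    for species in outside:
        assert not presence.loc[species, "beta"]
        assert not presence.loc[species, "gamma"]


def test_all_absent_species_are_tree_tips():
    spec = default_census_spec()
    tree, presence = t3.generate_species_tree(spec)
    tips = set(tree.tip_names())
    for e in spec.species:
        if not e.counts:
            assert e.name in tips
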
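import numpy as np
import pytest

import type3copper as t3
from type3copper.motif_engine import PlaceholderConvention, ScanParams
from type3copper.synthetic import DEFAULT_PROFILES, MOLLUSC_HEMOCYANIN

from oracles import brute_force_pairs, brute_force_triads

PARAMS = ScanParams()


def rec(seq, rid="r"):
    return t3.ProteinRecord(rid, seq)


# -- triad scanning --------------------------------------------------------


def test_canonical_cuA_triad():
    sites = t3.scan_his_triads(rec("MHAAAAHAAAAAAAAH"), "A", PARAMS)
    assert len(sites) == 1
    site = sites[0]
    assert (site.h1, site.h2, site.h3) == (1, 6, 15)
    assert (site.spacing12, site.spacing23) == (4, 8)


def test_canonical_cuB_triad():
    sites = t3.scan_his_triads(rec("MHAAAHAAAAAH"), "B", PARAMS)
    assert len(sites) == 1
    assert (sites[0].spacing12, sites[0].spacing23) == (3, 5)


@pytest.mark.parametrize("kind", ["A", "B"])
def test_his_free_sequence_yields_nothing(kind):
    assert t3.scan_his_triads(rec("A" * 60), kind, PARAMS) == []


@pytest.mark.parametrize("kind", ["A", "B"])
def test_scan_matches_brute_force_enumeration(kind):
    """Exhaustiveness: scanner == brute force over all His triples on 200
    random sequences (H-enriched so triads actually occur)."""
    rng = np.random.default_rng(42)
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWYH"))  # H twice: ~10%
    for _ in range(200):
        n = int(rng.integers(10, 500))
        seq = "".join(rng.choice(letters, size=n))
        got = [(s.h1, s.h2, s.h3)
               for s in t3.scan_his_triads(rec(seq), kind, PARAMS)]
        assert sorted(got) == brute_force_triads(seq, kind, PARAMS)


# -- pairing ---------------------------------------------------------------


def _planted(posA, posB, length=500):
    seq = ["A"] * length
    for p in posA + posB:
        seq[p] = "H"
    return "".join(seq)


def test_pair_gap_above_range_excluded():
    seq = _planted([1, 6, 15], [420, 424, 430])
    r = rec(seq)
    pairs = t3.pair_sites(r, t3.scan_his_triads(r, "A", PARAMS),
                          t3.scan_his_triads(r, "B", PARAMS), PARAMS)
    assert [p for p in pairs if p.cuA.h1 == 1 and p.cuB.h1 == 420] == []


def test_pair_gap_within_range_kept():
    seq = _planted([1, 6, 15], [50, 54, 60])
    r = rec(seq)
    pairs = t3.pair_sites(r, t3.scan_his_triads(r, "A", PARAMS),
                          t3.scan_his_triads(r, "B", PARAMS), PARAMS)
    matching = [p for p in pairs if p.cuA.h1 == 1 and p.cuB.h1 == 50]
    assert len(matching) == 1
    assert matching[0].intersite_gap == 34


def test_pairing_matches_brute_force_on_random_sequences():
    rng = np.random.default_rng(7)
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWYHH"))
    for _ in range(50):
        seq = "".join(rng.choice(letters, size=int(rng.integers(30, 400))))
        r = rec(seq)
        A = t3.scan_his_triads(r, "A", PARAMS)
        B = t3.scan_his_triads(r, "B", PARAMS)
        got = {((p.cuA.h1, p.cuA.h2, p.cuA.h3),
                (p.cuB.h1, p.cuB.h2, p.cuB.h3))
               for p in t3.pair_sites(r, A, B, PARAMS)}
        expected = {(a, b) for a, b in brute_force_pairs(
            [(s.h1, s.h2, s.h3) for s in A],
            [(s.h1, s.h2, s.h3) for s in B], PARAMS)}
        assert got == expected


# -- diagnostics -----------------------------------------------------------


def test_template_diagnostics_all_true(templates):
    for sub, tpl in templates.items():
        site = t3.best_binuclear_site(tpl.record)
        assert site.phe_A_ok and site.phe_B_ok and site.asp_B_ok, sub


def test_single_diagnostic_mutation_flips_one_flag(templates):
    tpl = templates["alpha"]
    seq = list(tpl.record.sequence)
    h3A = tpl.his_positions[2]
    seq[h3A - 4] = "A"
    site = t3.best_binuclear_site(t3.ProteinRecord("m", "".join(seq)))
    assert not site.phe_A_ok
    assert site.phe_B_ok and site.asp_B_ok


def test_out_of_bounds_probe_is_false_not_an_error():
    # Cu(B) H3 at the last residue: Asp probe runs off the end
    seq = _planted([1, 6, 15], [50, 54, 73], length=74)
    site = t3.best_binuclear_site(rec(seq))
    assert site is not None
    assert site.asp_B_ok is False


# -- placeholder -----------------------------------------------------------


def test_placeholder_residues_by_subclass(templates):
    expected = {"beta": "F", "gamma": "V"}
    for sub, residue in expected.items():
        site = t3.best_binuclear_site(templates[sub].record)
        assert site.placeholder_residue == residue


def test_placeholder_out_of_bounds_returns_unknown():
    seq = _planted([1, 6, 15], [30, 34, 40], length=60)
    r = rec(seq)
    site = t3.best_binuclear_site(r)
    residue, pos = t3.extract_placeholder(
        r, site, PlaceholderConvention(anchor="cuA.h1", offset=-10))
    assert residue is None and pos is None


# -- cysteine features -----------------------------------------------------


def test_molluscan_hemocyanin_cys_profile():
    tpl = t3.subclass_template("alpha", MOLLUSC_HEMOCYANIN)
    site = t3.best_binuclear_site(tpl.record)
    assert site.cys_his_bond_candidate is True
    assert site.disulfide_candidate_count == 2


def test_poriferan_beta_cys_profile():
    tpl = t3.subclass_template("beta",
                               DEFAULT_PROFILES[("porifera", "beta")])
    site = t3.best_binuclear_site(tpl.record)
    assert site.cys_his_bond_candidate is False
    assert site.disulfide_candidate_count == 1


def test_cys_free_template(templates):
    site = t3.best_binuclear_site(templates["gamma"].record)
    assert site.cys_his_bond_candidate is False
    assert site.disulfide_candidate_count == 0


# -- best site selection ---------------------------------------------------


def test_each_template_has_exactly_the_planted_site(templates):
    for sub, tpl in templates.items():
        site = t3.best_binuclear_site(tpl.record)
        found = (site.cuA.h1, site.cuA.h2, site.cuA.h3,
                 site.cuB.h1, site.cuB.h2, site.cuB.h3)
        assert found == tpl.his_positions, sub


def test_his_free_sequence_has_no_site():
    assert t3.best_binuclear_site(rec("AGSTK" * 40)) is None


def test_tie_break_prefers_first_site(templates):
    # two copies of the same template: the N-terminal site wins on the
    # position tie-break (scores are equal by construction)
    tpl = templates["alpha"]
    doubled = t3.ProteinRecord("d", tpl.record.sequence * 2)
    site = t3.best_binuclear_site(doubled)
    assert (site.cuA.h1, site.cuB.h3) == (tpl.his_positions[0],
                                          tpl.his_positions[5])


def test_mutating_a_diagnostic_never_increases_score(templates):
    for sub, tpl in templates.items():
        base = t3.best_binuclear_site(tpl.record).score
        h = tpl.his_positions
        for pos in (h[2] - 4, h[5] - 4, h[5] + 4):
            seq = list(tpl.record.sequence)
            seq[pos] = "G"
            mutated = t3.best_binuclear_site(
                t3.ProteinRecord("m", "".join(seq)))
            assert mutated.score <= base


def test_scan_is_deterministic(templates):
    r = templates["beta"].record
    assert t3.best_binuclear_site(r) == t3.best_binuclear_site(r)


def test_planted_site_recovered_under_5pct_noise(templates):
    for sub, tpl in templates.items():
        for k in range(20):
            noised = t3.mutate(tpl.record, 0.05, tpl.protected, seed=k)
            site = t3.best_binuclear_site(noised)
            found = (site.cuA.h1, site.cuA.h2, site.cuA.h3,
                     site.cuB.h1, site.cuB.h2, site.cuB.h3)
            assert found == tpl.his_positions, (sub, k)
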
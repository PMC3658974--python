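import pytest

import type3copper as t3
from type3copper.synthetic import DEFAULT_PROFILES


@pytest.fixture(scope="session")
def templates():
    """One validated template per subclass (fixed lineage profiles)."""
    return {
        "alpha": t3.subclass_template(
            "alpha", DEFAULT_PROFILES[("cnidaria", "alpha")]),
        "beta": t3.subclass_template(
            "beta", DEFAULT_PROFILES[("urochordata", "beta")]),
        "gamma": t3.subclass_template(
            "gamma", DEFAULT_PROFILES[("vertebrata", "gamma")]),
    }


@pytest.fixture(scope="session")
def census_dataset():
    """The packaged census at the survey noise level."""
    return t3.generate_census(noise_rate=0.05, seed=1)


@pytest.fixture(scope="session")
def census_results(census_dataset):
    return t3.classify_records(census_dataset.records)


@pytest.fixture(scope="session")
def census_table(census_dataset, census_results):
    meta = {e.name: e for e in census_dataset.spec.species}
    rows = [{"species": cr.record.species,
             "lineage": cr.record.lineage,
             "metazoan": meta[cr.record.species].metazoan,
             "subclass": cr.call.subclass}
            for cr in census_results]
    rows += [{"species": e.name, "lineage": e.lineage,
              "metazoan": e.metazoan, "subclass": ""}
             for e in census_dataset.spec.species if not e.counts]
    return t3.build_census(rows)


@pytest.fixture(scope="session")
def phylo_fixture():
    """Low-noise three-subclass dataset with sites and anchored alignment."""
    records, labels = t3.make_phylo_dataset(n_per_class=6, noise=0.02,
                                            seed=3)
    sites = {r.id: t3.best_binuclear_site(r) for r in records}
    aln = t3.anchor_align(records, sites)
    return records, labels, sites, aln
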
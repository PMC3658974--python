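# type3copper

Classification and molecular evolution of the **type-3 copper protein
family** — tyrosinases, catechol oxidases and hemocyanins — for
comparative genomicists studying how this ancient family diversified
across the tree of life.

Type-3 copper proteins share a binuclear active site: two coppers,
Cu(A) and Cu(B), each held by three histidines.  In sequence the two
sites follow the motifs

```
Cu(A):  H1 (n) H2 (8) H3          Cu(B):  H1 (3) H2 (n) H3
```

(numbers = residues strictly between histidines, *n* variable), with a
conserved Phe at H3−4 in both sites and Asp at Cu(B) H3+4.  On top of
the shared site, domain architecture splits the family into three
subclasses: **α** (secreted; signal peptide), **β** (cytosolic; no
signal peptide, shifted Cu(A) H2), and **γ** (membrane-bound; signal
peptide + Cys-rich region + transmembrane segment, metazoan-only).  The
residue covering the Cu(A) pocket (the *placeholder*: bulky Phe blocks
monophenol docking, small Val/Ile/Leu permits it), a possible Cys–His
bond and the disulfide-bridge count then index a per-lineage feature
table of compatible functions (tyrosinase / catechol oxidase /
hemocyanin).

The package provides, as a library with a thin CLI:

* **motif_engine** — exhaustive His-triad scanning, site pairing,
  diagnostic/placeholder/cysteine evaluation, deterministic scoring;
* **architecture_scan** — Kyte–Doolittle heuristics for signal
  peptides, transmembrane segments and Cys-rich regions;
* **classify** — architecture-first α/β/γ assignment with evidence
  accounting, the functional feature table, per-species census;
* **phylo** — His-anchored alignment of the copper-binding region,
  p/Poisson distances, Saitou–Nei neighbor joining with deterministic
  tie-breaks, midpoint rooting, column bootstrap, monophyly tests;
* **genome_context** — tandem gene-cluster detection by single-linkage
  chaining of coordinates (GFF3/BED);
* **char_evolution** — minimal Dollo loss reconstruction on a species
  tree under fixed subclass origins (α root, β unikont stem, γ metazoan
  stem) plus expansion flagging;
* **synthetic** — a generator that is the constructive inverse of the
  classifier and realizes the published census aggregates (179 proteins,
  35 metazoan + 17 non-metazoan species, the named lineage expansions)
  so every stage is testable offline.

## Worked example

```python
import type3copper as t3

dataset = t3.generate_census(noise_rate=0.05, seed=1)   # 179 proteins
results = t3.classify_records(dataset.records)
meta = {e.name: e for e in dataset.spec.species}
rows = [{"species": cr.record.species, "lineage": cr.record.lineage,
         "metazoan": meta[cr.record.species].metazoan,
         "subclass": cr.call.subclass} for cr in results]
rows += [{"species": e.name, "lineage": e.lineage, "metazoan": e.metazoan,
          "subclass": ""} for e in dataset.spec.species if not e.counts]
census = t3.build_census(rows)
print(census.total, census.species_with_all_three())
print({s: census.count("Branchiostoma floridae", s)
       for s in t3.SUBCLASSES})
```

prints

```
179 ['Ciona intestinalis']
{'alpha': 0, 'beta': 0, 'gamma': 18}
```

— all 179 records classify to their subclass at 5% substitution noise,
exactly one species (the urochordate) retains all three subclasses, and
the amphioxus entry shows the 18-gene γ expansion.  Running
`python examples/03_build_tree.py` prints the phylogenetic side:

```
alignment: 18 rows x 113 columns, anchors at (10, 27, 38, 79, 83, 102)
alpha  monophyletic=True bootstrap=100% mean divergence=0.504
beta   monophyletic=True bootstrap=100% mean divergence=0.817
gamma  monophyletic=True bootstrap=99% mean divergence=0.499
```

— each subclass forms a supported clade on the midpoint-rooted NJ tree
and the cytosolic β subclass is the most divergent.  The other scripts
in `examples/` cover motif scanning, cluster detection (sizes 2–7, the
largest cluster holding 7 linked γ genes) and the Dollo loss /
expansion report (8 expansions ≥ 4 genes; 4 genomes without any type-3
copper protein).

## Command line

```bash
type3copper --seed 1 all --out-dir out/        # full pipeline on the fixture
type3copper scan proteins.fasta --out scan.tsv
type3copper classify proteins.fasta --metadata meta.tsv --out calls.tsv
type3copper phylo proteins.fasta --out tree.nwk --replicates 1000
type3copper clusters genes.gff3 calls.tsv --out clusters.tsv
type3copper evolve species.nwk census.tsv --out evolution.tsv
```

All parameters live in a YAML config (`--config`); unknown keys are
rejected and the resolved config is echoed next to the outputs.

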
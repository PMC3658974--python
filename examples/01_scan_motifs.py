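"""Detect a binuclear copper site in a single protein sequence.

Builds one α-subclass synthetic protein, scans it for Cu(A)/Cu(B)
histidine triads, and prints the site geometry and diagnostic residues.
"""

import type3copper as t3
from type3copper.synthetic import DEFAULT_PROFILES

template = t3.subclass_template("alpha",
                                DEFAULT_PROFILES[("cnidaria", "alpha")])
record = template.record
site = t3.best_binuclear_site(record)

print(f"sequence length: {len(record.sequence)}")
print(f"Cu(A) His triad: {site.cuA.h1}, {site.cuA.h2}, {site.cuA.h3} "
      f"(spacings {site.cuA.spacing12}, {site.cuA.spacing23})")
print(f"Cu(B) His triad: {site.cuB.h1}, {site.cuB.h2}, {site.cuB.h3} "
      f"(spacings {site.cuB.spacing12}, {site.cuB.spacing23})")
print(f"intersite gap:   {site.intersite_gap} residues")
print(f"diagnostics:     PheA={site.phe_A_ok} PheB={site.phe_B_ok} "
      f"AspB={site.asp_B_ok}")
print(f"placeholder:     {site.placeholder_residue} "
      f"at {site.placeholder_position}")
print(f"site score:      {site.score} (2 - shifted + diagnostics)")

# The Cu(A) site follows H1(n)-H2(8)-H3 and Cu(B) H1(3)-H2(n)-H3; the
# conserved Phe/Asp diagnostics and a small placeholder residue (V here)
# mark a tyrosinase-like secreted α-subclass active site.
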
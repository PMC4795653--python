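"""Splice-variant consequence arithmetic on the packaged Otx2-like fixtures.

One primer pair co-amplifies all three isoforms with distinct product sizes;
the ORF finder flags start/stop completeness; the protein diff locates each
indel relative to the homeodomain.
"""

from retsplice import diff_proteins, in_silico_pcr, predict_cds
from retsplice.fixtures import HOMEODOMAIN, otx2_like_fixture

f = otx2_like_fixture()
print("template       amplicon  ATG  CDS  protein")
for name in ("ref", "long_variant", "short_variant"):
    (bp,) = in_silico_pcr(f.templates[name], f.primers)
    p = predict_cds(f.templates[name])
    print(f"{name:14s} {bp:6d} bp   {'+' if p.has_atg else '-'}    "
          f"{'+' if p.cds_complete else '-'}   {len(p.protein)} aa")

for name in ("long_variant", "short_variant"):
    d = diff_proteins(f.proteins["ref"], f.proteins[name], [HOMEODOMAIN])
    (e,) = d.edits
    _, span, touching = d.domain_overlaps[0]
    where = "inside" if touching else "outside"
    print(f"{name}: {e.kind} of {e.length} aa at residue {e.position} "
          f"({where} the homeodomain {span[0]}-{span[1]})"
          + (f", sequence {e.sequence}" if e.kind == "insertion" else ""))
# Product-size differences equal the coding indels (271-247 = 24 nt = 8 aa
# insertion; 247-208 = 39 nt = 13 aa deletion).
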
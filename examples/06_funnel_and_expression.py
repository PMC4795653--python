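"""Candidate funnel on the packaged six-gene catalog, plus the qPCR
relative-expression arithmetic used to compare variant expression."""

from retsplice import (apply_funnel, load_reference_catalog,
                       rel_expression_dct, rel_expression_ddct)

catalog, go = load_reference_catalog()
report = apply_funnel(catalog, go)
for stage, n in report.staged_counts.items():
    print(f"{stage:32s} {n}")
print("final candidates:", ", ".join(report.genes_with_eye_go))

# Variant-vs-canonical expression in one tissue (2^-dCt against Actb):
ct_otx2, ct_variant, ct_actb = 22.0, 27.4, 18.0
rel = rel_expression_dct(ct_variant, ct_actb) / \
    rel_expression_dct(ct_otx2, ct_actb)
print(f"\nvariant expression = {100 * rel:.1f}% of the canonical isoform "
      "(2^-dCt ratio)")

# Knockdown of a target gene after overexpression (2^-ddCt vs GFP control):
fold = rel_expression_ddct(25.47, 17.0, 24.0, 17.0)
print(f"target gene fold change vs control: {fold:.2f} "
      "(below 1 = repressed)")
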
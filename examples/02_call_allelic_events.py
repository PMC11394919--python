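"""Heterozygote calling and SNP-level allelic-asymmetry testing.

A site is heterozygous when its depth pooled over all assays exceeds 20
reads with a minor-allele fraction of at least 0.2.  Each het site is then
tested per assay with an exact two-sided binomial test against equal
coverage of the two alleles, BH-adjusted within each (individual, assay)
family at 0.1.
"""

import pandas as pd

from rsnp_scan import binomial_asymmetry_p, call_events, pool_and_call_het

depths = pd.DataFrame({
    "individual": ["I0"] * 6,
    "assay": ["H3K4me3", "H3K27ac", "RNA"] * 2,
    "chrom": ["chr1"] * 6,
    "pos": [100, 100, 100, 200, 200, 200],
    "ref": ["A"] * 3 + ["C"] * 3,
    "alt": ["G"] * 3 + ["T"] * 3,
    "ref_count": [38, 31, 25, 10, 12, 9],
    "alt_count": [9, 6, 24, 11, 9, 10],
})

het = pool_and_call_het(depths, "I0")
print("heterozygous sites after pooling:")
print(het[["pos", "pooled_depth", "pooled_minor_fraction"]].to_string(index=False))

calls = call_events(het, depths)
print("\nper-assay asymmetry calls (ASB = chromatin mark, ASE = RNA):")
print(calls[["pos", "assay", "event_class", "ref_count", "alt_count",
             "p_value", "p_adj", "significant"]].to_string(index=False))

print(f"\nexact binomial p for 38 vs 9 reads: "
      f"{binomial_asymmetry_p(38, 9):.2e}")
print("Site 100 is strongly reference-skewed in both chromatin marks "
      "(candidate ASB) but balanced in RNA; site 200 shows no imbalance.")
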
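"""Gene-level allele-specific expression via pseudo-phasing Monte Carlo.

With unknown phase, picking the larger count at every SNV biases the
aggregate major-haplotype frequency above 0.5 even for balanced data, so
the null distribution must apply the same pseudo-phasing.  Note how two
perfectly balanced SNVs give p = 1 while the same aggregate frequency
computed naively would look inflated.
"""

from rsnp_scan import mbased_gene_ase

balanced = [(15, 15), (20, 20)]
maf, p = mbased_gene_ase(balanced, n_sim=9999, seed=0)
print(f"balanced gene   : aggregate MAF = {maf:.3f}, p = {p:.4f}")

skewed = [(26, 6), (4, 23), (19, 5)]  # per-SNV major alleles disagree: phase-free
maf, p = mbased_gene_ase(skewed, n_sim=9999, seed=0)
print(f"imbalanced gene : aggregate MAF = {maf:.3f}, p = {p:.4f}")

mild = [(18, 12), (17, 13)]
maf, p = mbased_gene_ase(mild, n_sim=9999, seed=0)
print(f"mildly skewed   : aggregate MAF = {maf:.3f}, p = {p:.4f}")

print("\nOnly the clearly imbalanced gene reaches a small p-value; the "
      "mild skew is what pseudo-phasing produces by chance at this depth.")
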
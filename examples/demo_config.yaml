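# Demonstration assay configuration for a 12-SNP panel.
#
# The calling model uses the published "paper-2011" coefficient preset.
# SNP ids, allele labels and trained offsets follow the demonstration
# panel; the theoretical melting temperatures are ILLUSTRATIVE values
# (real assays compute them from the primer sequences with a
# nearest-neighbour model and supply them here).
model:
  preset: paper-2011
  rho: 0.05
  smoothing_sigma: null
snps:
  - {snp_id: SNP1,  tm_a: 74.0, tm_b: 77.5, allele_a: T, allele_b: C, delta: 0.0}
  - {snp_id: SNP2,  tm_a: 75.0, tm_b: 78.75, allele_a: G, allele_b: A, delta: 0.0}
  - {snp_id: SNP3,  tm_a: 76.0, tm_b: 80.0, allele_a: A, allele_b: G, delta: 0.0}
  - {snp_id: SNP4,  tm_a: 77.0, tm_b: 81.25, allele_a: C, allele_b: T, delta: 0.0}
  - {snp_id: SNP5,  tm_a: 78.0, tm_b: 82.5, allele_a: C, allele_b: G, delta: -0.1}
  - {snp_id: SNP6,  tm_a: 79.0, tm_b: 82.5, allele_a: A, allele_b: G, delta: 0.1}
  - {snp_id: SNP7,  tm_a: 80.0, tm_b: 83.75, allele_a: G, allele_b: T, delta: 0.0}
  - {snp_id: SNP8,  tm_a: 74.0, tm_b: 78.0, allele_a: T, allele_b: C, delta: 0.1}
  - {snp_id: SNP9,  tm_a: 75.0, tm_b: 79.25, allele_a: T, allele_b: C, delta: 0.0}
  - {snp_id: SNP10, tm_a: 76.0, tm_b: 79.5, allele_a: G, allele_b: C, delta: -0.1}
  - {snp_id: SNP11, tm_a: 77.0, tm_b: 80.75, allele_a: A, allele_b: G, delta: 0.0}
  - {snp_id: SNP12, tm_a: 78.0, tm_b: 82.0, allele_a: G, allele_b: A, delta: 0.0}
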
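"""QC a microarray genotyping export: samples first, then SNPs.

Two poorly performing samples and ten bad SNPs are planted; the cascade
(outlier samples -> recomputed statistics -> cluster-separation / no-call /
intensity filters -> biallelic -> MAF > 0.01) should remove exactly those.
"""

from panelforge import array_qc as aq
from panelforge import synthetic_data as sd

samples, snps, manifest = sd.simulate_array_tables(
    n_samples=24, n_snps=200,
    planted_failures={"sample_outlier": 2, "cluster_sep": 4,
                      "nocall": 3, "ab_r_mean": 2, "low_maf": 1},
    seed=5,
)

sites, report = aq.array_pipeline(samples, snps)

print(f"samples excluded: {report['excluded_samples']}"
      f"  (planted: {manifest['planted_outlier_samples']})")
print(f"SNP exclusions by reason: {report['snp_qc']['by_reason']}")
print(f"removed for low MAF: {report['removed_low_maf']}")
print(f"final SNPs: {report['final_snps']}  (expected {manifest['expected_snp_survivors']})")
# The surviving site list carries chrom/pos and can be merged with
# sequencing-derived loci into one capture-target set.
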
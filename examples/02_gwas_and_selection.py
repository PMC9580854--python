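"""Fisher-exact GWAS on the training split and p-value SNP preselection.

The scan runs on training data only (no test-set leakage); SNPs at or
below a p-value threshold are kept, in sequence order, from both splits.
"""

import numpy as np

from genimg import (
    SimConfig,
    gwas_scan,
    select_snps,
    simulate_cohort,
    stratified_split,
)

cohort = simulate_cohort(
    SimConfig(n_samples=2000, n_snps=1000, n_causal=8, heritability=0.85, seed=1)
)
split = stratified_split(cohort, train_fraction=0.8, seed=1)
print(f"train {split.train.n_samples} / test {split.test.n_samples} samples, "
      f"case fraction {split.train.phenotype.mean():.3f} in both")

assoc = gwas_scan(split.train)
print(f"scanned {len(assoc)} SNPs; smallest p = {assoc.p_values.min():.2e}")

for threshold in (1.0, 1e-4, 1e-10):
    kept = select_snps(assoc, split.train, threshold)
    hits = set(kept.snp_ids) & set(cohort.snp_ids[cohort.causal_index])
    print(f"p <= {threshold:g}: kept {kept.n_snps:4d} SNPs "
          f"({len(hits)}/{len(cohort.causal_index)} causal among them)")
# stricter thresholds concentrate on the causal SNPs and their LD partners
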
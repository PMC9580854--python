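"""Iteration-averaged 1-D vs 2-D comparison and the head-similarity trace.

Runs the full repeated-iteration protocol at demonstration scale: per
iteration the split, liability noise and weight init are re-drawn; the
table reports per-cell means. Then the 1-D model is frozen and the cosine
similarity between both models' dense(10)->dense(2) weight blocks is
recorded at each 2-D training epoch.
"""

import numpy as np
from scipy.stats import spearmanr

from genimg import (
    ExperimentConfig,
    Hyperparams,
    SimConfig,
    build_1dcnn,
    build_2dcnn,
    encode_e1,
    flatten_for_1d,
    gwas_scan,
    penultimate_cosine_trace,
    select_snps,
    simulate_cohort,
    stratified_split,
    to_network_input,
    train,
)

cfg = ExperimentConfig(
    sim=SimConfig(n_samples=1500, n_snps=800, n_causal=8, heritability=0.85, seed=4),
    thresholds=(1.0, 1e-5),
    encodings=("E1",),
    models=("2d", "1d"),
    n_iterations=2,
    base_seed=4,
    hyperparams=Hyperparams(epochs=8, seed=4),
)
from genimg import run_iterations

res = run_iterations(cfg)
print(res.summary[["threshold", "encoding", "model", "train_acc", "test_acc",
                   "n_snps_selected"]].to_string(index=False))
print("(selection concentrates signal: the strict-threshold cells beat the "
      "all-SNP cells; 1-D and 2-D land close together)")

# head-similarity trace on the strict-threshold data
cohort = simulate_cohort(cfg.sim)
split = stratified_split(cohort, 0.8, seed=4)
assoc = gwas_scan(split.train)
sel = select_snps(assoc, split.train, 1e-5)
x1 = to_network_input(flatten_for_1d(sel))
x2 = to_network_input(encode_e1(sel))
hp = Hyperparams(epochs=10, seed=4)
frozen = train(build_1dcnn(x1.shape[1]), hp, x1, split.train.phenotype)
trace = penultimate_cosine_trace(
    frozen, build_2dcnn(x2.shape[1]), hp, x2, split.train.phenotype
)
rho = spearmanr(np.arange(len(trace.values)), trace.values).statistic
print(f"cosine similarity per epoch: {[f'{v:.3f}' for v in trace.values]}")
print(f"epoch-vs-similarity Spearman rho = {rho:.2f}")
print("(the trace drifts smoothly as the 2-D head trains; its direction is "
      "seed-dependent because the hidden-unit correspondence between the "
      "two independently initialized models is arbitrary)")
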
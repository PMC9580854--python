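"""Convert genotype sequences into square images under E1/E2/E3.

E1 writes the 0/1/2 dosage per pixel, E2 the heterozygosity indicator,
E3 packs 8 heterozygosity bits into one 0-255 byte pixel. Sequences wrap
row-major; trailing SNPs beyond the square capacity are discarded.
"""

import tempfile

import numpy as np

from genimg import (
    SimConfig,
    decode_e1,
    encode_e1,
    encode_e2,
    encode_e3,
    export_png,
    image_rmse,
    simulate_cohort,
    square_dim,
)

cohort = simulate_cohort(
    SimConfig(n_samples=4, n_snps=603, n_causal=3, heritability=0.7, seed=2)
)

for scheme, enc in [("E1", encode_e1), ("E2", encode_e2), ("E3", encode_e3)]:
    m = square_dim(cohort.n_snps, scheme)
    stack = enc(cohort)
    per_pixel = 8 if scheme == "E3" else 1
    print(f"{scheme}: {cohort.n_snps} SNPs -> {m}x{m} image, "
          f"{stack.n_snps_used} used, {cohort.n_snps - m * m * per_pixel} discarded")

e1 = encode_e1(cohort)
assert np.array_equal(decode_e1(e1)[0], cohort.genotypes[0, : e1.n_snps_used])
print("E1 decode(encode(x)) reproduces the consumed SNPs exactly")

print(f"RMSE between sample 0 and 1 (E1 images): "
      f"{image_rmse(e1.images[0], e1.images[1]):.3f}  (pixelwise genotype distance)")

with tempfile.TemporaryDirectory() as d:
    paths = export_png(e1, d)
    print(f"exported {len(paths)} grayscale PNGs, e.g. {paths[0].name}")
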
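"""Synthetic GWAS cohort: LD-structured genotypes, liability phenotypes.

The generator emulates the Hapgen2 -> PhenotypeSimulator pipeline with two
ingredients that need no external reference data:

* a founder-mosaic genotype model — each haplotype copies a small panel of
  founder haplotypes, switching founders along the chromosome, which
  produces local linkage disequilibrium whose strength and range are set by
  the panel and the switch rate;
* an additive polygenic liability model — a sparse set of causal SNPs with
  Gaussian effects, genetic variance h2, unit-variance liability, cut at 0
  into case/control labels.
"""

from __future__ import annotations

from typing import Optional, Tuple, Union

import numpy as np
from scipy.stats import norm

from .datatypes import GenotypeDataset, HaplotypePanel, SimConfig
from .errors import ConfigurationError, DataError

__all__ = [
    "simulate_founders",
    "simulate_genotypes",
    "simulate_phenotype",
    "binarize_phenotype",
    "simulate_cohort",
]


def simulate_founders(
    n_founders: int,
    n_snps: int,
    freq_range: Tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    ld: float = 0.97,
) -> HaplotypePanel:
    """Draw a founder haplotype panel with local LD.

    Per-SNP minor-allele frequencies are uniform on ``freq_range``. Each
    founder's alleles are generated by thresholding a latent AR(1) Gaussian
    process (autocorrelation ``ld`` per SNP step), so every allele is
    marginally Bernoulli(freqs[j]) and founders are i.i.d., while nearby
    SNPs within a founder are correlated — the panel-level source of LD
    blocks. ``ld=0`` recovers fully independent SNPs.
    """
    if n_founders < 2:
        raise ConfigurationError("need at least 2 founders")
    if n_snps < 0:
        raise ConfigurationError("n_snps must be non-negative")
    lo, hi = freq_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ConfigurationError("freq_range must lie inside (0, 0.5]")
    if not (0.0 <= ld < 1.0):
        raise ConfigurationError("ld must lie in [0, 1)")
    rng = np.random.default_rng([seed, 101])
    freqs = rng.uniform(lo, hi, size=n_snps)
    if n_snps == 0:
        return HaplotypePanel(
            founders=np.zeros((n_founders, 0), dtype=np.uint8), freqs=freqs
        )
    z = rng.standard_normal((n_founders, n_snps))
    if ld > 0.0:
        innov = np.sqrt(1.0 - ld * ld)
        for j in range(1, n_snps):
            z[:, j] = ld * z[:, j - 1] + innov * z[:, j]
    alleles = (z < norm.ppf(freqs)[None, :]).astype(np.uint8)
    return HaplotypePanel(founders=alleles, freqs=freqs)


def _mosaic_haplotypes(
    panel: HaplotypePanel, n_hap: int, switch_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Copy founder mosaics: at each SNP, switch to a uniformly chosen
    founder with probability ``switch_rate``, else keep copying."""
    k, m = panel.founders.shape
    out = np.empty((n_hap, m), dtype=np.uint8)
    cols = np.arange(m)
    chunk = max(1, int(2e7) // max(m, 1))
    for start in range(0, n_hap, chunk):
        stop = min(start + chunk, n_hap)
        b = stop - start
        switch = rng.random((b, m)) < switch_rate
        switch[:, 0] = True  # initial founder is a fresh uniform draw
        chosen = rng.integers(0, k, size=(b, m))
        last = np.maximum.accumulate(np.where(switch, cols[None, :], -1), axis=1)
        founder = np.take_along_axis(chosen, last, axis=1)
        out[start:stop] = panel.founders[founder, cols[None, :]]
    return out


def simulate_genotypes(
    panel: HaplotypePanel,
    n_samples: int,
    switch_rate: float = 0.01,
    seed: int = 0,
) -> GenotypeDataset:
    """Diploid genotypes as the sum of two independent founder mosaics."""
    if panel.n_snps == 0 or panel.n_founders == 0:
        raise DataError("haplotype panel is empty")
    if not (0.0 < switch_rate < 1.0):
        raise ConfigurationError("switch_rate must lie in (0, 1)")
    rng = np.random.default_rng([seed, 202])
    h1 = _mosaic_haplotypes(panel, n_samples, switch_rate, rng)
    h2 = _mosaic_haplotypes(panel, n_samples, switch_rate, rng)
    geno = (h1 + h2).astype(np.int8)
    m = panel.n_snps
    return GenotypeDataset(
        genotypes=geno,
        snp_ids=np.array([f"snp{j + 1:06d}" for j in range(m)], dtype=object),
        positions=np.arange(1, m + 1, dtype=np.int64),
        sample_ids=np.array(
            [f"sample{i + 1:06d}" for i in range(n_samples)], dtype=object
        ),
    )


def simulate_phenotype(
    genotypes: Union[GenotypeDataset, np.ndarray],
    n_causal: int,
    heritability: float,
    seed: int = 0,
    noise_seed: Optional[int] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Additive liability: causal subset, Gaussian effects, h2, noise.

    Causal indices (without replacement) and effect sizes beta ~ N(0, 1)
    derive from ``seed``; the environmental noise derives from
    ``noise_seed`` (defaulting to ``seed``), so repeated draws of the
    phenotype over a fixed genetic architecture are possible. The genetic
    score on standardized dosages is rescaled to variance ``heritability``,
    noise has variance 1 - h2, and the returned liability is standardized
    to mean 0, variance 1.

    Returns ``(liability, causal_index)``.
    """
    x = genotypes.genotypes if isinstance(genotypes, GenotypeDataset) else genotypes
    x = np.asarray(x)
    n, m = x.shape
    if not (0.0 <= heritability <= 1.0):
        raise ConfigurationError("heritability must lie in [0, 1]")
    if heritability > 0 and not (1 <= n_causal <= m):
        raise ConfigurationError("need 1 <= n_causal <= n_snps when h2 > 0")
    if n_causal > m:
        raise ConfigurationError("n_causal cannot exceed n_snps")
    rng_eff = np.random.default_rng([seed, 303])
    rng_noise = np.random.default_rng(
        [seed if noise_seed is None else noise_seed, 404]
    )
    causal = np.sort(rng_eff.choice(m, size=n_causal, replace=False))
    beta = rng_eff.standard_normal(n_causal)
    if heritability > 0.0:
        xc = x[:, causal].astype(np.float64)
        mu = xc.mean(axis=0)
        sd = xc.std(axis=0)
        sd[sd == 0.0] = 1.0  # monomorphic causal SNP contributes nothing
        g = ((xc - mu) / sd) @ beta
        gs = g.std()
        if gs == 0.0:
            raise DataError("genetic score has zero variance; cohort degenerate")
        g *= np.sqrt(heritability) / gs
    else:
        g = np.zeros(n)
    eps = rng_noise.standard_normal(n) * np.sqrt(max(0.0, 1.0 - heritability))
    liability = g + eps
    sd = liability.std()
    if sd == 0.0:
        raise DataError("liability has zero variance")
    liability = (liability - liability.mean()) / sd
    return liability, causal


def binarize_phenotype(liability: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """Case (1) iff liability strictly exceeds the threshold; ties -> control."""
    liability = np.asarray(liability, dtype=np.float64)
    if not np.isfinite(liability).all():
        raise DataError("liability contains non-finite values")
    return (liability > threshold).astype(np.int8)


def simulate_cohort(config: SimConfig) -> GenotypeDataset:
    """Full cohort: founders -> mosaics -> liability -> binary labels.

    Bit-reproducible from ``config`` (including its seed).
    """
    panel = simulate_founders(
        config.n_founders,
        config.n_snps,
        config.freq_range,
        seed=config.seed,
        ld=config.founder_ld,
    )
    ds = simulate_genotypes(
        panel, config.n_samples, config.switch_rate, seed=config.seed
    )
    liability, causal = simulate_phenotype(
        ds, config.n_causal, config.heritability, seed=config.seed
    )
    phen = binarize_phenotype(liability)
    return ds.replace(phenotype=phen, liability=liability, causal_index=causal)
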
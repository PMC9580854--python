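"""Core containers: haplotype panels, genotype datasets, simulation config.

Genotypes are always stored as minor-allele dosage (0/1/2, no missing
values), one row per sample, SNPs in sequence order. Everything downstream
(association scan, image encodings, CNN input) relies on that ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np

from .errors import ConfigurationError, DataError


@dataclass
class HaplotypePanel:
    """A set of founder haplotypes standing in for a reference panel.

    ``founders`` is an (n_founders, n_snps) 0/1 matrix (1 = minor allele);
    ``freqs`` holds the per-SNP minor-allele frequency used to draw it,
    each in (0, 0.5].
    """

    founders: np.ndarray
    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.founders = np.asarray(self.founders, dtype=np.uint8)
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        if self.founders.ndim != 2:
            raise DataError("founders must be a 2-D matrix")
        if self.freqs.shape != (self.founders.shape[1],):
            raise DataError("freqs length must equal the number of SNPs")
        if self.founders.size and not np.isin(self.founders, (0, 1)).all():
            raise DataError("founder alleles must be 0 or 1")
        if self.freqs.size and not ((self.freqs > 0) & (self.freqs <= 0.5)).all():
            raise ConfigurationError("minor-allele frequencies must lie in (0, 0.5]")

    @property
    def n_founders(self) -> int:
        return self.founders.shape[0]

    @property
    def n_snps(self) -> int:
        return self.founders.shape[1]


@dataclass
class GenotypeDataset:
    """Per-sample dosage matrix plus SNP metadata and (optional) phenotype.

    ``genotypes``: (n_samples, n_snps) with entries in {0, 1, 2}.
    ``positions``: strictly increasing 1-based coordinates.
    ``phenotype``: 0 = control, 1 = case, or None for a genotypes-only set.
    ``liability``: the continuous phenotype the binary labels were cut from.
    ``causal_index``: indices of the SNPs given nonzero simulated effects.
    """

    genotypes: np.ndarray
    snp_ids: np.ndarray
    positions: np.ndarray
    sample_ids: np.ndarray
    phenotype: Optional[np.ndarray] = None
    liability: Optional[np.ndarray] = None
    causal_index: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        if self.genotypes.ndim != 2:
            raise DataError("genotypes must be a 2-D matrix")
        if self.genotypes.size and (
            (self.genotypes < 0) | (self.genotypes > 2)
        ).any():
            raise DataError("genotype dosages must be 0, 1 or 2")
        self.genotypes = self.genotypes.astype(np.int8, copy=False)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        n, m = self.genotypes.shape
        if len(self.snp_ids) != m:
            raise DataError("snp_ids length must equal the number of SNPs")
        if len(self.positions) != m:
            raise DataError("positions length must equal the number of SNPs")
        if m and (np.diff(self.positions) <= 0).any():
            raise DataError("positions must be strictly increasing")
        if len(self.sample_ids) != n:
            raise DataError("sample_ids length must equal the number of samples")
        if self.phenotype is not None:
            self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
            if self.phenotype.shape != (n,):
                raise DataError("phenotype length must equal the number of samples")
            if self.phenotype.size and not np.isin(self.phenotype, (0, 1)).all():
                raise DataError("phenotype labels must be 0 or 1")
        if self.liability is not None:
            self.liability = np.asarray(self.liability, dtype=np.float64)
            if self.liability.shape != (n,):
                raise DataError("liability length must equal the number of samples")
        if self.causal_index is not None:
            self.causal_index = np.asarray(self.causal_index, dtype=np.int64)

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def subset_samples(self, index: np.ndarray) -> "GenotypeDataset":
        """Dataset restricted to the given sample indices (order kept)."""
        index = np.asarray(index)
        return GenotypeDataset(
            genotypes=self.genotypes[index],
            snp_ids=self.snp_ids,
            positions=self.positions,
            sample_ids=self.sample_ids[index],
            phenotype=None if self.phenotype is None else self.phenotype[index],
            liability=None if self.liability is None else self.liability[index],
            causal_index=self.causal_index,
        )

    def subset_snps(self, index: np.ndarray) -> "GenotypeDataset":
        """Dataset restricted to the given SNP indices (sequence order kept)."""
        index = np.asarray(index)
        if index.size and (np.diff(index) <= 0).any():
            index = np.sort(index)
        remap = None
        if self.causal_index is not None:
            pos = {int(j): k for k, j in enumerate(index)}
            remap = np.array(
                [pos[int(j)] for j in self.causal_index if int(j) in pos],
                dtype=np.int64,
            )
        return GenotypeDataset(
            genotypes=self.genotypes[:, index],
            snp_ids=self.snp_ids[index],
            positions=self.positions[index],
            sample_ids=self.sample_ids,
            phenotype=self.phenotype,
            liability=self.liability,
            causal_index=remap,
        )

    def replace(self, **kw) -> "GenotypeDataset":
        return replace(self, **kw)


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Defaults are calibrated so that the cohort sits in the operating regime
    the method is meant for: local LD blocks, a sparse polygenic
    architecture, and an after-selection Bayes accuracy of roughly 0.85
    (see docs/methods.md for the calibration argument).
    """

    n_samples: int = 10_000
    n_snps: int = 12_000
    n_founders: int = 20
    switch_rate: float = 0.01
    n_causal: int = 8
    heritability: float = 0.85
    freq_range: Tuple[float, float] = (0.05, 0.5)
    founder_ld: float = 0.99
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.heritability <= 1.0):
            raise ConfigurationError("heritability must lie in [0, 1]")
        if not (0.0 < self.switch_rate < 1.0):
            raise ConfigurationError("switch_rate must lie in (0, 1)")
        if self.n_causal > self.n_snps:
            raise ConfigurationError("n_causal cannot exceed n_snps")
        if self.n_causal < 0:
            raise ConfigurationError("n_causal must be non-negative")
        if self.n_causal == 0 and self.heritability > 0:
            raise ConfigurationError(
                "n_causal=0 is only valid with heritability 0 (pure-noise cohort)"
            )
        lo, hi = self.freq_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("freq_range must lie inside (0, 0.5]")
        if not (0.0 <= self.founder_ld < 1.0):
            raise ConfigurationError("founder_ld must lie in [0, 1)")
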
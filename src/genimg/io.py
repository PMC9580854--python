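"""Genotype file I/O and the stratified train/test split.

Two interchange formats are supported, both deliberately minimal:

* a GT-only biallelic VCF 4.2 dialect (optionally gzipped), read through
  cyvcf2/htslib — the container format the pipeline passes through;
* a PLINK-recodeA-style tab-delimited matrix: header
  ``sample_id  phenotype  <snp ids...>``, one 0/1/2 dosage cell per SNP.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import GenotypeDataset, SimConfig
from .errors import DataError, ParseError

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_recoded",
    "write_recoded",
    "write_manifest",
    "stratified_split",
    "SplitResult",
]

_PathLike = Union[str, Path]


@dataclass
class SplitResult:
    """A case/control-stratified partition of a dataset."""

    train: GenotypeDataset
    test: GenotypeDataset
    train_fraction: float


# ---------------------------------------------------------------------------
# VCF


def write_vcf(dataset: GenotypeDataset, path: _PathLike) -> None:
    """Write genotypes as a minimal biallelic VCF 4.2 (gzip if *.gz).

    Dosage 0 -> 0/0, 1 -> 0/1, 2 -> 1/1; REF=A, ALT=G; chromosome 21.
    The phenotype is not representable in VCF and is not written.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    gt_map = np.array(["0/0", "0/1", "1/1"], dtype=object)
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=21>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in dataset.sample_ids)
            + "\n"
        )
        for j in range(dataset.n_snps):
            row = gt_map[dataset.genotypes[:, j]]
            fh.write(
                f"21\t{dataset.positions[j]}\t{dataset.snp_ids[j]}\tA\tG\t.\t.\t.\tGT\t"
                + "\t".join(row)
                + "\n"
            )


def read_vcf(path: _PathLike) -> GenotypeDataset:
    """Read a biallelic GT-only VCF into a 0/1/2 dosage dataset.

    Multiallelic records and missing genotypes raise :class:`ParseError`
    naming the offending record.
    """
    path = str(path)
    vcf = VCF(path, gts012=True)
    sample_ids = np.array(vcf.samples, dtype=object)
    cols, ids, pos = [], [], []
    for v in vcf:
        rid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        if len(v.ALT) != 1:
            raise ParseError(f"record {rid}: multiallelic site not supported")
        # with gts012=True: 0=hom-ref, 1=het, 2=hom-alt, 3=missing
        g = np.asarray(v.gt_types)
        if (g == 3).any():
            raise ParseError(f"record {rid}: missing genotype")
        cols.append(g.astype(np.int8))
        ids.append(rid)
        pos.append(v.POS)
    if not cols:
        raise ParseError(f"{path}: no variant records found")
    return GenotypeDataset(
        genotypes=np.stack(cols, axis=1),
        snp_ids=np.array(ids, dtype=object),
        positions=np.array(pos, dtype=np.int64),
        sample_ids=sample_ids,
    )


# ---------------------------------------------------------------------------
# recodeA-style matrix


def write_recoded(dataset: GenotypeDataset, path: _PathLike) -> None:
    """Write the tab-delimited recodeA-style matrix (phenotype included)."""
    phen = dataset.phenotype
    if phen is None:
        phen = np.full(dataset.n_samples, -9, dtype=int)  # plink missing code
    df = pd.DataFrame(
        dataset.genotypes, columns=[str(s) for s in dataset.snp_ids]
    )
    df.insert(0, "phenotype", phen)
    df.insert(0, "sample_id", [str(s) for s in dataset.sample_ids])
    df.to_csv(path, sep="\t", index=False)


def read_recoded(path: _PathLike) -> GenotypeDataset:
    """Read a recodeA-style matrix written by :func:`write_recoded`.

    Positions are not stored in this format and are regenerated as the
    1-based column order.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.ParserError as e:
        raise ParseError(f"{path}: malformed table ({e})") from e
    if df.shape[1] < 2 or list(df.columns[:2]) != ["sample_id", "phenotype"]:
        raise ParseError(
            f"{path}: header must start with 'sample_id<TAB>phenotype'"
        )
    snp_ids = np.array(df.columns[2:], dtype=object)
    raw = df.iloc[:, 2:].to_numpy(dtype=object)
    ok = np.isin(raw, ("0", "1", "2"))
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise ParseError(
            f"{path}: row {i + 2}, column '{snp_ids[j]}': "
            f"invalid dosage {raw[i, j]!r} (must be 0/1/2)"
        )
    geno = raw.astype(np.int8)
    phen_raw = df["phenotype"].to_numpy(dtype=object)
    phenotype = None
    if not all(p == "-9" for p in phen_raw):
        try:
            phenotype = np.array([int(p) for p in phen_raw], dtype=np.int8)
        except ValueError as e:
            raise ParseError(f"{path}: non-integer phenotype value") from e
    return GenotypeDataset(
        genotypes=geno,
        snp_ids=snp_ids,
        positions=np.arange(1, len(snp_ids) + 1, dtype=np.int64),
        sample_ids=df["sample_id"].to_numpy(dtype=object),
        phenotype=phenotype,
    )


def write_manifest(config: SimConfig, path: _PathLike) -> None:
    """Echo the simulation config (seed included) to a key=value text file."""
    with open(path, "wt") as fh:
        for k, v in vars(config).items():
            fh.write(f"{k}={v}\n")


# ---------------------------------------------------------------------------
# split


def stratified_split(
    dataset: GenotypeDataset, train_fraction: float = 0.8, seed: int = 0
) -> SplitResult:
    """Random case/control-stratified split.

    Within each stratum the train size is ``floor(n * fraction + 0.5)``;
    membership is a seeded permutation, and sample order inside each side
    follows the original dataset. Both sides must end up non-empty in both
    strata.
    """
    if dataset.phenotype is None:
        raise DataError("dataset has no phenotype; cannot stratify")
    if not (0.0 < train_fraction < 1.0):
        raise DataError(
            f"train_fraction {train_fraction} leaves an empty train or test set"
        )
    rng = np.random.default_rng([seed, 505])
    train_idx, test_idx = [], []
    for label in (0, 1):
        stratum = np.flatnonzero(dataset.phenotype == label)
        name = "controls" if label == 0 else "cases"
        if stratum.size < 2:
            raise DataError(f"stratum too small: need at least 2 {name}")
        n_train = int(np.floor(stratum.size * train_fraction + 0.5))
        if n_train == 0 or n_train == stratum.size:
            raise DataError(
                f"train_fraction {train_fraction} leaves an empty side "
                f"for the {name} stratum (size {stratum.size})"
            )
        perm = rng.permutation(stratum.size)
        train_idx.append(stratum[perm[:n_train]])
        test_idx.append(stratum[perm[n_train:]])
    train = np.sort(np.concatenate(train_idx))
    test = np.sort(np.concatenate(test_idx))
    return SplitResult(
        train=dataset.subset_samples(train),
        test=dataset.subset_samples(test),
        train_fraction=train_fraction,
    )
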
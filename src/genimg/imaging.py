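"""Genotype-sequence -> square-image encodings E1/E2/E3 and image metrics.

A length-N dosage sequence is wrapped row-major (left to right, top to
bottom) into an M x M single-channel image; trailing SNPs beyond the square
capacity are discarded:

* E1 — additive: pixel = dosage (0/1/2), M = floor(sqrt(N));
* E2 — heterozygosity indicator: pixel = 1 iff dosage == 1 (lossy, 0 and 2
  collapse), M = floor(sqrt(N));
* E3 — byte packing: E2 bits in groups of 8, MSB first, one 0-255 pixel per
  group, M = floor(sqrt(N / 8)).

E1 and E3 are invertible on the consumed SNPs; E2 is not, and its decode is
refused. PNG export uses a display mapping (E1 {0,1,2}->{0,127,254}, E2
{0,1}->{0,255}, E3 identity); network input instead scales raw class values
to [0,1] by the scheme maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Union

import numpy as np
from PIL import Image

from .datatypes import GenotypeDataset
from .errors import DataError

__all__ = [
    "ImageStack",
    "square_dim",
    "encode",
    "encode_e1",
    "encode_e2",
    "encode_e3",
    "decode_e1",
    "unpack_e3",
    "image_mse",
    "image_rmse",
    "export_png",
    "read_png",
    "flatten_for_1d",
    "to_network_input",
]

SCHEMES = ("E1", "E2", "E3")
_SCHEME_MAX = {"E1": 2, "E2": 1, "E3": 255}
_PNG_LUT = {
    "E1": np.array([0, 127, 254], dtype=np.uint8),
    "E2": np.array([0, 255], dtype=np.uint8),
    "E3": np.arange(256, dtype=np.uint8),
}


@dataclass
class ImageStack:
    """Per-sample square single-channel images from one encoding scheme."""

    images: np.ndarray  # (n_samples, M, M) integers
    scheme: str
    n_snps_used: int
    snp_ids_used: np.ndarray
    sample_ids: np.ndarray

    @property
    def side(self) -> int:
        return self.images.shape[1]

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise DataError(f"unknown scheme {self.scheme!r}")
        if self.images.ndim != 3 or self.images.shape[1] != self.images.shape[2]:
            raise DataError("images must be a (n, M, M) stack")


def square_dim(n_snps: int, scheme: str = "E1") -> int:
    """Largest image side M fitting the scheme's capacity into n_snps.

    E1/E2 consume M^2 SNPs, E3 consumes 8*M^2; the remainder is discarded.
    """
    if scheme not in SCHEMES:
        raise DataError(f"unknown scheme {scheme!r}")
    per_pixel = 8 if scheme == "E3" else 1
    m = int(np.floor(np.sqrt(n_snps / per_pixel)))
    if m < 1:
        raise DataError(
            f"{n_snps} SNPs cannot fill a single {scheme} pixel "
            f"(needs at least {per_pixel})"
        )
    return m


def _as_matrix(genotypes):
    if isinstance(genotypes, GenotypeDataset):
        g = genotypes.genotypes
        snp_ids = genotypes.snp_ids
        sample_ids = genotypes.sample_ids
    else:
        g = np.asarray(genotypes)
        if g.ndim == 1:
            g = g[None, :]
        snp_ids = np.array([f"snp{j + 1:06d}" for j in range(g.shape[1])], dtype=object)
        sample_ids = np.array([str(i) for i in range(g.shape[0])], dtype=object)
    if g.size and ((g < 0) | (g > 2)).any():
        raise DataError("genotype dosages must be 0, 1 or 2")
    return g, snp_ids, sample_ids


def encode_e1(genotypes) -> ImageStack:
    """Additive encoding: the first M^2 dosages, row-major."""
    g, snp_ids, sample_ids = _as_matrix(genotypes)
    m = square_dim(g.shape[1], "E1")
    used = m * m
    return ImageStack(
        images=g[:, :used].reshape(-1, m, m).astype(np.int16),
        scheme="E1",
        n_snps_used=used,
        snp_ids_used=snp_ids[:used],
        sample_ids=sample_ids,
    )


def encode_e2(genotypes) -> ImageStack:
    """Heterozygosity-indicator encoding: pixel = 1 iff dosage == 1."""
    g, snp_ids, sample_ids = _as_matrix(genotypes)
    m = square_dim(g.shape[1], "E2")
    used = m * m
    bits = (g[:, :used] == 1).astype(np.int16)
    return ImageStack(
        images=bits.reshape(-1, m, m),
        scheme="E2",
        n_snps_used=used,
        snp_ids_used=snp_ids[:used],
        sample_ids=sample_ids,
    )


def encode_e3(genotypes) -> ImageStack:
    """Byte-packed encoding: 8 heterozygosity bits per pixel, MSB first."""
    g, snp_ids, sample_ids = _as_matrix(genotypes)
    m = square_dim(g.shape[1], "E3")
    used = 8 * m * m
    bits = (g[:, :used] == 1).astype(np.uint8)
    pixels = np.packbits(bits.reshape(g.shape[0], -1, 8), axis=-1)[..., 0]
    return ImageStack(
        images=pixels.reshape(-1, m, m).astype(np.int16),
        scheme="E3",
        n_snps_used=used,
        snp_ids_used=snp_ids[:used],
        sample_ids=sample_ids,
    )


def encode(genotypes, scheme: str) -> ImageStack:
    """Dispatch to the requested encoding scheme."""
    try:
        fn = {"E1": encode_e1, "E2": encode_e2, "E3": encode_e3}[scheme.upper()]
    except KeyError:
        raise DataError(f"unknown scheme {scheme!r}") from None
    return fn(genotypes)


def decode_e1(stack: ImageStack) -> np.ndarray:
    """Exact inverse of E1 on the consumed SNPs: (n, M^2) dosage matrix.

    E2 is 2-to-1 on {0, 2} and has no inverse; asking for one is an error.
    """
    if stack.scheme == "E2":
        raise DataError("E2 is lossy (0 and 2 collapse); no decoder exists")
    if stack.scheme != "E1":
        raise DataError(f"decode_e1 expects an E1 stack, got {stack.scheme}")
    n = stack.images.shape[0]
    return stack.images.reshape(n, -1).astype(np.int8)


def unpack_e3(stack: ImageStack) -> np.ndarray:
    """Exact inverse of E3 packing: (n, 8*M^2) heterozygosity bits."""
    if stack.scheme != "E3":
        raise DataError(f"unpack_e3 expects an E3 stack, got {stack.scheme}")
    n = stack.images.shape[0]
    bytes_ = stack.images.reshape(n, -1).astype(np.uint8)
    return np.unpackbits(bytes_[..., None], axis=-1).reshape(n, -1)


def image_mse(a: np.ndarray, b: np.ndarray) -> float:
    """Mean squared pixel difference between two images (or stacks)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise DataError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def image_rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root mean squared pixel difference."""
    return float(np.sqrt(image_mse(a, b)))


def export_png(stack: ImageStack, directory: Union[str, Path]) -> List[Path]:
    """Write one 8-bit grayscale PNG per sample: ``<sample_id>_<scheme>.png``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lut = _PNG_LUT[stack.scheme]
    paths = []
    for i, sid in enumerate(stack.sample_ids):
        img = lut[stack.images[i].astype(np.int64)]
        path = directory / f"{sid}_{stack.scheme}.png"
        Image.fromarray(img, mode="L").save(path)
        paths.append(path)
    return paths


def read_png(path: Union[str, Path], scheme: str) -> np.ndarray:
    """Read back an exported PNG to integer class values (inverse mapping)."""
    arr = np.asarray(Image.open(path).convert("L"))
    if scheme == "E1":
        return (arr.astype(np.int32) // 127).astype(np.int16)
    if scheme == "E2":
        return (arr > 0).astype(np.int16)
    if scheme == "E3":
        return arr.astype(np.int16)
    raise DataError(f"unknown scheme {scheme!r}")


def flatten_for_1d(dataset) -> np.ndarray:
    """Dosage sequences for the 1D CNN: all selected SNPs, no square cut."""
    g, _, _ = _as_matrix(dataset)
    return g.astype(np.int16)


def to_network_input(data: Union[ImageStack, np.ndarray]) -> np.ndarray:
    """Scale class values to [0, 1] by the scheme maximum (2, 1 or 255).

    Plain arrays are treated as dosage sequences (divided by 2).
    """
    if isinstance(data, ImageStack):
        return data.images.astype(np.float32) / _SCHEME_MAX[data.scheme]
    return np.asarray(data).astype(np.float32) / 2.0
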
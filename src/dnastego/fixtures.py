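"""Synthetic inputs: random covers and ridge-patterned test images.

The experiments this package mirrors used genomic records downloaded
from GenBank and fingerprint scans from the FVC2004 competition corpus.
Neither is needed to exercise the pipeline: any ACGT sequence is a valid
cover and any 8-bit grayscale raster is a valid secret.  This module
generates both deterministically, so the whole test suite runs offline.

:func:`published_cover_profiles` lists the eight published accession names
with their recorded lengths, for simulation harnesses that want covers
of realistic genomic size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bitimage import GrayscaleImage
from .errors import DnaStegoError
from .fasta import FastaRecord

__all__ = [
    "CoverProfile",
    "random_cover",
    "synthetic_fingerprint",
    "published_cover_profiles",
]


@dataclass(frozen=True)
class CoverProfile:
    """An accession-like label with its sequence length in bases."""

    name: str
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise DnaStegoError("cover length must be positive")


#: the eight published cover sequences and their lengths
_PROFILES = (
    ("AC153526", 200_117),
    ("AC166252", 149_884),
    ("AC167221", 204_841),
    ("AC168874", 206_488),
    ("AC168897", 200_203),
    ("AC168901", 191_456),
    ("AC168907", 194_226),
    ("AC168908", 218_028),
)


def published_cover_profiles() -> list[CoverProfile]:
    """The eight published accessions with their printed lengths."""
    return [CoverProfile(name, length) for name, length in _PROFILES]


def random_cover(
    length: int,
    seed: int,
    gc_fraction: float = 0.5,
    name: str = "synthetic_cover",
) -> FastaRecord:
    """A random ACGT sequence with a target GC fraction.

    Bases are drawn i.i.d. with P(G) = P(C) = gc_fraction/2 and
    P(A) = P(T) = (1 - gc_fraction)/2; deterministic per seed.
    """
    if length < 1:
        raise DnaStegoError(f"cover length must be >= 1, got {length}")
    if not 0.0 <= gc_fraction <= 1.0:
        raise DnaStegoError(f"gc_fraction must be in [0, 1], got {gc_fraction}")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    draws = rng.choice(alphabet, size=length, p=[at, gc, gc, at])
    return FastaRecord(identifier=name, sequence=draws.tobytes().decode("ascii"))


def synthetic_fingerprint(width: int, height: int, seed: int) -> GrayscaleImage:
    """A fingerprint-like test image: oriented sinusoidal ridges plus noise.

    The ridge orientation drifts smoothly across the frame (as real
    ridge flow does locally), the ridge period is ~9 px, and i.i.d.
    Gaussian noise is added before clamping to [0, 255].  Deterministic
    per seed; statistically it only emulates the ridge texture, not
    minutiae, cores or deltas.
    """
    if width < 1 or height < 1:
        raise DnaStegoError("image dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    y, x = np.mgrid[0:height, 0:width].astype(float)
    theta = (
        np.pi / 4
        + 0.9 * (x / max(width, 2) - 0.5)
        + 0.5 * np.sin(2 * np.pi * y / max(height, 2))
    )
    phase = (2 * np.pi / 9.0) * (x * np.cos(theta) + y * np.sin(theta))
    ridges = np.sin(phase + rng.uniform(0, 2 * np.pi))
    noisy = 127.5 + 100.0 * ridges + rng.normal(0.0, 18.0, size=ridges.shape)
    pixels = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)
    return GrayscaleImage(width, height, pixels.tobytes())
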
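"""Lossless conversion between 8-bit grayscale images and flat bit strings.

A grayscale image is serialized pixel by pixel in row-major order, each
pixel contributing its 8 bits most-significant bit first.  The bit string
is the plaintext that enters the Feistel cipher; the inverse conversion
reconstructs the image bit-exactly, so the pair forms a lossless codec.

Image dimensions are *not* embedded in the bit stream — they travel in
the key bundle, like the rest of the shared reconstruction metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import DimensionError, ImageFormatError

__all__ = [
    "GrayscaleImage",
    "image_to_bits",
    "bits_to_image",
    "read_image",
    "write_pgm",
]


@dataclass(frozen=True)
class GrayscaleImage:
    """An 8-bit (256-shade) grayscale image.

    Parameters
    ----------
    width, height : int
        Image dimensions in pixels, both >= 1.
    pixels : bytes
        Row-major intensity values, one byte per pixel.
    """

    width: int
    height: int
    pixels: bytes

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ImageFormatError(
                f"image dimensions must be positive, got {self.width}x{self.height}"
            )
        if len(self.pixels) != self.width * self.height:
            raise ImageFormatError(
                f"expected {self.width * self.height} pixels, got {len(self.pixels)}"
            )

    @classmethod
    def from_pixels(
        cls, width: int, height: int, values: Iterable[int]
    ) -> "GrayscaleImage":
        """Build an image from an iterable of intensities in [0, 255]."""
        vals = list(values)
        for v in vals:
            if not isinstance(v, (int, np.integer)) or not 0 <= v <= 255:
                raise ImageFormatError(f"pixel value {v!r} outside [0, 255]")
        return cls(width, height, bytes(vals))

    @property
    def array(self) -> np.ndarray:
        """Pixels as a (height, width) uint8 array (a copy)."""
        return (
            np.frombuffer(self.pixels, dtype=np.uint8)
            .reshape(self.height, self.width)
            .copy()
        )


def image_to_bits(img: GrayscaleImage) -> str:
    """Serialize an image to a '0'/'1' string, MSB-first, row-major.

    The output length is always ``8 * width * height``.
    """
    raw = np.frombuffer(img.pixels, dtype=np.uint8)
    bits = np.unpackbits(raw)  # MSB first
    return (bits + ord("0")).astype(np.uint8).tobytes().decode("ascii")


def bits_to_image(bits: str, width: int, height: int) -> GrayscaleImage:
    """Exact inverse of :func:`image_to_bits`.

    Raises
    ------
    DimensionError
        If ``len(bits) != 8 * width * height`` — the usual symptom of
        wrong metadata or a corrupted payload.
    """
    expected = 8 * width * height
    if len(bits) != expected:
        raise DimensionError(
            f"need {expected} bits for a {width}x{height} image, got {len(bits)}"
        )
    arr = np.frombuffer(bits.encode("ascii"), dtype=np.uint8) - ord("0")
    if arr.size and arr.max() > 1:
        raise DimensionError("bit string contains symbols other than 0/1")
    pixels = np.packbits(arr).tobytes()
    return GrayscaleImage(width, height, pixels)


def read_image(path: str | Path) -> GrayscaleImage:
    """Read a PGM (P5, maxval 255) or 8-bit grayscale PNG.

    Color or high-bit-depth inputs are rejected rather than converted:
    the pipeline is defined for 256-shade grayscale only.
    """
    try:
        with Image.open(path) as im:
            if im.mode != "L":
                raise ImageFormatError(
                    f"{path}: mode {im.mode!r} is not 8-bit grayscale; "
                    "convert the image before hiding it"
                )
            return GrayscaleImage(im.width, im.height, im.tobytes())
    except UnidentifiedImageError as exc:
        raise ImageFormatError(f"{path}: not a recognizable image file") from exc


def write_pgm(img: GrayscaleImage, path: str | Path) -> None:
    """Write a binary PGM (P5, maxval 255) file."""
    header = f"P5\n{img.width} {img.height}\n255\n".encode("ascii")
    Path(path).write_bytes(header + img.pixels)
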
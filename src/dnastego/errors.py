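"""Exception hierarchy.

Everything raised on bad data, bad keys, or inconsistent metadata derives
from :class:`DnaStegoError`, so callers (and the CLI) can distinguish
usage mistakes from data/key failures with a single except clause.
"""


class DnaStegoError(Exception):
    """Base class for all errors raised by this package."""


class ImageFormatError(DnaStegoError):
    """Image is not 8-bit grayscale, or pixel values are out of range."""


class DimensionError(DnaStegoError):
    """Bit-string length does not match the declared image dimensions."""


class KeyFormatError(DnaStegoError):
    """A key string has the wrong alphabet or bit length."""


class KeySizeError(KeyFormatError):
    """A key has the wrong bit width for its role (e.g. EK != 32 bits)."""


class KeyRangeError(DnaStegoError):
    """A key value is outside the range the current cover admits."""


class BlockError(DnaStegoError):
    """Ciphertext length is not a multiple of the 64-bit block size."""


class PaddingError(DnaStegoError):
    """Recorded padding size is inconsistent with the data length."""


class CodecError(DnaStegoError):
    """Bit string cannot be mapped to bases (odd length / bad symbols)."""


class AlphabetError(DnaStegoError):
    """Sequence contains symbols outside {A, C, G, T}."""


class CapacityError(DnaStegoError):
    """Cover sequence is too short for the requested layout."""


class TruncationError(DnaStegoError):
    """Stego sequence ends before the implied layout is exhausted."""


class MetadataError(DnaStegoError):
    """Bundle metadata (positions, counts) is inconsistent with the data."""


class BundleFormatError(DnaStegoError):
    """Key/bundle file is malformed: missing, unknown or inconsistent fields."""


class FastaError(DnaStegoError):
    """FASTA file is empty, has no header, or violates the alphabet policy."""
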
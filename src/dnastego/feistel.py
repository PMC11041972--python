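"""Single-round Feistel cipher on 64-bit blocks with a 32-bit key.

Each 64-bit plaintext block is split into a left half LT (bits 0..31)
and a right half RT (bits 32..63).  The round function is a bitwise AND
of RT with the 32-bit encryption key EK, and the output block is

    AE = RT || ((RT & EK) ^ LT)

i.e. the right half passes through verbatim and the left half is masked
by a key-dependent function of the right half.  Decryption recomputes
the same round function from the transmitted right half and XORs it off.

Messages whose bit length is not a multiple of 64 are padded with zero
bits appended at the end; the padding size is shared metadata and the
same number of bits is removed from the end after decryption.

This is exactly one round with an AND-based round function.  It is a
structural scrambling step inside a larger hiding scheme, not a modern
confidentiality primitive; see the structural pass-through property in
the tests, which asserts precisely what the construction guarantees.
"""

from __future__ import annotations

from .errors import BlockError, CodecError, KeySizeError, PaddingError
from .keys import parse_key_string

BLOCK_BITS = 64
HALF_BITS = 32
EK_BITS = 32

__all__ = ["BLOCK_BITS", "EK_BITS", "pad_to_blocks", "encrypt", "decrypt"]

_HALF_MASK = (1 << HALF_BITS) - 1


def _as_ek(key: int | str) -> int:
    """Normalize an encryption key given as int or 32-char binary string."""
    if isinstance(key, str):
        try:
            return parse_key_string(key, EK_BITS)
        except Exception as exc:
            raise KeySizeError(str(exc)) from exc
    if not 0 <= key < (1 << EK_BITS):
        raise KeySizeError(f"encryption key must fit in {EK_BITS} bits, got {key}")
    return key


def _check_bits(bits: str) -> None:
    if bits and (set(bits) - {"0", "1"}):
        raise CodecError("bit string contains symbols other than 0/1")


def pad_to_blocks(bits: str) -> tuple[str, int]:
    """Append zero bits until the length is a multiple of 64.

    Returns the padded string and the number of bits appended
    (``(64 - len % 64) % 64``, so an already-aligned or empty input is
    returned unchanged with padding size 0).
    """
    _check_bits(bits)
    padding_size = (-len(bits)) % BLOCK_BITS
    return bits + "0" * padding_size, padding_size


def encrypt(bits: str, key: int | str) -> tuple[str, int]:
    """Encrypt a bit string; returns (ciphertext, padding_size).

    The input is zero-padded to a 64-bit block boundary first; the
    ciphertext has exactly the padded length.
    """
    ek = _as_ek(key)
    padded, padding_size = pad_to_blocks(bits)
    out: list[str] = []
    for i in range(0, len(padded), BLOCK_BITS):
        lt = int(padded[i : i + HALF_BITS], 2)
        rt = int(padded[i + HALF_BITS : i + BLOCK_BITS], 2)
        al = ((rt & ek) ^ lt) & _HALF_MASK
        out.append(format(rt, "032b"))
        out.append(format(al, "032b"))
    return "".join(out), padding_size


def decrypt(cipher: str, key: int | str, padding_size: int = 0) -> str:
    """Invert :func:`encrypt`; strips ``padding_size`` bits from the end.

    Raises
    ------
    BlockError
        If the ciphertext length is not a multiple of 64.
    PaddingError
        If ``padding_size`` is negative or exceeds the data length.
    """
    ek = _as_ek(key)
    _check_bits(cipher)
    if len(cipher) % BLOCK_BITS:
        raise BlockError(
            f"ciphertext length {len(cipher)} is not a multiple of {BLOCK_BITS}"
        )
    if not 0 <= padding_size <= len(cipher):
        raise PaddingError(
            f"padding size {padding_size} invalid for length {len(cipher)}"
        )
    out: list[str] = []
    for i in range(0, len(cipher), BLOCK_BITS):
        rt = int(cipher[i : i + HALF_BITS], 2)
        al = int(cipher[i + HALF_BITS : i + BLOCK_BITS], 2)
        lt = ((rt & ek) ^ al) & _HALF_MASK
        out.append(format(lt, "032b"))
        out.append(format(rt, "032b"))
    plain = "".join(out)
    return plain[: len(plain) - padding_size] if padding_size else plain
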
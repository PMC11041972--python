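"""Payload embedding: ambiguity bases, padding, and keyed segmented insertion.

The hiding layout is purely positional.  Starting at offset FPK in the
cover, payload segments of FSK bases alternate with untouched runs of
DSK cover bases:

    cover[0:FPK]  seg1  gap(DSK)  seg2  gap(DSK) ... segN  cover rest

so the stego ("fake DNA") sequence is the cover plus the payload, base
for base, and deleting the payload positions restores the cover exactly.

Before insertion the encrypted, DNA-encoded payload is expanded with
floor(len/10) decoy "ambiguity" bases at secret random positions, then
padded with 'A' bases to a multiple of FSK.  Both expansions are exactly
reversible from the bundle metadata: the padding count is stripped from
the end first (it was appended last), then the recorded ambiguity
positions are deleted in descending order.

Pipelines :func:`hide_image` / :func:`extract_image` compose the image,
cipher, codec and insertion stages and are exact inverses of each other.
"""

from __future__ import annotations

import random

from . import feistel
from .bitimage import GrayscaleImage, bits_to_image, image_to_bits
from .dna_codec import BASES, DEFAULT_RULE, EncodingRule, bits_to_dna, dna_to_bits
from .errors import (
    AlphabetError,
    CapacityError,
    CodecError,
    KeyRangeError,
    MetadataError,
    TruncationError,
)
from .keys import KeyBundle, KeyMaterial

__all__ = [
    "AMBIGUITY_DENOMINATOR",
    "PAD_BASE",
    "add_ambiguity",
    "strip_ambiguity",
    "pad_payload",
    "hide_payload",
    "extract_payload",
    "hide_image",
    "extract_image",
    "recover_cover",
]

#: one decoy base is inserted per this many payload bases (floor division)
AMBIGUITY_DENOMINATOR = 10

#: base appended to round the payload up to a multiple of FSK
PAD_BASE = "A"

_BASE_SET = frozenset(BASES)


def _check_alphabet(seq: str, what: str) -> None:
    if set(seq) - _BASE_SET:
        raise AlphabetError(f"{what} contains symbols outside ACGT")


def add_ambiguity(
    payload: str, seed: int | random.Random
) -> tuple[str, tuple[int, ...]]:
    """Insert ``floor(len/10)`` random decoy bases at random positions.

    Returns the expanded sequence and the final absolute indices of the
    inserted bases, sorted ascending.  The positions are drawn uniformly
    without replacement over the expanded coordinate space, which gives
    the same distribution as inserting one base at a time at a uniform
    offset of the current sequence.  Deleting the returned positions
    recovers the input exactly.
    """
    _check_alphabet(payload, "payload")
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    m = len(payload) // AMBIGUITY_DENOMINATOR
    if m == 0:
        return payload, ()
    total = len(payload) + m
    positions = sorted(rng.sample(range(total), m))
    decoys = rng.choices(BASES, k=m)
    # Single-pass merge over the expanded index space: copy the payload
    # slice between consecutive decoy slots, then the decoy itself.
    out: list[str] = []
    src = 0
    prev = -1
    for pos, base in zip(positions, decoys):
        take = pos - prev - 1
        out.append(payload[src : src + take])
        out.append(base)
        src += take
        prev = pos
    out.append(payload[src:])
    return "".join(out), tuple(positions)


def strip_ambiguity(expanded: str, positions: tuple[int, ...] | list[int]) -> str:
    """Delete the recorded decoy positions (equivalently: descending order).

    Raises :class:`MetadataError` when a position falls outside the
    sequence or repeats — the signature of a corrupt or mismatched bundle.
    """
    pos_set = set(positions)
    if len(pos_set) != len(positions):
        raise MetadataError("ambiguity positions contain duplicates")
    if pos_set and (min(pos_set) < 0 or max(pos_set) >= len(expanded)):
        raise MetadataError(
            f"ambiguity position outside sequence of length {len(expanded)}"
        )
    return "".join(c for i, c in enumerate(expanded) if i not in pos_set)


def pad_payload(payload: str, fsk: int) -> tuple[str, int]:
    """Append 'A' bases until the length is a multiple of FSK.

    Returns the padded payload and the number of bases appended.
    """
    if fsk < 1:
        raise KeyRangeError(f"FSK must be >= 1, got {fsk}")
    count = (-len(payload)) % fsk
    return payload + PAD_BASE * count, count


def _layout_check(cover_len: int, payload_len: int, fpk: int, dsk: int, fsk: int):
    if fsk < 1 or dsk < 1:
        raise KeyRangeError(f"DSK and FSK must be >= 1, got DSK={dsk}, FSK={fsk}")
    if not 0 <= fpk <= cover_len:
        raise KeyRangeError(
            f"FPK={fpk} outside the cover (length {cover_len}); "
            "choose a first-position key within the sequence"
        )
    if payload_len % fsk:
        raise CodecError(
            f"payload length {payload_len} is not a multiple of FSK {fsk}"
        )
    nseg = payload_len // fsk
    if nseg and cover_len - fpk < dsk * (nseg - 1):
        raise CapacityError(
            f"cover too short: need {dsk * (nseg - 1)} bases after offset {fpk} "
            f"for {nseg} segments, have {cover_len - fpk}"
        )
    return nseg


def hide_payload(cover: str, payload: str, fpk: int, dsk: int, fsk: int) -> str:
    """Interleave FSK-base payload segments into the cover from offset FPK."""
    _check_alphabet(cover, "cover")
    _check_alphabet(payload, "payload")
    nseg = _layout_check(len(cover), len(payload), fpk, dsk, fsk)
    if nseg == 0:
        return cover
    parts: list[str] = [cover[:fpk]]
    cpos = fpk
    for k in range(nseg):
        parts.append(payload[k * fsk : (k + 1) * fsk])
        if k < nseg - 1:
            parts.append(cover[cpos : cpos + dsk])
            cpos += dsk
    parts.append(cover[cpos:])
    return "".join(parts)


def extract_payload(
    stego: str, fpk: int, dsk: int, fsk: int, payload_len: int
) -> tuple[str, str]:
    """Inverse of :func:`hide_payload`: returns (payload, residual cover)."""
    _check_alphabet(stego, "stego sequence")
    if fsk < 1 or dsk < 1:
        raise KeyRangeError(f"DSK and FSK must be >= 1, got DSK={dsk}, FSK={fsk}")
    if payload_len % fsk:
        raise CodecError(
            f"payload length {payload_len} is not a multiple of FSK {fsk}"
        )
    if not 0 <= fpk <= len(stego):
        raise KeyRangeError(f"FPK={fpk} outside the stego sequence")
    nseg = payload_len // fsk
    if nseg == 0:
        return "", stego
    segs: list[str] = []
    cover_parts: list[str] = [stego[:fpk]]
    i = fpk
    for k in range(nseg):
        if i + fsk > len(stego):
            raise TruncationError(
                "stego sequence ends inside a payload segment; wrong keys or "
                "truncated data"
            )
        segs.append(stego[i : i + fsk])
        i += fsk
        if k < nseg - 1:
            if i + dsk > len(stego):
                raise TruncationError(
                    "stego sequence ends inside a cover gap; wrong keys or "
                    "truncated data"
                )
            cover_parts.append(stego[i : i + dsk])
            i += dsk
    cover_parts.append(stego[i:])
    return "".join(segs), "".join(cover_parts)


def hide_image(
    cover: str,
    image: GrayscaleImage,
    keys: KeyMaterial,
    rule: EncodingRule = DEFAULT_RULE,
    seed: int = 0,
) -> tuple[str, KeyBundle]:
    """Encrypt an image and hide it in a cover sequence.

    Composes image->bits, Feistel encryption, bits->DNA, ambiguity
    injection (seeded by ``seed``), FSK padding, and segmented insertion.
    Returns the stego sequence and the bundle holding everything the
    receiver needs for exact recovery.
    """
    bits = image_to_bits(image)
    cipher, padding_size = feistel.encrypt(bits, keys.ek)
    payload = bits_to_dna(cipher, rule)
    expanded, ambig_positions = add_ambiguity(payload, seed)
    padded, count = pad_payload(expanded, keys.fsk)
    stego = hide_payload(cover, padded, keys.fpk, keys.dsk, keys.fsk)
    bundle = KeyBundle(
        ek=keys.ek,
        fpk=keys.fpk,
        dsk=keys.dsk,
        fsk=keys.fsk,
        rule_id=rule.rule_id,
        padding_size=padding_size,
        count=count,
        ambig_positions=ambig_positions,
        payload_len=len(padded),
        image_width=image.width,
        image_height=image.height,
        seed=seed,
    )
    return stego, bundle


def extract_image(stego: str, bundle: KeyBundle) -> GrayscaleImage:
    """Recover the hidden image from a stego sequence and its bundle.

    The stages of :func:`hide_image` are inverted in reverse order:
    segmented extraction, FSK-padding removal (from the end), ambiguity
    deletion, DNA->bits decoding, Feistel decryption, bits->image.  With
    a wrong key this raises a :class:`~dnastego.errors.DnaStegoError`
    or returns a garbled image — never a silent partial success.
    """
    padded, _ = extract_payload(
        stego, bundle.fpk, bundle.dsk, bundle.fsk, bundle.payload_len
    )
    if bundle.count > len(padded):
        raise MetadataError("padding count exceeds the extracted payload")
    expanded = padded[: len(padded) - bundle.count] if bundle.count else padded
    payload = strip_ambiguity(expanded, bundle.ambig_positions)
    rule = EncodingRule.from_id(bundle.rule_id)
    cipher = dna_to_bits(payload, rule)
    bits = feistel.decrypt(cipher, bundle.ek, bundle.padding_size)
    return bits_to_image(bits, bundle.image_width, bundle.image_height)


def recover_cover(stego: str, bundle: KeyBundle) -> str:
    """Return the original cover: the stego minus all payload positions."""
    _, cover = extract_payload(
        stego, bundle.fpk, bundle.dsk, bundle.fsk, bundle.payload_len
    )
    return cover
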
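"""Keys: generation, parsing, serialization, and key-space arithmetic.

Four secret keys drive hiding and recovery:

EK
    32-bit encryption key for the Feistel round.
FPK
    32-bit first-position key — the 0-based offset in the cover where
    insertion starts.  Validated against the cover length at hide time
    (an out-of-range FPK is an error, never silently reduced).
DSK
    8-bit DNA-segment key — the number of cover bases kept between
    consecutive hidden segments.  Must be >= 1.
FSK
    8-bit fingerprint-segment key — the number of payload bases per
    hidden segment.  Must be >= 1.

The total key space is 2^32 * 2^8 * 2^8 * 2^32 = 2^80 by the published
count, which treats DSK/FSK as full 8-bit values; the generator here
excludes the degenerate value 0 for both (a documented discrepancy of
at most 2/256 of the counted space).

The receiver additionally needs shared reconstruction metadata — the
encoding-rule id, Feistel padding size, payload padding count, ambiguity
positions, payload length, image dimensions, and the ambiguity seed.
Keys plus metadata form a :class:`KeyBundle`, serialized as JSON with a
fixed schema (unknown fields are rejected).  Key integers are written in
decimal and echoed as spaced binary strings for eyeballing.

All positions in this package are 0-based.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass
from pathlib import Path

from .errors import BundleFormatError, KeyFormatError

__all__ = [
    "EK_BITS",
    "FPK_BITS",
    "DSK_BITS",
    "FSK_BITS",
    "KeyMaterial",
    "KeyBundle",
    "generate_keys",
    "parse_key_string",
    "format_key_string",
    "key_space",
    "write_bundle",
    "read_bundle",
    "write_key_material",
    "read_key_material",
]

EK_BITS = 32
FPK_BITS = 32
DSK_BITS = 8
FSK_BITS = 8

#: group width used when pretty-printing keys as binary
_GROUP = 16


def parse_key_string(s: str, expected_bits: int) -> int:
    """Parse a binary key string (whitespace tolerated) to an unsigned int.

    The bit count after whitespace removal must equal ``expected_bits``.
    """
    compact = "".join(s.split())
    if not compact or set(compact) - {"0", "1"}:
        raise KeyFormatError(f"key string {s!r} is not binary")
    if len(compact) != expected_bits:
        raise KeyFormatError(
            f"key string has {len(compact)} bits, expected {expected_bits}"
        )
    return int(compact, 2)


def format_key_string(value: int, bits: int) -> str:
    """Format an unsigned int as a binary string, in 16-bit groups."""
    if not 0 <= value < (1 << bits):
        raise KeyFormatError(f"value {value} does not fit in {bits} bits")
    raw = format(value, f"0{bits}b")
    if bits <= _GROUP:
        return raw
    return " ".join(raw[i : i + _GROUP] for i in range(0, bits, _GROUP))


def key_space(
    ek_bits: int = EK_BITS,
    dsk_bits: int = DSK_BITS,
    fsk_bits: int = FSK_BITS,
    fpk_bits: int = FPK_BITS,
) -> int:
    """Exact size of the combined key space, ``2**(sum of bit widths)``.

    Computed in arbitrary precision; (32, 8, 8, 32) gives 2**80.
    """
    for b in (ek_bits, dsk_bits, fsk_bits, fpk_bits):
        if b < 0:
            raise KeyFormatError("bit widths must be non-negative")
    return 1 << (ek_bits + dsk_bits + fsk_bits + fpk_bits)


@dataclass(frozen=True)
class KeyMaterial:
    """The four secret keys as unsigned integers."""

    ek: int
    fpk: int
    dsk: int
    fsk: int

    def __post_init__(self) -> None:
        _check_range("ek", self.ek, EK_BITS, minimum=0)
        _check_range("fpk", self.fpk, FPK_BITS, minimum=0)
        _check_range("dsk", self.dsk, DSK_BITS, minimum=1)
        _check_range("fsk", self.fsk, FSK_BITS, minimum=1)

    @property
    def ek_binary(self) -> str:
        return format_key_string(self.ek, EK_BITS)

    @property
    def fpk_binary(self) -> str:
        return format_key_string(self.fpk, FPK_BITS)

    @property
    def dsk_binary(self) -> str:
        return format_key_string(self.dsk, DSK_BITS)

    @property
    def fsk_binary(self) -> str:
        return format_key_string(self.fsk, FSK_BITS)


def _check_range(name: str, value: int, bits: int, minimum: int) -> None:
    if not isinstance(value, int) or not minimum <= value < (1 << bits):
        raise KeyFormatError(
            f"{name} must be an integer in [{minimum}, 2^{bits}), got {value!r}"
        )


def generate_keys(
    seed: int | random.Random, max_fpk: int | None = None
) -> KeyMaterial:
    """Draw the four keys uniformly at random, deterministically per seed.

    DSK and FSK are redrawn until non-zero (0 would be a degenerate
    layout).  If ``max_fpk`` is given, FPK is drawn uniformly from
    ``[0, max_fpk]`` instead of the full 32-bit range — convenient when
    the cover is much shorter than 2^32 bases.
    """
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    ek = rng.getrandbits(EK_BITS)
    if max_fpk is None:
        fpk = rng.getrandbits(FPK_BITS)
    else:
        fpk = rng.randint(0, min(max_fpk, (1 << FPK_BITS) - 1))
    dsk = 0
    while dsk == 0:
        dsk = rng.getrandbits(DSK_BITS)
    fsk = 0
    while fsk == 0:
        fsk = rng.getrandbits(FSK_BITS)
    return KeyMaterial(ek=ek, fpk=fpk, dsk=dsk, fsk=fsk)


@dataclass(frozen=True)
class KeyBundle:
    """Keys plus the shared metadata needed for exact recovery."""

    ek: int
    fpk: int
    dsk: int
    fsk: int
    rule_id: int
    padding_size: int
    count: int
    ambig_positions: tuple[int, ...]
    payload_len: int
    image_width: int
    image_height: int
    seed: int

    def __post_init__(self) -> None:
        _check_range("ek", self.ek, EK_BITS, minimum=0)
        _check_range("fpk", self.fpk, FPK_BITS, minimum=0)
        _check_range("dsk", self.dsk, DSK_BITS, minimum=1)
        _check_range("fsk", self.fsk, FSK_BITS, minimum=1)
        object.__setattr__(self, "ambig_positions", tuple(self.ambig_positions))
        if not 1 <= self.rule_id <= 24:
            raise BundleFormatError(f"rule_id {self.rule_id} outside 1..24")
        if not 0 <= self.padding_size <= 63:
            raise BundleFormatError(f"padding_size {self.padding_size} outside 0..63")
        if self.count < 0 or self.payload_len < 0:
            raise BundleFormatError("count and payload_len must be non-negative")
        if self.payload_len % self.fsk:
            raise BundleFormatError(
                f"payload_len {self.payload_len} is not a multiple of FSK {self.fsk}"
            )
        if self.image_width < 1 or self.image_height < 1:
            raise BundleFormatError("image dimensions must be positive")
        prev = -1
        for p in self.ambig_positions:
            if not prev < p < self.payload_len:
                raise BundleFormatError(
                    "ambig_positions must be strictly increasing and < payload_len"
                )
            prev = p

    @property
    def key_material(self) -> KeyMaterial:
        return KeyMaterial(ek=self.ek, fpk=self.fpk, dsk=self.dsk, fsk=self.fsk)


_BUNDLE_REQUIRED = (
    "ek",
    "fpk",
    "dsk",
    "fsk",
    "rule_id",
    "padding_size",
    "count",
    "ambig_positions",
    "payload_len",
    "image_width",
    "image_height",
    "seed",
)
_BINARY_ECHOES = {
    "ek_binary": ("ek", EK_BITS),
    "fpk_binary": ("fpk", FPK_BITS),
    "dsk_binary": ("dsk", DSK_BITS),
    "fsk_binary": ("fsk", FSK_BITS),
}
_KEYFILE_REQUIRED = ("ek", "fpk", "dsk", "fsk")


def _echoes(km: KeyMaterial) -> dict[str, str]:
    return {
        "ek_binary": km.ek_binary,
        "fpk_binary": km.fpk_binary,
        "dsk_binary": km.dsk_binary,
        "fsk_binary": km.fsk_binary,
    }


def write_bundle(bundle: KeyBundle, path: str | Path) -> None:
    """Serialize a complete bundle to JSON (decimal ints + binary echoes)."""
    doc = asdict(bundle)
    doc["ambig_positions"] = list(bundle.ambig_positions)
    doc.update(_echoes(bundle.key_material))
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def _load_json(path: str | Path) -> dict:
    try:
        doc = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise BundleFormatError(f"{path}: cannot parse key file: {exc}") from exc
    if not isinstance(doc, dict):
        raise BundleFormatError(f"{path}: key file must contain a JSON object")
    return doc


def _check_echoes(doc: dict, path) -> None:
    for name, (target, bits) in _BINARY_ECHOES.items():
        if name in doc and target in doc:
            if parse_key_string(str(doc[name]), bits) != doc[target]:
                raise BundleFormatError(
                    f"{path}: {name} disagrees with the decimal {target} value"
                )


def read_bundle(path: str | Path) -> KeyBundle:
    """Read a complete bundle; missing or unknown fields are rejected."""
    doc = _load_json(path)
    known = set(_BUNDLE_REQUIRED) | set(_BINARY_ECHOES)
    unknown = set(doc) - known
    if unknown:
        raise BundleFormatError(f"{path}: unknown fields {sorted(unknown)}")
    missing = [k for k in _BUNDLE_REQUIRED if k not in doc]
    if missing:
        raise BundleFormatError(f"{path}: missing fields {missing}")
    _check_echoes(doc, path)
    try:
        return KeyBundle(**{k: doc[k] for k in _BUNDLE_REQUIRED})
    except (TypeError, KeyFormatError) as exc:
        raise BundleFormatError(f"{path}: {exc}") from exc


def write_key_material(
    km: KeyMaterial,
    path: str | Path,
    rule_id: int | None = None,
    seed: int | None = None,
) -> None:
    """Write a keys-only file (the ``keygen`` output, consumed by ``hide``)."""
    doc: dict = {"ek": km.ek, "fpk": km.fpk, "dsk": km.dsk, "fsk": km.fsk}
    if rule_id is not None:
        doc["rule_id"] = rule_id
    if seed is not None:
        doc["seed"] = seed
    doc.update(_echoes(km))
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_key_material(path: str | Path) -> tuple[KeyMaterial, int | None, int | None]:
    """Read the four keys from a keys-only file or a full bundle.

    Returns ``(keys, rule_id, seed)`` with rule_id/seed ``None`` when the
    file does not carry them.
    """
    doc = _load_json(path)
    known = set(_BUNDLE_REQUIRED) | set(_BINARY_ECHOES)
    unknown = set(doc) - known
    if unknown:
        raise BundleFormatError(f"{path}: unknown fields {sorted(unknown)}")
    missing = [k for k in _KEYFILE_REQUIRED if k not in doc]
    if missing:
        raise BundleFormatError(f"{path}: missing fields {missing}")
    _check_echoes(doc, path)
    try:
        km = KeyMaterial(ek=doc["ek"], fpk=doc["fpk"], dsk=doc["dsk"], fsk=doc["fsk"])
    except KeyFormatError as exc:
        raise BundleFormatError(f"{path}: {exc}") from exc
    return km, doc.get("rule_id"), doc.get("seed")
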
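"""Binary <-> DNA base conversion under 2-bit encoding rules.

Each of the four bases A, C, G, T is assigned one of the four 2-bit
codes 00, 01, 10, 11; there are 4! = 24 such bijections.  Eight of them
are the published rule table (ids 1-8); the remaining sixteen receive
ids 9-24 in lexicographic order of their base-per-code layout.  The rule
in use is part of the shared secret (a 1/24 factor in the cracking
model), so bundles record its id.

The default rule maps A=00, C=01, G=10, T=11 — rule 2 of the table, and
the mapping hard-coded in the reference pseudocode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from .errors import AlphabetError, CodecError

__all__ = [
    "EncodingRule",
    "DEFAULT_RULE",
    "TABLE_RULES",
    "enumerate_rules",
    "bits_to_dna",
    "dna_to_bits",
]

BASES = "ACGT"
CODES = ("00", "01", "10", "11")

#: the eight published rules: base -> 2-bit code
_TABLE_MAPPINGS: dict[int, dict[str, str]] = {
    1: {"A": "00", "T": "11", "C": "10", "G": "01"},
    2: {"A": "00", "T": "11", "C": "01", "G": "10"},
    3: {"A": "11", "T": "00", "C": "10", "G": "01"},
    4: {"A": "11", "T": "00", "C": "01", "G": "10"},
    5: {"A": "10", "T": "01", "C": "00", "G": "11"},
    6: {"A": "01", "T": "10", "C": "00", "G": "11"},
    7: {"A": "10", "T": "01", "C": "11", "G": "00"},
    8: {"A": "01", "T": "10", "C": "11", "G": "00"},
}


def _layout(mapping: dict[str, str]) -> str:
    """Bases in code order 00,01,10,11 — a canonical 4-letter signature."""
    inv = {code: base for base, code in mapping.items()}
    return "".join(inv[c] for c in CODES)


@dataclass(frozen=True)
class EncodingRule:
    """A bijection between {A, C, G, T} and the 2-bit codes.

    Attributes
    ----------
    mapping : dict
        base -> 2-bit code.
    rule_id : int
        Canonical id in 1..24 (1..8 are the published table rows).
    """

    mapping: dict[str, str]
    rule_id: int = field(init=False)

    def __post_init__(self) -> None:
        if sorted(self.mapping) != sorted(BASES) or sorted(
            self.mapping.values()
        ) != sorted(CODES):
            raise CodecError(f"mapping {self.mapping!r} is not a base<->code bijection")
        object.__setattr__(self, "rule_id", _ID_BY_LAYOUT[_layout(self.mapping)])

    @classmethod
    def from_id(cls, rule_id: int) -> "EncodingRule":
        """Rule by canonical id (1..8 = published table rows, 9..24 the rest)."""
        try:
            return _ALL_RULES[rule_id]
        except KeyError:
            raise CodecError(f"rule id {rule_id} outside 1..24") from None

    @classmethod
    def from_layout(cls, layout: str) -> "EncodingRule":
        """Rule from a 4-base string listing the bases for codes 00,01,10,11.

        ``"ACGT"`` means A=00, C=01, G=10, T=11 (the default rule).
        """
        layout = layout.upper()
        if sorted(layout) != sorted(BASES):
            raise CodecError(
                f"layout {layout!r} must be a permutation of the four bases"
            )
        return cls({base: code for base, code in zip(layout, CODES)})

    @property
    def layout(self) -> str:
        return _layout(self.mapping)

    def base_for(self, code: str) -> str:
        return _layout(self.mapping)[int(code, 2)]


def _build_rules() -> tuple[dict[str, int], dict[int, EncodingRule]]:
    id_by_layout: dict[str, int] = {}
    for rid, mapping in _TABLE_MAPPINGS.items():
        id_by_layout[_layout(mapping)] = rid
    extra = sorted(
        "".join(p) for p in permutations(BASES) if "".join(p) not in id_by_layout
    )
    for offset, layout in enumerate(extra):
        id_by_layout[layout] = 9 + offset
    rules: dict[int, EncodingRule] = {}
    for layout, rid in id_by_layout.items():
        rule = object.__new__(EncodingRule)
        object.__setattr__(rule, "mapping", dict(zip(layout, CODES)))
        object.__setattr__(rule, "rule_id", rid)
        rules[rid] = rule
    return id_by_layout, rules


_ID_BY_LAYOUT, _ALL_RULES = _build_rules()

TABLE_RULES: dict[int, EncodingRule] = {rid: _ALL_RULES[rid] for rid in range(1, 9)}
DEFAULT_RULE: EncodingRule = _ALL_RULES[2]


def enumerate_rules() -> list[EncodingRule]:
    """All 24 encoding rules, ordered by canonical id."""
    return [_ALL_RULES[rid] for rid in sorted(_ALL_RULES)]


def bits_to_dna(bits: str, rule: EncodingRule = DEFAULT_RULE) -> str:
    """Map consecutive non-overlapping 2-bit chunks to bases, left to right.

    Raises :class:`CodecError` on odd length (a sign of missing padding
    upstream) or non-binary symbols.
    """
    if len(bits) % 2:
        raise CodecError(f"bit string length {len(bits)} is odd; pad upstream first")
    if not bits:
        return ""
    arr = np.frombuffer(bits.encode("ascii"), dtype=np.uint8) - ord("0")
    if arr.max() > 1:
        raise CodecError("bit string contains symbols other than 0/1")
    idx = (arr[0::2] << 1) | arr[1::2]
    lut = np.frombuffer(rule.layout.encode("ascii"), dtype=np.uint8)
    return lut[idx].tobytes().decode("ascii")


def dna_to_bits(dna: str, rule: EncodingRule = DEFAULT_RULE) -> str:
    """Exact inverse of :func:`bits_to_dna` under the same rule."""
    if set(dna) - set(BASES):
        raise AlphabetError(
            f"sequence contains symbols outside ACGT: {sorted(set(dna) - set(BASES))}"
        )
    return dna.translate(str.maketrans(rule.mapping))
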
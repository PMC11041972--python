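"""Security and capacity evaluation mathematics.

Implements the published evaluation model around the hiding scheme:

* cracking probability — the chance that an attacker simultaneously
  guesses the reference sequence (1 of ~1.63e8 public sequences), the
  binary coding rule (1 of 24), the message size (1/(n-1) for a fake
  DNA of length proxy n), both segmentations (1/(2^m - 1) image
  segments, 1/(2^s - 1) DNA segments), and the cipher key
  (1/2^feistel_bits).  Computed as an exact rational.
* the corresponding printed formulas for five competing schemes, as
  pure formula evaluators for comparison.
* BPN (bits per nucleotide) — secret image bits carried per base of the
  stego sequence; theoretical maximum 2 (every base carries 2 bits),
  strictly below 2 whenever ambiguity/padding overhead or a cover is
  present.
* a key-sensitivity scan: flip single key bits at decryption time and
  measure the failure-to-recover rate per key.
* the XOR consistency report for chosen-plaintext analysis, and a
  plain 0/1 bitstream export compatible with the NIST statistical test
  suite input format (running the suite is out of scope).
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

from . import feistel
from .bitimage import GrayscaleImage
from .dna_codec import DEFAULT_RULE, EncodingRule, dna_to_bits
from .errors import BlockError, DnaStegoError
from .keys import DSK_BITS, EK_BITS, FPK_BITS, FSK_BITS, KeyMaterial
from .stego import extract_image, hide_image

__all__ = [
    "DEFAULT_REFERENCE_POOL",
    "CrackModelParams",
    "cracking_probability",
    "BASELINE_METHODS",
    "baseline_crack_formulas",
    "CapacityReport",
    "bpn",
    "KeySensitivityReport",
    "key_sensitivity_scan",
    "BlockXorRecord",
    "xor_consistency_check",
    "export_bitstream",
]

#: number of publicly available reference DNA sequences (1.63 * 10^8)
DEFAULT_REFERENCE_POOL = 163_000_000


@dataclass(frozen=True)
class CrackModelParams:
    """Symbols of the cracking-probability model.

    Parameters
    ----------
    n : int
        Fake-DNA length proxy in the 1/(n-1) message-size factor; >= 2.
    m : int
        Secret-image segment count, the 1/(2^m - 1) factor; >= 1.
    s : int
        DNA-segment count, the 1/(2^s - 1) factor; >= 1.
    pool : int
        Public reference-sequence pool size (default 163 million).
    rules : int
        Number of binary coding rules (default 24).
    feistel_bits : int
        Cipher key bits for the 1/2^feistel_bits guess factor
        (default 32, the EK width).
    """

    n: int
    m: int = 1
    s: int = 1
    pool: int = DEFAULT_REFERENCE_POOL
    rules: int = 24
    feistel_bits: int = EK_BITS

    def __post_init__(self) -> None:
        if self.n < 2:
            raise DnaStegoError(f"n must be >= 2, got {self.n}")
        if self.m < 1 or self.s < 1:
            raise DnaStegoError("m and s must be >= 1")
        if self.pool < 1 or self.rules < 1 or self.feistel_bits < 0:
            raise DnaStegoError("pool/rules must be positive, feistel_bits >= 0")


def cracking_probability(p: CrackModelParams) -> Fraction:
    """Exact success probability of a simultaneous guess of all secrets.

    Strictly decreasing in n, m, s and feistel_bits.
    """
    return Fraction(
        1,
        p.pool
        * p.rules
        * (p.n - 1)
        * ((1 << p.m) - 1)
        * ((1 << p.s) - 1)
        * (1 << p.feistel_bits),
    )


def _baseline_two_key_division(pool: int, n: int, m: int, s: int) -> Fraction:
    # two-key XOR/division scheme: linear (2m-1), (2s-1) and 2^8 * m factors
    return Fraction(1, pool * 24 * (n - 1) * (2 * m - 1) * (2 * s - 1) * (256 * m))


def _baseline_amino_acid(pool: int) -> Fraction:
    # amino-acid / lsbase scheme: 16! coding tables, 4 bases, 4^64 key block
    return Fraction(1, pool * math.factorial(16) * 4 * 4**64)


def _baseline_quadratic_residue(pool: int, n: int) -> Fraction:
    # quadratic-residue generator scheme
    return Fraction(1, pool * n**3 * 64)


def _baseline_playfair_grid(pool: int) -> Fraction:
    # shuffled Playfair grid substitution scheme
    return Fraction(1, pool * 24 * 16)


def _baseline_ccnot_complement(pool: int, m: int) -> Fraction:
    # controlled-controlled-not / complement-rule scheme
    return Fraction(1, pool * 62 * (63 * 64) * (1 << m))


#: baseline name -> (evaluator, required free symbols)
BASELINE_METHODS = {
    "two_key_division": (_baseline_two_key_division, ("n", "m", "s")),
    "amino_acid_lsbase": (_baseline_amino_acid, ()),
    "quadratic_residue": (_baseline_quadratic_residue, ("n",)),
    "playfair_grid": (_baseline_playfair_grid, ()),
    "ccnot_complement": (_baseline_ccnot_complement, ("m",)),
}


def baseline_crack_formulas(
    method: str, pool: int = DEFAULT_REFERENCE_POOL, **params: int
) -> Fraction:
    """Evaluate a competing scheme's printed cracking formula exactly.

    ``method`` is one of :data:`BASELINE_METHODS`; ``params`` supplies
    that row's free symbols (``n``, ``m``, ``s`` as applicable).
    """
    try:
        fn, symbols = BASELINE_METHODS[method]
    except KeyError:
        raise DnaStegoError(
            f"unknown method {method!r}; expected one of {sorted(BASELINE_METHODS)}"
        ) from None
    missing = [s for s in symbols if s not in params]
    if missing:
        raise DnaStegoError(f"method {method!r} needs parameters {missing}")
    extra = set(params) - set(symbols)
    if extra:
        raise DnaStegoError(f"method {method!r} does not take {sorted(extra)}")
    return fn(pool, **{s: params[s] for s in symbols})


@dataclass(frozen=True)
class CapacityReport:
    """Hiding capacity of one embedding."""

    secret_bits: int
    stego_len: int
    bpn: float


def bpn(secret_bits: int, stego_len: int) -> CapacityReport:
    """Bits per nucleotide: secret image bits / stego sequence length.

    ``secret_bits`` counts payload bits only (no ambiguity or padding
    overhead), so the value is at most 2 and strictly below 2 whenever
    any overhead base is present.
    """
    if stego_len <= 0:
        raise DnaStegoError(f"stego length must be positive, got {stego_len}")
    if secret_bits < 0:
        raise DnaStegoError("secret bit count must be non-negative")
    return CapacityReport(secret_bits, stego_len, secret_bits / stego_len)


_KEY_WIDTHS = {"EK": EK_BITS, "FPK": FPK_BITS, "DSK": DSK_BITS, "FSK": FSK_BITS}


@dataclass
class KeySensitivityReport:
    """Per-key failure-to-recover rates of single-bit flips at decryption."""

    trials: dict[str, int] = field(default_factory=dict)
    failures: dict[str, int] = field(default_factory=dict)

    def rate(self, key: str) -> float:
        if self.trials.get(key, 0) == 0:
            return float("nan")
        return self.failures[key] / self.trials[key]

    @property
    def rates(self) -> dict[str, float]:
        return {k: self.rate(k) for k in self.trials}


def key_sensitivity_scan(
    image: GrayscaleImage,
    cover: str,
    keys: KeyMaterial,
    n_trials: int,
    seed: int,
    rule: EncodingRule = DEFAULT_RULE,
    flip_keys: tuple[str, ...] = ("EK", "FPK", "DSK", "FSK"),
    hide_seed: int = 0,
) -> KeySensitivityReport:
    """Hide once, then try recovery under single-bit key perturbations.

    Each trial picks one key uniformly from ``flip_keys`` and one of its
    bits uniformly, flips that bit in the decryption bundle only, and
    attempts extraction.  A trial fails when extraction raises or the
    recovered image differs from the original.  The unmodified bundle is
    verified to recover the image exactly (the control arm).

    Structural keys (FPK/DSK/FSK) are expected to fail in essentially
    every trial — a misaligned layout scrambles the payload.  An EK bit
    flip is a no-op on blocks whose corresponding right-half bit is 0,
    so the EK rate is reported empirically rather than asserted.
    """
    stego, bundle = hide_image(cover, image, keys, rule, seed=hide_seed)
    if extract_image(stego, bundle) != image:
        raise DnaStegoError("control extraction failed; inconsistent inputs")
    rng = random.Random(seed)
    report = KeySensitivityReport(
        trials={k: 0 for k in flip_keys}, failures={k: 0 for k in flip_keys}
    )
    for _ in range(n_trials):
        key = rng.choice(list(flip_keys))
        bit = rng.randrange(_KEY_WIDTHS[key])
        report.trials[key] += 1
        try:
            # a flipped key can already make the bundle internally
            # inconsistent (e.g. payload_len no longer divisible by FSK);
            # that is a failed recovery too
            flipped = replace(
                bundle, **{key.lower(): getattr(bundle, key.lower()) ^ (1 << bit)}
            )
            recovered = extract_image(stego, flipped)
            ok = recovered == image
        except DnaStegoError:
            ok = False
        if not ok:
            report.failures[key] += 1
    return report


@dataclass(frozen=True)
class BlockXorRecord:
    """XOR comparison of one 64-bit plaintext/ciphertext block pair."""

    p_xor: str
    c_xor: str
    equal: bool


def xor_consistency_check(
    p1: str, p2: str, ek: int | str
) -> list[BlockXorRecord]:
    """Per-block report of P1^P2 versus C1^C2 under the same key.

    No pass/fail semantics are imposed: the caller inspects whether the
    plaintext and ciphertext differences coincide block by block (for
    this cipher they do exactly when the key masks no differing
    right-half bit).
    """
    if len(p1) != len(p2):
        raise BlockError(f"length mismatch: {len(p1)} vs {len(p2)}")
    if len(p1) % feistel.BLOCK_BITS:
        raise BlockError("inputs must be a multiple of 64 bits")
    c1, _ = feistel.encrypt(p1, ek)
    c2, _ = feistel.encrypt(p2, ek)
    records = []
    for i in range(0, len(p1), feistel.BLOCK_BITS):
        j = i + feistel.BLOCK_BITS
        p_xor = format(int(p1[i:j], 2) ^ int(p2[i:j], 2), "064b")
        c_xor = format(int(c1[i:j], 2) ^ int(c2[i:j], 2), "064b")
        records.append(BlockXorRecord(p_xor, c_xor, p_xor == c_xor))
    return records


def export_bitstream(
    data: str, path: str | Path, rule: EncodingRule = DEFAULT_RULE
) -> None:
    """Write an ASCII '0'/'1' stream suitable as NIST STS input.

    ``data`` may be a bit string (written verbatim) or a DNA sequence
    (decoded through ``rule`` first).  No newlines are emitted.
    """
    if data and not set(data) - {"0", "1"}:
        bits = data
    else:
        bits = dna_to_bits(data, rule)
    Path(path).write_text(bits)
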
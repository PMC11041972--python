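# Methods

## The scheme

`dnastego` implements an insertion-family DNA steganography scheme for
8-bit grayscale images (the motivating use case is fingerprint scans,
whose compromise — unlike a password's — is irreversible). The sender
and receiver share four secret keys and a small bundle of
reconstruction metadata; the transmitted object is a single DNA
sequence that is superficially indistinguishable from an ordinary
genomic record.

Hiding proceeds in six stages, each exactly invertible:

1. **Image → bits.** Pixels are serialized row-major, 8 bits per pixel,
   most-significant bit first. Dimensions are not embedded in the
   stream; they travel in the bundle.
2. **Feistel encryption.** The bit stream is zero-padded at the end to
   a 64-bit block boundary (`padding_size` recorded) and each block
   `LT‖RT` maps to `RT‖((RT AND EK) XOR LT)` under the 32-bit key EK —
   one round, with bitwise AND as the round function. Decryption
   recomputes the mask from the transmitted right half and strips the
   padding from the end.
3. **Bits → bases.** Non-overlapping 2-bit chunks map to bases under
   one of the 4! = 24 bijections between {A,C,G,T} and {00,01,10,11}.
   Eight canonical rules carry ids 1–8 (id 2, A=00/C=01/G=10/T=11, is
   the default); the other sixteen get ids 9–24 in lexicographic order
   of their base-per-code layout. The rule id is part of the secret.
4. **Ambiguity bases.** ⌊len/10⌋ decoy bases are inserted at secret
   random positions to raise the noise floor for an attacker. The
   final absolute positions are recorded in the bundle (together with
   the PRNG seed, so hiding is reproducible); deleting them in
   descending order recovers the payload exactly.
5. **Segment padding.** The payload is extended with `A` bases (a
   valid-alphabet pad, stripped from the end by count) to a multiple
   of FSK.
6. **Keyed insertion.** Starting at offset FPK in the cover, payload
   segments of FSK bases alternate with untouched runs of DSK cover
   bases. The stego length is exactly cover + payload, and deleting
   the payload positions restores the cover byte-for-byte.

Extraction inverts the stages in reverse order. All positions in this
package are 0-based.

## Keys and parameters

| key | width | role | constraint |
|-----|-------|------|-----------|
| EK  | 32 bits | Feistel round mask | any value |
| FPK | 32 bits | first insertion offset (bases) | ≤ cover length, validated at hide time — never silently reduced |
| DSK | 8 bits  | cover bases between segments | ≥ 1 (0 would expose the payload as one contiguous run) |
| FSK | 8 bits  | payload bases per segment | ≥ 1 (0 hides nothing) |

The published key-space count, 2³² · 2⁸ · 2⁸ · 2³² = 2⁸⁰, treats
DSK/FSK as full 8-bit values; the generator here excludes 0 for both,
a documented discrepancy of 2 values in 256 per key. `key_space` is
computed in exact integer arithmetic.

The cover must satisfy `cover_len − FPK ≥ DSK · (segments − 1)`;
anything shorter raises a capacity error before any data is written.

## Evaluation mathematics

**Cracking probability** models an attacker who must simultaneously
guess the reference sequence (1 of ~1.63·10⁸ public records), the
coding rule (1/24), the message size (1/(n−1), n a fake-DNA length
proxy), the image segmentation (1/(2^m−1)), the DNA segmentation
(1/(2^s−1)) and the cipher key. The published form of the cipher
factor is typographically corrupted; it is canonicalized here as
1/2^`feistel_bits` with a default of 32 (the EK width), the only
reading under which the probability shrinks with key bits. All values
are exact `Fraction`s; the model is strictly decreasing in n, m, s and
`feistel_bits`. The printed formulas of five competing schemes are
provided as pure evaluators for comparison; the comparative claim
(this scheme's probability is smallest) holds at realistic segment
counts, where the 2^m−1 and 2^s−1 factors dominate, and is tested
there rather than at degenerate m = s = 1.

**BPN (bits per nucleotide)** is secret image bits divided by stego
length. The numerator excludes ambiguity and padding overhead, so
BPN ≤ 2 always, with equality only in the degenerate no-cover,
no-overhead case. At full scale (640×480 image, covers of the eight
published genomic lengths, ~150–218 kb) the pipeline lands at
BPN ≈ 1.57–1.64 — inside the published 1.30–1.76 band. Per-accession
published values depend on that study's random keys and are not
reproduction targets.

**Key sensitivity** is measured empirically: hide once, flip one
uniformly chosen bit of one key in the decryption bundle only, attempt
extraction, and count failures (an exception or any pixel difference).
Structural keys (FPK/DSK/FSK) fail in every observed trial — a
misaligned layout scrambles the payload, and some flips make the
bundle outright inconsistent (e.g. payload length no longer divisible
by FSK), which also counts as failure. An EK bit flip is a no-op on
blocks whose corresponding right-half bit is 0, so a universal
failure guarantee is impossible in principle; empirically, with
thousands of blocks per image, some block always exposes the flip and
the observed EK rate is also 1.0. The EK rate is reported, never
asserted.

**Chosen-plaintext XOR report.** For two plaintexts under one key the
per-block XOR of plaintexts and of ciphertexts is reported without a
verdict: for this cipher the two coincide exactly on blocks where the
key masks no differing right-half bit (with EK = 0 the ciphertext
difference is the half-swapped plaintext difference).

**NIST export** writes the plain `0`/`1` ASCII stream the NIST
statistical test suite consumes (DNA is decoded through the rule
first); running the suite itself is out of scope.

## Synthetic inputs

`fixtures.random_cover` draws i.i.d. bases with a configurable GC
fraction — adequate as a cover because the scheme is purely positional
and never conditions on cover content. It does not emulate repeats,
isochores or coding structure, so passing tests say nothing about
*statistical* detectability of the stego sequence against a real
genomic background (detectability is governed by the insertion layout,
which is identical for real and synthetic covers).
`fixtures.synthetic_fingerprint` renders oriented sinusoidal ridges
(period ≈ 9 px, smoothly drifting orientation) plus Gaussian noise —
the right texture class and entropy for a secret image, without
minutiae or cores; since the pipeline is content-agnostic and lossless,
image realism only affects realism of the payload statistics, not
correctness. Real FASTA covers and PGM/PNG scans drop in unchanged.

## Numerical and design choices

- **Pseudocode contradictions.** The reference pseudocode appends
  Feistel padding at the end but strips it from the front, and its
  hide/extract strides are mutually inconsistent. In both cases the
  encoder's side was taken and the decoder defined as its exact
  inverse; round-trip identity against an independent character-by-
  character splicing oracle is the arbiter, and both readings are
  regression-tested.
- **Ambiguity placement** draws the m decoy positions uniformly
  without replacement over the expanded coordinate space — the same
  distribution as inserting one base at a time at a uniform offset of
  the current sequence, but O(n) at full scale. Positions are stored
  explicitly (the decoder indexes them directly) *and* the seed is
  stored (so the encoder is reproducible); no further secret-sharing
  semantics are assumed.
- **Strictness over repair.** Out-of-range FPK, zero DSK/FSK,
  non-ACGT symbols under the strict FASTA policy, color images,
  unknown or missing bundle fields, and inconsistent binary echoes all
  raise; nothing is silently clamped, converted or dropped.
- **Problem sizes.** The test suite and the acceptance script use
  100 random triples at 32–64 px images and 50–200 kb covers for the
  round-trip law, 10⁴ blocks for the cipher structure, 500 instances
  ≤ 1 kb for oracle equivalence, 100/160 trials for key sensitivity,
  and the eight published cover lengths at 640×480 for capacity —
  sizes at which every law is exercised at or above its operating
  scale while the whole suite runs in seconds.

## Limitations

- One Feistel round with an AND round function is structurally weak:
  the right half of every block is transmitted in the clear (a tested
  property of the construction, not a defect of the implementation).
  The package asserts exactly this structure and makes no
  confidentiality claims beyond it.
- Only 8-bit grayscale images; color and high-bit-depth inputs are
  rejected by design. Video/audio/large payloads are out of scope.
- Wet-lab synthesis constraints (GC content, homopolymer runs) are
  ignored; the stego sequence is a text artifact.
- Substitution and complementary-pair hiding families are
  characterized only through their printed cracking/BPN formulas, not
  reimplemented.
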
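# dnastego

Hide an 8-bit grayscale image inside a DNA sequence — and get it back,
bit for bit.

Biometric images such as fingerprints cannot be revoked once leaked,
which motivates hiding them rather than merely encrypting them.
`dnastego` implements an insertion-style DNA steganography scheme: the
secret image is serialized to bits, encrypted with a single-round
64-bit-block Feistel cipher (32-bit key EK, round function
`AE = RT ‖ ((RT ∧ EK) ⊕ LT)`), encoded to bases under one of the
4! = 24 two-bit coding rules, expanded with ⌊n/10⌋ random decoy
("ambiguity") bases, and woven into a real or synthetic cover sequence
as FSK-base segments separated by DSK untouched cover bases, starting
at offset FPK. Four secret keys (EK, FPK, DSK, FSK — key space
2³²·2⁸·2⁸·2³² = 2⁸⁰) plus a JSON metadata bundle make the extraction
exact; deleting the payload positions restores the cover
byte-for-byte.

The package also implements the scheme's evaluation mathematics:
exact-rational cracking probability
(1/1.63·10⁸ · 1/24 · 1/(n−1) · 1/(2^m−1) · 1/(2^s−1) · 1/2³²) with the
printed formulas of five competing schemes, bits-per-nucleotide (BPN)
capacity with its upper bound of 2, an empirical single-bit
key-sensitivity scan, a chosen-plaintext XOR consistency report, and
NIST-STS-compatible bitstream export. See `docs/methods.md` for the
full model and design choices.

## Worked example

```sh
dnastego fixtures cover --length 30000 --seed 2 --out cover.fasta
dnastego fixtures fingerprint --size 24x24 --seed 1 --out secret.pgm
dnastego keygen --seed 5 --max-fpk 4000 --out keys.json
dnastego hide --cover cover.fasta --image secret.pgm --keys keys.json \
              --out stego.fasta --seed 9
dnastego extract --stego stego.fasta --keys keys.json --out recovered.pgm
```

prints

```
wrote 30000-base cover to cover.fasta
wrote 24x24 image to secret.pgm
wrote keys to keys.json
  EK   1001111101110110 0111110001000101
  FPK  0000000000000000 0000010000010110
  DSK  10111101
  FSK  01011011
hid 24x24 image in synthetic_cover (30000 -> 32548 bases); bundle -> keys.json
recovered 24x24 image -> recovered.pgm
```

The 24×24 image is 4608 bits → 2304 payload bases; with 230 ambiguity
bases and 14 pad bases the stego sequence grows by exactly the
2548-base payload, and `recovered.pgm` is byte-identical to
`secret.pgm`. `hide` writes the reconstruction metadata (padding
sizes, ambiguity positions, payload length, image size) back into
`keys.json`, so the same file drives both directions. Real inputs work
the same way: any single-record ACGT FASTA as `--cover`, any 8-bit
grayscale PGM/PNG as `--image`.

The same pipeline from Python:

```python
import dnastego as ds

cover = ds.random_cover(30_000, seed=2).sequence
image = ds.synthetic_fingerprint(24, 24, seed=1)
keys = ds.generate_keys(5, max_fpk=4_000)
stego, bundle = ds.hide_image(cover, image, keys, seed=9)
assert ds.extract_image(stego, bundle) == image
assert ds.recover_cover(stego, bundle) == cover
print(ds.bpn(8 * 24 * 24, len(stego)).bpn)   # 0.1416 — short cover dominates
```

Evaluation one-liners:

```sh
dnastego eval crack --n 2 --m 1 --s 1 --feistel-bits 1
# cracking probability = 1/7824000000 ~= 1.278119e-10
dnastego eval keysense --trials 100 --seed 0
dnastego export-bits --in stego.fasta --out stego_bits.txt
```

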
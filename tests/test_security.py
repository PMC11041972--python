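"""Evaluation mathematics: cracking model, capacity, sensitivity, exports."""

from fractions import Fraction

import pytest

from dnastego import generate_keys, random_cover, synthetic_fingerprint
from dnastego.errors import DnaStegoError
from dnastego.security import (
    DEFAULT_REFERENCE_POOL,
    CrackModelParams,
    baseline_crack_formulas,
    bpn,
    cracking_probability,
    export_bitstream,
    key_sensitivity_scan,
    xor_consistency_check,
)
from dnastego.stego import hide_image


class TestCrackingProbability:
    def test_exact_rational_example(self):
        p = CrackModelParams(n=2, m=1, s=1, feistel_bits=1)
        assert cracking_probability(p) == Fraction(1, 7_824_000_000)

    def test_all_unity_factors(self):
        p = CrackModelParams(n=2, m=1, s=1, pool=1, rules=1, feistel_bits=0)
        assert cracking_probability(p) == 1

    def test_reference_pool_is_163_million(self):
        assert DEFAULT_REFERENCE_POOL == 163_000_000
        assert CrackModelParams(n=2).pool == 163_000_000
        p = CrackModelParams(n=2, m=1, s=1, rules=1, feistel_bits=0)
        assert cracking_probability(p) == Fraction(1, 163_000_000)

    def test_float_view_agrees_to_12_digits(self):
        p = CrackModelParams(n=1000, m=7, s=9)
        exact = cracking_probability(p)
        assert float(exact) == pytest.approx(
            1
            / (163e6 * 24 * 999 * (2**7 - 1) * (2**9 - 1) * 2**32),
            rel=1e-12,
        )

    @pytest.mark.parametrize("param", ["n", "m", "s", "feistel_bits"])
    def test_strictly_decreasing_in_each_parameter(self, param):
        base = dict(n=10, m=4, s=4, feistel_bits=8)
        lo = cracking_probability(CrackModelParams(**base))
        base[param] += 1
        hi = cracking_probability(CrackModelParams(**base))
        assert hi < lo

    def test_doubling_feistel_bits_at_least_halves(self):
        a = cracking_probability(CrackModelParams(n=5, feistel_bits=4))
        b = cracking_probability(CrackModelParams(n=5, feistel_bits=8))
        assert b <= a / 2

    def test_domain_error(self):
        with pytest.raises(DnaStegoError):
            CrackModelParams(n=1)


class TestBaselineFormulas:
    def test_playfair_grid_row(self):
        assert baseline_crack_formulas("playfair_grid") == Fraction(
            1, 163_000_000 * 24 * 16
        )

    def test_all_rows_positive(self):
        values = {
            "two_key_division": baseline_crack_formulas(
                "two_key_division", n=2, m=1, s=1
            ),
            "amino_acid_lsbase": baseline_crack_formulas("amino_acid_lsbase"),
            "quadratic_residue": baseline_crack_formulas("quadratic_residue", n=1),
            "playfair_grid": baseline_crack_formulas("playfair_grid"),
            "ccnot_complement": baseline_crack_formulas("ccnot_complement", m=1),
        }
        assert all(0 < v < 1 for v in values.values())

    def test_proposed_is_smallest_at_realistic_segment_counts(self):
        # segment counts as a real embedding produces (hundreds+), where
        # the 2^m - 1 and 2^s - 1 factors dominate every competing row
        n, m, s = 200_000, 1000, 1000
        proposed = cracking_probability(CrackModelParams(n=n, m=m, s=s))
        for method, symbols in (
            ("two_key_division", dict(n=n, m=m, s=s)),
            ("amino_acid_lsbase", {}),
            ("quadratic_residue", dict(n=n)),
            ("playfair_grid", {}),
            ("ccnot_complement", dict(m=m)),
        ):
            assert proposed <= baseline_crack_formulas(method, **symbols)

    def test_unknown_method_and_missing_params(self):
        with pytest.raises(DnaStegoError):
            baseline_crack_formulas("nonexistent")
        with pytest.raises(DnaStegoError):
            baseline_crack_formulas("quadratic_residue")
        with pytest.raises(DnaStegoError):
            baseline_crack_formulas("playfair_grid", n=3)


class TestBpn:
    def test_upper_bound_case(self):
        assert bpn(200, 100).bpn == 2.0

    def test_zero_secret(self):
        assert bpn(0, 100).bpn == 0.0

    def test_zero_length_rejected(self):
        with pytest.raises(DnaStegoError):
            bpn(10, 0)

    def test_pipeline_bpn_bookkeeping(self, small_image, small_cover, small_keys):
        stego, bundle = hide_image(small_cover, small_image, small_keys, seed=3)
        secret_bits = 8 * small_image.width * small_image.height
        report = bpn(secret_bits, len(stego))
        assert report.bpn == secret_bits / (len(small_cover) + bundle.payload_len)
        # ambiguity/padding overhead makes the bound strict
        assert report.bpn < 2.0


class TestKeySensitivity:
    def test_structural_flips_always_fail_and_control_succeeds(self):
        image = synthetic_fingerprint(16, 16, seed=1)
        cover = random_cover(30_000, seed=2).sequence
        keys = generate_keys(3, max_fpk=5_000)
        report = key_sensitivity_scan(
            image, cover, keys, n_trials=30, seed=4, flip_keys=("FPK", "DSK", "FSK")
        )
        assert sum(report.trials.values()) == 30
        for key in ("FPK", "DSK", "FSK"):
            assert report.failures[key] == report.trials[key]

    def test_ek_rate_is_reported_not_asserted(self):
        image = synthetic_fingerprint(16, 16, seed=1)
        cover = random_cover(30_000, seed=2).sequence
        keys = generate_keys(3, max_fpk=5_000)
        report = key_sensitivity_scan(
            image, cover, keys, n_trials=20, seed=4, flip_keys=("EK",)
        )
        assert 0.0 <= report.rate("EK") <= 1.0


class TestXorConsistency:
    def test_equal_plaintexts_give_zero_xors(self):
        records = xor_consistency_check("01" * 32, "01" * 32, ek=12345)
        assert len(records) == 1
        assert records[0].p_xor == "0" * 64
        assert records[0].c_xor == "0" * 64
        assert records[0].equal

    def test_zero_key_round_is_half_swap_linear(self, rng):
        p1 = "".join(rng.choice("01") for _ in range(128))
        p2 = "".join(rng.choice("01") for _ in range(128))
        for rec in xor_consistency_check(p1, p2, ek=0):
            # with EK=0 the round is L||R -> R||L, so the ciphertext
            # difference is the half-swapped plaintext difference
            assert rec.c_xor == rec.p_xor[32:] + rec.p_xor[:32]

    def test_one_record_per_block(self, rng):
        p1 = "".join(rng.choice("01") for _ in range(320))
        p2 = "".join(rng.choice("01") for _ in range(320))
        records = xor_consistency_check(p1, p2, ek=rng.getrandbits(32))
        assert len(records) == 5

    def test_length_mismatch_rejected(self):
        with pytest.raises(DnaStegoError):
            xor_consistency_check("0" * 64, "0" * 128, ek=0)


class TestBitstreamExport:
    def test_dna_decoded_through_rule(self, tmp_path):
        path = tmp_path / "bits.txt"
        export_bitstream("AGCT", path)
        assert path.read_text() == "00100111"

    def test_empty_input(self, tmp_path):
        path = tmp_path / "bits.txt"
        export_bitstream("", path)
        assert path.read_text() == ""

    def test_bit_input_verbatim_and_length(self, tmp_path, rng):
        path = tmp_path / "bits.txt"
        bits = "".join(rng.choice("01") for _ in range(100))
        export_bitstream(bits, path)
        assert path.read_text() == bits
        dna = "".join(rng.choice("ACGT") for _ in range(50))
        export_bitstream(dna, path)
        assert len(path.read_text()) == 100
        assert "\n" not in path.read_text()
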
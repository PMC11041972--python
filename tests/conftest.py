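import random

import pytest

from dnastego import generate_keys, random_cover, synthetic_fingerprint


@pytest.fixture
def rng():
    return random.Random(20240319)


@pytest.fixture
def small_image():
    return synthetic_fingerprint(16, 16, seed=7)


@pytest.fixture
def small_cover():
    return random_cover(20_000, seed=11).sequence


@pytest.fixture
def small_keys(small_cover):
    return generate_keys(13, max_fpk=len(small_cover) // 4)
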
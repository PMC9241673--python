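import random

import pytest


@pytest.fixture
def rng():
    """A deterministically seeded stdlib RNG for test-local sampling."""
    return random.Random(0xC0FFEE)


def random_dna(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(alphabet) for _ in range(length))
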
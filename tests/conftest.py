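import random

import pytest

from casmap import Reference


def random_reference(rng: random.Random, length: int, alphabet: str = "ACGT") -> Reference:
    return Reference(
        name=f"rnd{length}",
        sequence="".join(rng.choice(alphabet) for _ in range(length)),
        alphabet=alphabet,
    )


@pytest.fixture
def rng() -> random.Random:
    return random.Random(1234)
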
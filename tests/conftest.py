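import numpy as np
import pytest

from pmulti.codebook import (
    Codebook,
    assign_codewords,
    generate_constant_weight_code,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_book():
    """6-bit weight-3 distance-4 codebook: 2 coding, 2 blank codewords."""
    book = generate_constant_weight_code(6, 3, 4, 4)
    return assign_codewords(["geneA", "geneB"], book, seed=1)


@pytest.fixture
def toy_pair_book():
    """Two weight-2 codewords at distance 4 for hand-checkable decoding."""
    return Codebook(
        n_bits=6,
        weight=2,
        min_distance=4,
        names=["A", "B"],
        bits=np.array([[1, 1, 0, 0, 0, 0], [0, 0, 1, 1, 0, 0]], dtype=np.uint8),
    )


@pytest.fixture(scope="session")
def barcode_book():
    """18-bit weight-6 distance-4 book with 456 coding codewords assigned."""
    book = generate_constant_weight_code(18, 6, 4, 456)
    targets = [f"bc_{i:03d}" for i in range(456)]
    return assign_codewords(targets, book, seed=0)
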
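import numpy as np
import pytest

from varfuse._tensor import get_default_dtype, set_default_dtype
from varfuse.synthetic import DimSpec, gen_variant_dataset
from varfuse.tokenizer import Tokenizer


@pytest.fixture
def float64_mode():
    """High-precision mode for finite-difference gradient checks."""
    prev = get_default_dtype()
    set_default_dtype(np.float64)
    yield
    set_default_dtype(prev)


@pytest.fixture(scope="session")
def dims():
    return DimSpec()

@pytest.fixture(scope="session")
def small_items(dims):
    return gen_variant_dataset(48, seed=7, dims=dims)


@pytest.fixture(scope="session")
def tokenizer(small_items):
    return Tokenizer.from_corpus([it.caption for it in small_items])
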
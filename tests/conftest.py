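import random

import pytest
from hypothesis import HealthCheck, settings

from bialignment import ScoringConfig, SubstitutionTable, read_matrix

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def blosum62():
    return read_matrix()


@pytest.fixture(scope="session")
def default_cfg(blosum62):
    """The demonstration parameter set on the packaged BLOSUM62."""
    return ScoringConfig(substitution=blosum62)


@pytest.fixture
def toy_table():
    return SubstitutionTable.match_mismatch("AB", match=3, mismatch=-2)


def random_instance(rng: random.Random, max_len: int = 3):
    """A random tiny bi-alignment instance over 2-letter alphabets."""
    n1 = rng.randint(0, max_len)
    n2 = rng.randint(0, max_len)
    seq_a = "".join(rng.choice("AB") for _ in range(n1))
    seq_b = "".join(rng.choice("AB") for _ in range(n2))
    str_a = "".join(rng.choice("HC") for _ in range(n1))
    str_b = "".join(rng.choice("HC") for _ in range(n2))
    return seq_a, seq_b, str_a, str_b


def random_params(rng: random.Random, mode: str = "affine_both", **over):
    """Random small-integer scoring parameters on the {A,B} alphabet."""
    kwargs = dict(
        substitution=SubstitutionTable.match_mismatch(
            "AB", match=rng.randint(1, 8), mismatch=rng.randint(-4, 2)
        ),
        structure_match=rng.randint(0, 8),
        structure_mismatch=rng.randint(-4, 0),
        gap_open=rng.randint(-6, 0),
        gap_extend=rng.randint(-4, 0),
        shift_extend=rng.randint(-5, 0),
        shift_open=rng.randint(-6, 0),
        lambda_max=None,
        mode=mode,
    )
    kwargs.update(over)
    return ScoringConfig(**kwargs)
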
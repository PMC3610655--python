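from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitution noise at the given per-base rate."""
    if rate <= 0:
        return seq
    out = list(seq)
    n_mut = rng.binomial(len(seq), rate)
    for pos in rng.choice(len(seq), size=n_mut, replace=False):
        alts = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alts[int(rng.integers(3))]
    return "".join(out)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_clean_fixture():
    """One small clean three-assembly fixture shared by fast tests."""
    from asmblend.fixtures import standard_fixture

    return standard_fixture(seed=5, genome_len=20000, mean_len=4000)
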
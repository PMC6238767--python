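import numpy as np
import pytest

from fractalsad import RankAbundance


def make_random_sad(rng: np.random.Generator, *, max_S: int = 200, sigma: float = 0.5) -> RankAbundance:
    """A noisy power-law community: r**(-p) times log-normal noise, re-ranked.

    Used wherever a test needs "realistic" rank-abundance input whose true
    exponent is irrelevant.
    """
    S = int(rng.integers(2, max_S + 1))
    p = float(rng.uniform(0.0, 3.0))
    r = np.arange(1, S + 1, dtype=float)
    values = r ** (-p) * rng.lognormal(mean=0.0, sigma=sigma, size=S)
    return RankAbundance.from_counts(f"noisy_p{p:.3f}_S{S}", values)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20180513)


@pytest.fixture
def random_sads(rng):
    def factory(n: int, **kwargs):
        return [make_random_sad(rng, **kwargs) for _ in range(n)]

    return factory
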
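import numpy as np
import pytest

from nanomap.motifmap import ReferenceMap

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


def spaced_sites(rng: np.random.Generator, length: int, n: int,
                 minsep: int = 2500, margin: int = 4000) -> list[int]:
    """n irregular positions with a guaranteed minimum separation.

    Stick-breaking: exponential gaps rescaled to the available slack, plus the
    minimum separation. Irregular spacing keeps the label pattern distinctive,
    which regular grids are not.
    """
    slack = (length - 2 * margin) - (n - 1) * minsep
    if slack <= 0:
        raise ValueError("too many sites for the requested separation")
    gaps = rng.exponential(1.0, n + 1)
    gaps = gaps / gaps.sum() * slack
    pos = margin + gaps[0] + np.cumsum(np.concatenate([[0.0], gaps[1:n] + minsep]))
    return np.sort(pos).astype(int).tolist()


def spaced_reference(rng, length=150_000, n1=30, n2=20, map_id="ref") -> ReferenceMap:
    return ReferenceMap(
        map_id, length,
        {1: spaced_sites(rng, length, n1), 2: spaced_sites(rng, length, n2)},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
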
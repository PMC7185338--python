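import random

import pytest

from pfbwt import RollingHashPolicy, index_from_build, build, parse


def random_text(rng: random.Random, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(n))


def random_lengths(rng: random.Random, count: int, max_n: int = 5000):
    """Edge lengths first, then a log-uniform spread up to max_n."""
    fixed = [1, 2, 3, 5, 11, 17]
    out = fixed[: min(len(fixed), count)]
    while len(out) < count:
        out.append(int(round(10 ** rng.uniform(0, 3.699))))
    return [min(n, max_n) for n in out]


STANDARD_POLICIES = [
    RollingHashPolicy(2, 5),
    RollingHashPolicy(4, 11),
    RollingHashPolicy(10, 101),
    RollingHashPolicy(2, 1),
]


def index_of(text, policy=None):
    """Parse + build + r-index in one step (test convenience)."""
    policy = policy or RollingHashPolicy(4, 11)
    return index_from_build(build(parse(text, policy), mode="bwt+samples"))


@pytest.fixture
def rng():
    return random.Random(0xC0FFEE)
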
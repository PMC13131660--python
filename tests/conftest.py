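import numpy as np
import pytest

from cretrace import synth as sy
from cretrace.seqmut import ALPHABET, Sequence


def random_seq(rng: np.random.Generator, length: int, seq_id: str = "s") -> Sequence:
    return Sequence(
        id=seq_id, residues="".join(ALPHABET[i] for i in rng.integers(0, 4, length))
    )


@pytest.fixture(scope="session")
def scenario_i():
    return sy.make_scenario_i(seed=0)


@pytest.fixture(scope="session")
def scenario_ii():
    return sy.make_scenario_ii(seed=0)


@pytest.fixture(scope="session")
def surrogate():
    return sy.make_surrogate(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


class ConstantOracle:
    """Oracle returning a fixed score regardless of sequence."""

    name = "constant"

    def __init__(self, value: float = 1.0):
        self.value = value

    def score(self, seq) -> float:
        return self.value


class HitCountOracle:
    """Strictly additive toy oracle: weighted count of exact substring
    occurrences, one weight per pattern. No gate, no ceiling."""

    name = "hit-count"

    def __init__(self, patterns: dict[str, float]):
        self.patterns = patterns

    def score(self, seq) -> float:
        total = 1.0
        s = seq.residues
        for pat, w in self.patterns.items():
            count = sum(
                1 for i in range(len(s) - len(pat) + 1) if s[i:i + len(pat)] == pat
            )
            total += w * count
        return total


class PositionWeightOracle:
    """Additive oracle keyed on (position, base) of the raw sequence; used
    where per-mutation gains must be exactly independent."""

    name = "position-weight"

    def __init__(self, weights: dict[tuple[int, str], float]):
        self.weights = weights

    def score(self, seq) -> float:
        return 1.0 + sum(
            self.weights.get((i, b), 0.0) for i, b in enumerate(seq.residues)
        )
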
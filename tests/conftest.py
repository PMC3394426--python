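import itertools
import random

import numpy as np
import pytest

from abbrclust.matching import APair, CandidatePair


def all_strings(alphabet: str, max_len: int) -> list[str]:
    """Every string over ``alphabet`` with length <= max_len (incl. empty)."""
    out = [""]
    for n in range(1, max_len + 1):
        out.extend("".join(t) for t in itertools.product(alphabet, repeat=n))
    return out


def random_string(rng: random.Random, alphabet: str, max_len: int, min_len: int = 0) -> str:
    n = rng.randint(min_len, max_len)
    return "".join(rng.choice(alphabet) for _ in range(n))


def make_scored_pairs(
    rng: random.Random, n: int, *, n_distinct_scores: int | None = None
) -> list[CandidatePair]:
    """Random gold labels and scores (optionally with forced score ties)."""
    pairs = []
    for i in range(n):
        if n_distinct_scores:
            score = round(rng.randrange(n_distinct_scores) / n_distinct_scores, 6)
        else:
            score = round(rng.random(), 6)
        left = APair("AB", f"form {i} l", f"C{i}")
        right = APair("AB", f"form {i} r", f"C{i if rng.random() < 0.4 else i + 1000}")
        pairs.append(
            CandidatePair(left, right, gold=rng.random() < 0.4, score=score)
        )
    return pairs


@pytest.fixture
def pyrng() -> random.Random:
    return random.Random(20240917)


@pytest.fixture
def nprng() -> np.random.Generator:
    return np.random.default_rng(20240917)
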
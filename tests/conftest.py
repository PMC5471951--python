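"""Shared fixtures and independent (naive) oracles for the test suite."""

import numpy as np
import pytest

from acsphylo import SequenceRecord

DNA = np.array(list("ACGT"))


def random_dna(rng, lo, hi, name="s"):
    length = int(rng.integers(lo, hi + 1))
    return SequenceRecord(name, "".join(rng.choice(DNA, length)))


def naive_lcp(s: str, t: str) -> int:
    """Character-by-character exact longest common prefix."""
    n = 0
    for a, b in zip(s, t):
        if a != b:
            break
        n += 1
    return n


def naive_lcp_k(s: str, t: str, k: int) -> int:
    """Direct scan tolerating up to k mismatches; a mismatch is never
    charged at or past either string's end."""
    n = 0
    budget = k
    while n < len(s) and n < len(t):
        if s[n] != t[n]:
            if budget == 0:
                break
            budget -= 1
        n += 1
    return n


def naive_lambda_profile(x: str, y: str, k: int):
    """Brute-force lambda_k(i) = max_j naive_lcp_k(X_i, Y_j) — the slowest,
    most independent oracle (pure python scans)."""
    return [
        max(naive_lcp_k(x[i:], y[j:], k) for j in range(len(y)))
        for i in range(len(x))
    ]


@pytest.fixture(scope="session")
def pair_corpus():
    """Seeded random sequence pairs used by several estimator tests."""
    rng = np.random.default_rng(424242)
    return [
        (random_dna(rng, 20, 200, "X"), random_dna(rng, 20, 200, "Y"))
        for _ in range(40)
    ]
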
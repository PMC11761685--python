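"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import aavswap as av


def dp_levenshtein(a: str, b: str) -> int:
    """Independent dynamic-programming Levenshtein oracle (no edlib)."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


@pytest.fixture(scope="session")
def designs():
    return av.default_designs()


@pytest.fixture(scope="session")
def small_truth():
    """50 well-separated pairs shared across parsing/stats tests."""
    return av.generate_barcode_truth(50, min_pairwise_dist=5, seed=101)


@pytest.fixture(scope="session")
def small_pdict(small_truth):
    return av.PairDictionary.from_pairs(
        zip(small_truth.pairs["bc1"], small_truth.pairs["bc2"])
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
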
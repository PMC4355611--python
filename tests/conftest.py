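"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library's own code paths: diversity
statistics are recomputed by brute-force enumeration of haplotype pairs,
and the Tajima coefficient chain is evaluated in exact rational arithmetic.
"""

from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest

from popwin.matrix import HaplotypeMatrix

MISSING = 5


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def mean_pairwise_hamming(values: np.ndarray) -> float:
    """Π oracle: mean Hamming distance over all unordered column pairs."""
    n = values.shape[1]
    pairs = list(combinations(range(n), 2))
    total = sum(
        int((values[:, i] != values[:, j]).sum()) for i, j in pairs
    )
    return total / len(pairs)


def distinct_pair_fraction(values: np.ndarray) -> float:
    """Hd oracle: fraction of unordered column pairs that differ anywhere."""
    n = values.shape[1]
    pairs = list(combinations(range(n), 2))
    distinct = sum(
        int(not np.array_equal(values[:, i], values[:, j])) for i, j in pairs
    )
    return distinct / len(pairs)


def tajima_constants_exact(n: int) -> dict[str, Fraction]:
    """Exact-rational evaluation of a1..e2 for N = n haplotypes."""
    a1 = sum((Fraction(1, i) for i in range(1, n)), Fraction(0))
    a2 = sum((Fraction(1, i * i) for i in range(1, n)), Fraction(0))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d_exact(big_pi: Fraction, s: int, n: int) -> float:
    """End-to-end D oracle from exact constants (final sqrt in float)."""
    c = tajima_constants_exact(n)
    var = c["e1"] * s + c["e2"] * s * (s - 1)
    num = big_pi - Fraction(s) / c["a1"]
    return float(num) / float(var) ** 0.5


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

#: Four haplotypes ACA, ACG, TCG, TGG over three sites (as matrix columns).
TOY_VALUES = np.array(
    [[1, 1, 4, 4],
     [2, 2, 2, 3],
     [1, 3, 3, 3]], dtype=np.int8
)


@pytest.fixture
def toy_values() -> np.ndarray:
    return TOY_VALUES.copy()


@pytest.fixture
def toy_matrix() -> HaplotypeMatrix:
    return HaplotypeMatrix(
        values=TOY_VALUES.copy(),
        positions=np.array([10, 20, 30]),
        haplotype_ids=["h1", "h2", "h3", "h4"],
        populations=["ALL"] * 4,
    )


def random_matrix(rng: np.random.Generator, max_n=8, max_m=10,
                  allow_missing=False) -> np.ndarray:
    """Small random code matrix for property tests."""
    n = int(rng.integers(2, max_n + 1))
    m = int(rng.integers(1, max_m + 1))
    hi = 6 if allow_missing else 5
    return rng.integers(1, hi, size=(m, n)).astype(np.int8)
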
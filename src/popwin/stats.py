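"""Windowed population-genetic summary statistics.

All functions operate on integer-encoded site × haplotype matrices
(codes 1–4 = A,C,G,T; 5 = missing; see :mod:`popwin.matrix`) and implement
the classical single-population diversity estimators:

* ``S`` — number of segregating (polymorphic) sites,
* haplotype number and haplotype diversity ``Hd``,
* nucleotide diversity ``Π`` (per window) and ``π = Π / n`` (per bp),
* Watterson's ``θw = S / a1``,
* Tajima's ``D = (Π − θw) / sqrt(e1·S + e2·S(S−1))``.

Missing-data conventions: a site's diversity πᵢ and its segregating status
use only the non-missing alleles at that site (site-specific nᵢ); sites
with fewer than two non-missing alleles are excluded from both S and Π.
Watterson's θ and the Tajima variance constants use the full haplotype
count N.  Haplotype grouping treats the missing code as a literal fifth
symbol, so two haplotypes that differ only in where data is missing are
counted as distinct.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "HaplotypeTable",
    "TajimaConstants",
    "count_segregating_sites",
    "segregating_flags",
    "haplotype_table",
    "haplotype_diversity",
    "site_diversity",
    "site_diversities",
    "window_pi",
    "tajima_constants",
    "watterson_theta",
    "tajimas_d",
]

#: Var(Π − θw) at or below this is treated as exactly zero → D undefined.
VARIANCE_EPS = 1e-15

MISSING = 5


def _allele_counts(values: np.ndarray) -> np.ndarray:
    """Per-site counts of the four base codes, shape (M, 4). Missing excluded."""
    values = np.asarray(values)
    return np.stack([(values == c).sum(axis=1) for c in (1, 2, 3, 4)], axis=1)


def segregating_flags(values: np.ndarray) -> np.ndarray:
    """Boolean per-site vector: ≥ 2 distinct non-missing alleles present."""
    counts = _allele_counts(values)
    return (counts > 0).sum(axis=1) >= 2


def count_segregating_sites(values: np.ndarray) -> int:
    """Number of polymorphic sites in the window (missing codes ignored)."""
    return int(segregating_flags(values).sum())


@dataclass
class HaplotypeTable:
    """Distinct haplotype code-strings with their counts and frequencies."""

    haplotypes: list[str]  # digit strings over {1..5}, e.g. "1243"
    counts: np.ndarray
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.frequencies = np.asarray(self.frequencies, dtype=np.float64)
        if len(self.haplotypes) != len(self.counts):
            raise ValueError("haplotypes/counts length mismatch")
        if len(set(self.haplotypes)) != len(self.haplotypes):
            raise ValueError("haplotypes must be pairwise distinct")
        if self.counts.size and self.counts.min() < 1:
            raise ValueError("counts must be positive")
        if abs(float(self.frequencies.sum()) - 1.0) > 1e-12:
            raise ValueError("frequencies must sum to 1")

    @property
    def n_haplotypes(self) -> int:
        """Number of *distinct* haplotypes (the haplotype-number statistic)."""
        return len(self.haplotypes)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def haplotype_table(values: np.ndarray) -> HaplotypeTable:
    """Group matrix columns by exact code-string equality.

    The missing code participates as an ordinary fifth symbol.  Haplotypes
    are returned in order of first appearance (column order), which keeps
    results deterministic under identical input.
    """
    values = np.asarray(values)
    n = values.shape[1]
    seen: dict[str, int] = {}
    counts: list[int] = []
    for j in range(n):
        key = "".join(chr(48 + c) for c in values[:, j])
        if key in seen:
            counts[seen[key]] += 1
        else:
            seen[key] = len(counts)
            counts.append(1)
    counts_arr = np.asarray(counts, dtype=np.int64)
    return HaplotypeTable(
        haplotypes=list(seen.keys()),
        counts=counts_arr,
        frequencies=counts_arr / n,
    )


def haplotype_diversity(table: HaplotypeTable, n: int) -> float:
    """Hd = N/(N−1) · (1 − Σⱼ Hf[j]²); the unbiased gene-diversity estimator.

    Equals the probability that two haplotypes drawn without replacement
    from the sample are distinct.
    """
    if n < 2:
        raise ValueError("haplotype diversity is undefined for N < 2")
    if table.total != n:
        raise ValueError(f"table totals {table.total} haplotypes, N = {n} given")
    hd = n / (n - 1) * (1.0 - float(np.square(table.frequencies).sum()))
    # clip float jitter at the boundaries
    return min(max(hd, 0.0), 1.0)


def site_diversity(codes: np.ndarray) -> float:
    """Unbiased per-site nucleotide diversity πᵢ.

    πᵢ = nᵢ/(nᵢ−1) · (1 − Σₗ pₗ²) over the k non-missing alleles, where nᵢ
    is the number of non-missing entries.  Equals the mean pairwise
    difference at the site, and supports any number of alleles k.
    """
    codes = np.asarray(codes)
    kept = codes[codes != MISSING]
    n_eff = kept.size
    if n_eff < 2:
        raise ValueError(
            f"site diversity is undefined with {n_eff} non-missing allele(s)"
        )
    counts = np.bincount(kept, minlength=5)[1:5].astype(np.float64)
    sumsq = float(np.square(counts).sum())
    return (n_eff * n_eff - sumsq) / (n_eff * (n_eff - 1))


def site_diversities(values: np.ndarray) -> tuple[np.ndarray, int]:
    """Vector of πᵢ for every site, plus the count of excluded sites.

    Sites with fewer than two non-missing alleles have no estimator; they
    contribute 0 and are tallied in the second return value.
    """
    counts = _allele_counts(np.asarray(values)).astype(np.float64)
    n_eff = counts.sum(axis=1)
    sumsq = np.square(counts).sum(axis=1)
    ok = n_eff >= 2
    pi = np.zeros(len(n_eff))
    pi[ok] = (n_eff[ok] ** 2 - sumsq[ok]) / (n_eff[ok] * (n_eff[ok] - 1))
    return pi, int((~ok).sum())


def window_pi(values: np.ndarray, span_bp: int) -> tuple[float, float]:
    """(Π, π) for a window: Π = Σᵢ πᵢ over its sites, π = Π / span_bp."""
    if span_bp < 1:
        raise ValueError("window span must be ≥ 1 bp")
    pi_i, _ = site_diversities(values)
    big_pi = float(pi_i.sum())
    return big_pi, big_pi / span_bp


@dataclass(frozen=True)
class TajimaConstants:
    """The a1..e2 coefficient chain for a sample of N haplotypes (Tajima 1989)."""

    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    """Compute a1, a2, b1, b2, c1, c2, e1, e2 for N = n haplotypes.

    a1 = Σ_{i=1}^{N−1} 1/i              a2 = Σ_{i=1}^{N−1} 1/i²
    b1 = (N+1)/(3(N−1))                 b2 = 2(N²+N+3)/(9N(N−1))
    c1 = b1 − 1/a1                      c2 = b2 − (N+2)/(a1·N) + a2/a1²
    e1 = c1/a1                          e2 = c2/(a1² + a2)
    """
    if n < 2:
        raise ValueError("Tajima constants require N ≥ 2")
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return TajimaConstants(a1, a2, b1, b2, c1, c2, e1, e2)


def watterson_theta(s: int, n: int) -> float:
    """Watterson's estimator θw = S / a1(N) (per window, not per bp)."""
    if n < 2:
        raise ValueError("Watterson's θ requires N ≥ 2")
    if s < 0:
        raise ValueError("S must be non-negative")
    if s == 0:
        return 0.0
    return s / tajima_constants(n).a1


def tajimas_d(big_pi: float, s: int, n: int) -> float | None:
    """Tajima's D, or None when its variance is null (in particular S = 0).

    D = (Π − θw) / sqrt(e1·S + e2·S(S−1)).  The None sentinel is rendered
    as the literal "?" in output files.
    """
    if s == 0:
        return None
    const = tajima_constants(n)
    var = const.e1 * s + const.e2 * s * (s - 1)
    if var <= VARIANCE_EPS:
        return None
    return (big_pi - s / const.a1) / math.sqrt(var)


def global_haplotype_frequencies(values: np.ndarray) -> HaplotypeTable:
    """Haplotype table over the full analysed segment (window-independent)."""
    return haplotype_table(values)
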
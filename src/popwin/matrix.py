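"""Integer-encoded haplotype matrices.

The central data structure is a matrix with one row per genomic site and one
column per haplotype.  Bases are encoded as small integers — A=1, C=2, G=3,
T=4 — and 5 marks missing data (anything that is not an unambiguous base:
'N', gaps, IUPAC ambiguity codes, uncalled genotypes).  All downstream
statistics operate on this encoding, so VCF and FASTA inputs describing the
same polymorphism data become indistinguishable once loaded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "MISSING",
    "encode_base",
    "encode_sequence",
    "decode_codes",
    "HaplotypeMatrix",
]

#: Integer code for missing / non-ACGT data.
MISSING = 5

# 256-entry lookup: byte value -> code.  Everything outside acgtACGT is
# missing, so encoding is total over all byte values.
_CODE_OF = np.full(256, MISSING, dtype=np.int8)
for _b, _c in zip(b"ACGT", (1, 2, 3, 4)):
    _CODE_OF[_b] = _c
    _CODE_OF[_b + 32] = _c  # lowercase

_BASE_OF = np.array(["?", "A", "C", "G", "T", "N"])

#: Characters accepted in strict mode (explicit missing-data symbols).
STRICT_MISSING_CHARS = frozenset("Nn-.?")


def encode_base(b: str) -> int:
    """Encode a single nucleotide character.

    A/C/G/T (case-insensitive) map to 1/2/3/4; every other character —
    'N', '-', '.', '?', IUPAC ambiguity codes — maps to the missing code 5.
    """
    if len(b) != 1:
        raise ValueError(f"encode_base expects a single character, got {b!r}")
    return int(_CODE_OF[ord(b) & 0xFF])


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string into a vector of codes in {1..5}."""
    raw = np.frombuffer(seq.encode("latin-1"), dtype=np.uint8)
    return _CODE_OF[raw].copy()


def decode_codes(codes: Sequence[int]) -> str:
    """Decode a code vector back to characters (5 renders as 'N')."""
    arr = np.asarray(codes, dtype=np.int64)
    if arr.size and (arr.min() < 1 or arr.max() > 5):
        raise ValueError("codes must lie in {1..5}")
    return "".join(_BASE_OF[arr])


@dataclass
class HaplotypeMatrix:
    """Sites × haplotypes matrix of integer-encoded alleles.

    Parameters
    ----------
    values
        Integer matrix, shape (M sites, N haplotypes), entries in {1..5}.
    positions
        Length-M vector of 1-based genomic coordinates, strictly increasing.
    haplotype_ids
        Length-N column labels (sample name plus phase suffix, e.g. "s1|2").
    populations
        Length-N population labels; a single shared label when no
        sample→population map was supplied.
    source_kind
        One of {"vcf", "fasta_sequence", "fasta_snp"}.
    meta
        Free-form provenance (e.g. count of VCF records skipped by the SNP
        filter); never consulted by the statistics.
    """

    values: np.ndarray
    positions: np.ndarray
    haplotype_ids: list[str]
    populations: list[str]
    source_kind: str = "fasta_snp"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotype_ids = list(self.haplotype_ids)
        self.populations = list(self.populations)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (sites × haplotypes) matrix")
        m, n = self.values.shape
        if n < 2:
            raise ValueError(
                f"need at least 2 haplotypes for diversity statistics, got {n}"
            )
        if self.values.size and (self.values.min() < 1 or self.values.max() > 5):
            raise ValueError("matrix entries must lie in {1..5}")
        if len(self.positions) != m:
            raise ValueError(
                f"positions length {len(self.positions)} != number of sites {m}"
            )
        if m > 1 and not np.all(np.diff(self.positions) > 0):
            bad = int(np.flatnonzero(np.diff(self.positions) <= 0)[0])
            raise ValueError(
                "positions must be strictly increasing; violation at "
                f"position index {bad + 1} (coordinate {self.positions[bad + 1]})"
            )
        if len(self.haplotype_ids) != n or len(self.populations) != n:
            raise ValueError("haplotype_ids/populations must match column count")

    # -- basic geometry -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return self.values.shape[1]

    def rows_in(self, lo: int, hi: int) -> np.ndarray:
        """Indices of site rows with lo <= position <= hi (1-based, inclusive)."""
        i = int(np.searchsorted(self.positions, lo, side="left"))
        j = int(np.searchsorted(self.positions, hi, side="right"))
        return np.arange(i, j)

    def subset_columns(self, idx: Sequence[int]) -> "HaplotypeMatrix":
        idx = np.asarray(idx, dtype=np.intp)
        return HaplotypeMatrix(
            values=self.values[:, idx],
            positions=self.positions.copy(),
            haplotype_ids=[self.haplotype_ids[i] for i in idx],
            populations=[self.populations[i] for i in idx],
            source_kind=self.source_kind,
            meta=dict(self.meta),
        )

    def population_indices(self) -> dict[str, np.ndarray]:
        """Column indices per population label, in order of first appearance."""
        out: dict[str, list[int]] = {}
        for i, p in enumerate(self.populations):
            out.setdefault(p, []).append(i)
        return {p: np.asarray(ix, dtype=np.intp) for p, ix in out.items()}
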
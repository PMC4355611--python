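"""Synthetic haplotype panels with known ground truth.

The generator produces infinite-sites-style SNP panels: segregating
positions are drawn uniformly without replacement along the region, and at
each site the derived-allele count ``i`` (out of ``N`` haplotypes) is drawn
with probability proportional to ``1/i`` — the site-frequency spectrum
expected at mutation–drift equilibrium in a constant-size neutral
population.  Under that spectrum the expected window nucleotide diversity
equals Watterson's θ, so Tajima's D is centred on zero by construction and
the panels serve as a neutral null for the whole statistic chain.

Each panel can be written as a matched pair of files — a phased diploid
VCF and the equivalent SNP-haplotype FASTA with a positions sidecar — that
encode the same polymorphism data and must yield identical statistics.

Deliberately *not* modelled: recombination, linkage between sites,
demography, and selection.  The optional population structure is a simple
per-population allele-frequency perturbation, not a demographic model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import write_fasta, write_vcf
from .matrix import MISSING, HaplotypeMatrix

__all__ = ["SimConfig", "GroundTruth", "simulate_panel", "write_fixture_pair"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic panel.

    Exactly one of ``seg_sites`` (target number of segregating sites) or
    ``mutation_rate`` (per-bp probability that a site segregates) must be
    given.  ``drift`` perturbs each population's derived-allele frequency
    by a uniform offset in ``[-drift, +drift]``, crudely emulating
    differentiation between demes.
    """

    n_haplotypes: int
    region_length: int = 100_000
    seg_sites: int | None = None
    mutation_rate: float | None = None
    missing_rate: float = 0.0
    n_populations: int = 1
    drift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_haplotypes < 2:
            raise ValueError("need at least 2 haplotypes")
        if (self.seg_sites is None) == (self.mutation_rate is None):
            raise ValueError("give exactly one of seg_sites or mutation_rate")
        if self.seg_sites is not None and self.seg_sites > self.region_length:
            raise ValueError(
                f"target of {self.seg_sites} segregating sites exceeds "
                f"region length {self.region_length}"
            )
        for name in ("missing_rate", "drift"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mutation_rate is not None and not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.n_populations < 1 or self.n_populations > self.n_haplotypes // 2:
            raise ValueError(
                "n_populations must allow ≥ 2 haplotypes per population"
            )


@dataclass
class GroundTruth:
    """What the generator actually planted, before missing-data masking."""

    s: int                      # segregating sites in the clean matrix
    positions: np.ndarray
    ancestral_codes: np.ndarray  # per site, in {1..4}
    derived_codes: np.ndarray
    derived_counts: np.ndarray   # copies of the derived allele per site
    haplotypes: list[str]        # clean per-column code strings


def _spectrum_counts(rng: np.random.Generator, n: int, size: int) -> np.ndarray:
    """Draw derived-allele counts i ∈ {1..N−1} with P(i) ∝ 1/i."""
    i = np.arange(1, n)
    w = 1.0 / i
    return rng.choice(i, size=size, p=w / w.sum())


def simulate_panel(config: SimConfig) -> tuple[HaplotypeMatrix, GroundTruth]:
    """Generate one panel plus its ground-truth record (seed-reproducible)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_haplotypes
    if config.seg_sites is not None:
        m = config.seg_sites
    else:
        m = int(rng.binomial(config.region_length, config.mutation_rate))
        m = max(m, 1)
    positions = np.sort(
        rng.choice(config.region_length, size=m, replace=False) + 1
    ).astype(np.int64)

    ancestral = rng.integers(1, 5, size=m)
    shift = rng.integers(1, 4, size=m)
    derived = (ancestral - 1 + shift) % 4 + 1  # any base but the ancestral

    values = np.repeat(ancestral[:, None], n, axis=1).astype(np.int8)
    counts = _spectrum_counts(rng, n, m)

    pop_of_col = np.repeat(np.arange(config.n_populations),
                           _split_sizes(n, config.n_populations))
    for row in range(m):
        if config.drift == 0.0 or config.n_populations == 1:
            carriers = rng.choice(n, size=counts[row], replace=False)
        else:
            p = counts[row] / n
            carriers_mask = np.zeros(n, dtype=bool)
            for pop in range(config.n_populations):
                cols = np.flatnonzero(pop_of_col == pop)
                p_pop = float(np.clip(
                    p + rng.uniform(-config.drift, config.drift), 0.0, 1.0
                ))
                carriers_mask[cols] = rng.random(cols.size) < p_pop
            carriers = np.flatnonzero(carriers_mask)
        values[row, carriers] = derived[row]

    truth = GroundTruth(
        s=int((np.stack([(values == c).any(axis=1) for c in (1, 2, 3, 4)])
               .sum(axis=0) >= 2).sum()),
        positions=positions.copy(),
        ancestral_codes=ancestral.copy(),
        derived_codes=derived.copy(),
        derived_counts=counts.copy(),
        haplotypes=[
            "".join(chr(48 + c) for c in values[:, j]) for j in range(n)
        ],
    )

    if config.missing_rate > 0.0:
        mask = rng.random(values.shape) < config.missing_rate
        values = values.copy()
        values[mask] = MISSING

    ids: list[str] = []
    pops: list[str] = []
    if n % 2 == 0:  # diploid pairing for VCF round trips
        for s_idx in range(n // 2):
            name = f"s{s_idx + 1}"
            ids.extend((f"{name}|1", f"{name}|2"))
            pops.extend([f"POP{pop_of_col[2 * s_idx] + 1}"] * 2)
    else:
        ids = [f"s{j + 1}" for j in range(n)]
        pops = [f"POP{pop_of_col[j] + 1}" for j in range(n)]

    matrix = HaplotypeMatrix(
        values=values,
        positions=positions,
        haplotype_ids=ids,
        populations=pops,
        source_kind="fasta_snp",
        meta={"simulated": True, "seed": config.seed},
    )
    return matrix, truth


def _split_sizes(n: int, k: int) -> np.ndarray:
    """Partition n columns into k near-equal, even-sized groups."""
    pairs = n // 2
    per = np.full(k, pairs // k)
    per[: pairs % k] += 1
    sizes = per * 2
    if n % 2:  # odd panel: last population takes the spare haploid column
        sizes[-1] += 1
    return sizes


def write_fixture_pair(
    matrix: HaplotypeMatrix, out_dir: str | Path, prefix: str = "panel"
) -> dict[str, Path]:
    """Write matched VCF and FASTA(+positions) renditions of one panel.

    Consecutive column pairs become diploid VCF samples, so the haplotype
    count must be even.  Reading either file back reproduces the matrix.
    """
    if matrix.n_haplotypes % 2:
        raise ValueError(
            "diploid VCF pairing needs an even haplotype count; "
            "simulate an even panel or write FASTA only"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out_dir / f"{prefix}.vcf",
        "fasta": out_dir / f"{prefix}.fasta",
        "positions": out_dir / f"{prefix}.positions.txt",
        "pop_map": out_dir / f"{prefix}.popmap.txt",
    }
    write_vcf(matrix, paths["vcf"])
    write_fasta(matrix, paths["fasta"], positions_path=paths["positions"])
    samples = dict.fromkeys(h.rsplit("|", 1)[0] for h in matrix.haplotype_ids)
    pop_of = {
        h.rsplit("|", 1)[0]: p
        for h, p in zip(matrix.haplotype_ids, matrix.populations)
    }
    paths["pop_map"].write_text(
        "".join(f"{s}\t{pop_of[s]}\n" for s in samples)
    )
    return paths
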
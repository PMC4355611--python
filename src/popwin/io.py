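"""Reading and writing haplotype data.

Supported inputs:

* **Phased VCF 4.x** — each k-ploid sample contributes k matrix columns
  ("sample|1" … "sample|k"; haploid samples keep the bare name).  Only
  records whose REF and every ALT are single A/C/G/T bases are retained
  (SNP filter); multi-allelic SNPs are kept as single sites.  Skipped
  records are counted in ``matrix.meta["skipped_records"]``, never fatal.
* **FASTA** — either full aligned DNA sequences (positions run from a
  declared region start) or SNP-haplotype strings plus a positions sidecar
  file (one 1-based coordinate per line).

A sample→population map is plain two-column whitespace-delimited text.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .matrix import (
    MISSING,
    STRICT_MISSING_CHARS,
    HaplotypeMatrix,
    decode_codes,
    encode_sequence,
)

logger = logging.getLogger("popwin")

__all__ = [
    "ValidationError",
    "PopulationMap",
    "read_population_map",
    "read_positions",
    "read_fasta",
    "read_vcf",
    "write_fasta",
    "write_vcf",
    "validate_inputs",
]


class ValidationError(Exception):
    """Input fails the pre-analysis checks; the message names the culprit."""


@dataclass
class PopulationMap:
    """Mapping from sample name to population label."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError("no samples in population map")

    def label_for(self, haplotype_id: str) -> str:
        """Population of a haplotype column; the phase suffix is stripped."""
        sample = haplotype_id.rsplit("|", 1)[0]
        try:
            return self.entries[sample]
        except KeyError:
            raise ValidationError(
                f"sample '{sample}' is absent from the population map"
            ) from None


def read_population_map(path: str | Path) -> PopulationMap:
    """Parse a two-column (sample, population) text file."""
    entries: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ValidationError(
                    f"population map line {lineno}: expected 2 fields "
                    f"(sample, population), got {len(fields)}: {line!r}"
                )
            sample, pop = fields
            if sample in entries:
                raise ValidationError(
                    f"population map line {lineno}: duplicate sample '{sample}'"
                )
            entries[sample] = pop
    if not entries:
        raise ValidationError("no samples in population map")
    return PopulationMap(entries)


def read_positions(path: str | Path) -> list[int]:
    """Read a positions sidecar: one 1-based integer coordinate per line."""
    positions: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                positions.append(int(line))
            except ValueError:
                raise ValidationError(
                    f"positions file line {lineno}: not an integer: {line!r}"
                ) from None
    return positions


DEFAULT_POPULATION = "ALL"


def _population_labels(
    haplotype_ids: Sequence[str], pop_map: PopulationMap | None
) -> list[str]:
    if pop_map is None:
        return [DEFAULT_POPULATION] * len(haplotype_ids)
    return [pop_map.label_for(h) for h in haplotype_ids]


def read_fasta(
    path: str | Path,
    positions: str | Path | Sequence[int] | None = None,
    region_start: int = 1,
    pop_map: PopulationMap | None = None,
    strict: bool = False,
) -> HaplotypeMatrix:
    """Load aligned haplotype sequences into an encoded matrix.

    Parameters
    ----------
    positions
        Sidecar file path or explicit coordinate list for SNP-haplotype
        input; omit for full DNA sequences, whose sites are numbered
        ``region_start .. region_start + M − 1``.
    strict
        Reject characters outside ACGT and the explicit missing symbols
        (N, -, ., ?) instead of silently encoding them as missing.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValidationError(f"no FASTA records found in {path}")
    length = len(records[0].seq)
    for i, rec in enumerate(records, start=1):
        if len(rec.seq) != length:
            raise ValidationError(
                f"record {i} ('{rec.id}') has length {len(rec.seq)}, "
                f"expected {length} as in record 1 ('{records[0].id}')"
            )
        if strict:
            bad = set(str(rec.seq)) - set("ACGTacgt") - STRICT_MISSING_CHARS
            if bad:
                raise ValidationError(
                    f"record {i} ('{rec.id}') contains unexpected "
                    f"character(s) {sorted(bad)} (strict mode)"
                )
    if positions is not None:
        if isinstance(positions, (str, Path)):
            pos_list = read_positions(positions)
        else:
            pos_list = [int(p) for p in positions]
        if len(pos_list) != length:
            raise ValidationError(
                f"positions list has {len(pos_list)} entries but sequences "
                f"have {length} sites"
            )
        source_kind = "fasta_snp"
    else:
        pos_list = list(range(region_start, region_start + length))
        source_kind = "fasta_sequence"

    values = np.stack(
        [encode_sequence(str(rec.seq)) for rec in records], axis=1
    )
    ids = [rec.id for rec in records]
    return HaplotypeMatrix(
        values=values,
        positions=np.asarray(pos_list, dtype=np.int64),
        haplotype_ids=ids,
        populations=_population_labels(ids, pop_map),
        source_kind=source_kind,
    )


_BASE_CODE = {"A": 1, "C": 2, "G": 3, "T": 4}


def read_vcf(
    path: str | Path,
    pop_map: PopulationMap | None = None,
    chrom: str | None = None,
    strict_phase: bool = False,
) -> HaplotypeMatrix:
    """Load phased SNP genotypes from a VCF into an encoded matrix.

    Allele indices in GT are resolved through REF/ALT to bases and then
    encoded; '.' genotype calls become the missing code.  Unphased ('/')
    genotypes are accepted with a warning — the written allele order is
    treated as phase — unless ``strict_phase`` makes them fatal.
    """
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ValidationError(f"cannot parse VCF {path}: {exc}") from exc
    if "GT" not in vcf.header.formats:
        raise ValidationError(
            f"VCF {path}: FORMAT field 'GT' is not declared; phased "
            "genotypes are required"
        )
    samples = list(vcf.header.samples)
    if not samples:
        raise ValidationError(f"VCF {path} has no sample columns")

    rows: list[np.ndarray] = []
    positions: list[int] = []
    ploidy: list[int] | None = None
    skipped = 0
    unphased_warned = False
    seen_chroms: set[str] = set()

    for rec in vcf:
        seen_chroms.add(rec.chrom)
        if chrom is not None and rec.chrom != chrom:
            continue
        alts = rec.alts or ()
        alleles = (rec.ref,) + tuple(alts)
        if any(a is None or len(a) != 1 or a.upper() not in _BASE_CODE
               for a in alleles):
            skipped += 1
            continue
        codes = [_BASE_CODE[a.upper()] for a in alleles]

        row: list[int] = []
        rec_ploidy: list[int] = []
        for name in samples:
            call = rec.samples[name]
            gt = call.get("GT")
            if gt is None:
                raise ValidationError(
                    f"VCF {path} position {rec.pos}: sample '{name}' has "
                    "no GT field"
                )
            if len(gt) > 1 and not call.phased:
                if strict_phase:
                    raise ValidationError(
                        f"VCF {path} position {rec.pos}: sample '{name}' "
                        "genotype is unphased ('/') and --strict-phase is set"
                    )
                if not unphased_warned:
                    logger.warning(
                        "unphased genotype(s) found (first at position %d, "
                        "sample %s); treating written allele order as phase — "
                        "haplotype statistics are approximations",
                        rec.pos, name,
                    )
                    unphased_warned = True
            rec_ploidy.append(len(gt))
            for allele_idx in gt:
                row.append(MISSING if allele_idx is None else codes[allele_idx])
        if ploidy is None:
            ploidy = rec_ploidy
        elif ploidy != rec_ploidy:
            raise ValidationError(
                f"VCF {path} position {rec.pos}: sample ploidy changed "
                "between records"
            )
        rows.append(np.asarray(row, dtype=np.int8))
        positions.append(rec.pos)

    if chrom is None and len(seen_chroms) > 1:
        raise ValidationError(
            f"VCF {path} contains multiple chromosomes "
            f"({', '.join(sorted(seen_chroms))}); select one with --chrom"
        )
    if not rows:
        raise ValidationError(
            f"VCF {path}: no usable SNP records"
            + (f" on chromosome {chrom}" if chrom else "")
        )
    assert ploidy is not None
    ids: list[str] = []
    for name, k in zip(samples, ploidy):
        if k == 1:
            ids.append(name)
        else:
            ids.extend(f"{name}|{j}" for j in range(1, k + 1))
    if skipped:
        logger.warning("skipped %d non-SNP VCF record(s)", skipped)
    return HaplotypeMatrix(
        values=np.stack(rows, axis=0),
        positions=np.asarray(positions, dtype=np.int64),
        haplotype_ids=ids,
        populations=_population_labels(ids, pop_map),
        source_kind="vcf",
        meta={"skipped_records": skipped},
    )


# ---------------------------------------------------------------------------
# writers (fixture generation and round-trip support)
# ---------------------------------------------------------------------------

def write_fasta(
    matrix: HaplotypeMatrix,
    fasta_path: str | Path,
    positions_path: str | Path | None = None,
) -> None:
    """Write one FASTA record per haplotype column (missing code as 'N').

    When ``positions_path`` is given a sidecar with one coordinate per line
    is written alongside, making the pair a complete SNP-haplotype input.
    """
    records = [
        SeqRecord(Seq(decode_codes(matrix.values[:, j])),
                  id=matrix.haplotype_ids[j], description="")
        for j in range(matrix.n_haplotypes)
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    if positions_path is not None:
        with open(positions_path, "w") as fh:
            fh.writelines(f"{p}\n" for p in matrix.positions)


def _sample_groups(ids: Sequence[str]) -> list[tuple[str, list[int]]]:
    """Group consecutive haplotype columns into samples by their '|' prefix."""
    groups: list[tuple[str, list[int]]] = []
    for i, hid in enumerate(ids):
        name = hid.rsplit("|", 1)[0] if "|" in hid else hid
        if groups and groups[-1][0] == name:
            groups[-1][1].append(i)
        else:
            groups.append((name, [i]))
    return groups


_CODE_BASE = {1: "A", 2: "C", 3: "G", 4: "T"}


def write_vcf(
    matrix: HaplotypeMatrix, path: str | Path, chrom: str = "1"
) -> None:
    """Write the matrix as a phased plain-text VCF.

    Consecutive columns sharing a "name|k" prefix form one multi-ploid
    sample; suffix-less columns become haploid samples.  The REF allele at
    each site is the first non-missing code observed in column order.
    """
    groups = _sample_groups(matrix.haplotype_ids)
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom},length={int(matrix.positions[-1]) + 1}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(name for name, _ in groups),
    ]
    for i in range(matrix.n_sites):
        row = matrix.values[i]
        allele_order: list[int] = []
        for c in row:
            if c != MISSING and c not in allele_order:
                allele_order.append(int(c))
        if not allele_order:  # all-missing site: arbitrary REF, no ALT
            allele_order = [1]
        ref = _CODE_BASE[allele_order[0]]
        alts = ",".join(_CODE_BASE[c] for c in allele_order[1:]) or "."
        index_of = {c: k for k, c in enumerate(allele_order)}
        gt_fields = []
        for _, cols in groups:
            gt_fields.append("|".join(
                "." if row[j] == MISSING else str(index_of[int(row[j])])
                for j in cols
            ))
        lines.append(
            f"{chrom}\t{int(matrix.positions[i])}\t.\t{ref}\t{alts}"
            f"\t.\t.\t.\tGT\t" + "\t".join(gt_fields)
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# pre-analysis validation
# ---------------------------------------------------------------------------

def validate_inputs(matrix: HaplotypeMatrix, spec) -> list[str]:
    """Pre-analysis checks; returns a list of human-readable failures.

    An empty list means the run may proceed.  Checks that the window
    schedule is geometrically possible and that site numbering is
    consistent with the declared segment bounds.
    """
    failures: list[str] = []
    if spec.increment < 1:
        failures.append(f"increment must be ≥ 1 (got {spec.increment})")
    if spec.size < 1:
        failures.append(f"window size must be ≥ 1 (got {spec.size})")
    if spec.start > spec.end:
        failures.append(
            f"segment start {spec.start} exceeds segment end {spec.end}"
        )
    else:
        region = spec.end - spec.start + 1
        if spec.mode == "bp" and spec.size > region:
            failures.append(
                f"window exceeds region: size {spec.size} bp > segment "
                f"length {region} bp"
            )
        in_segment = matrix.rows_in(spec.start, spec.end)
        if in_segment.size == 0:
            failures.append(
                f"no sites fall inside the segment [{spec.start}, "
                f"{spec.end}]; site positions span "
                f"[{int(matrix.positions[0])}, {int(matrix.positions[-1])}] — "
                "check that position numbering matches the segment definition"
            )
    return failures
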
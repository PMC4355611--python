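"""Tabular output writers.

Two tab-separated files: per-window statistics and global haplotype
frequencies.  Real numbers are fixed to 6 decimal places; an undefined
Tajima's D (null variance, e.g. zero segregating sites) is written as the
literal ``?``.
"""

from __future__ import annotations

import logging
from pathlib import Path

from .matrix import decode_codes
from .stats import HaplotypeTable
from .windows import WindowResult

logger = logging.getLogger("popwin")

__all__ = ["write_window_results", "write_haplotype_frequencies"]

UNDEFINED_GLYPH = "?"

_WINDOW_HEADER = (
    "population\twindow_start\twindow_end\tS\thap_number\tHd\tPi"
    "\tpi_per_bp\ttheta_w\ttajimas_D"
)


def format_window_results(results: list[WindowResult]) -> str:
    """Render results as TSV text (deterministic; used by both writers and tests)."""
    lines = [_WINDOW_HEADER]
    for r in results:
        d = UNDEFINED_GLYPH if r.tajimas_d is None else f"{r.tajimas_d:.6f}"
        lines.append(
            f"{r.population}\t{r.window.lo}\t{r.window.hi}\t{r.s}"
            f"\t{r.hap_number}\t{r.hd:.6f}\t{r.big_pi:.6f}"
            f"\t{r.pi_per_bp:.6f}\t{r.theta_w:.6f}\t{d}"
        )
    return "\n".join(lines) + "\n"


def write_window_results(results: list[WindowResult], path: str | Path) -> None:
    """Write the per-window statistics table; one row per (population, window)."""
    if not results:
        logger.warning("no window results to write; emitting header only")
    try:
        Path(path).write_text(format_window_results(results))
    except OSError as exc:
        raise OSError(f"cannot write window results to {path}: {exc}") from exc


def format_haplotype_frequencies(table: HaplotypeTable) -> str:
    """Render the haplotype-frequency table as TSV text.

    Haplotype code-strings are decoded back to A/C/G/T/N; rows sorted by
    descending count, ties broken lexicographically by sequence.
    """
    rows = sorted(
        (
            (decode_codes([int(c) for c in hap]), int(cnt), float(freq))
            for hap, cnt, freq in zip(
                table.haplotypes, table.counts, table.frequencies
            )
        ),
        key=lambda r: (-r[1], r[0]),
    )
    lines = ["haplotype\tcount\tfrequency"]
    lines.extend(f"{h}\t{c}\t{f:.6f}" for h, c, f in rows)
    return "\n".join(lines) + "\n"


def write_haplotype_frequencies(table: HaplotypeTable, path: str | Path) -> None:
    """Write the global haplotype-frequency table."""
    try:
        Path(path).write_text(format_haplotype_frequencies(table))
    except OSError as exc:
        raise OSError(
            f"cannot write haplotype frequencies to {path}: {exc}"
        ) from exc
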
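"""Sliding-window schedules and the per-window / per-population driver.

A window of size ``n`` starting at ``p`` covers the inclusive 1-based span
``[p, p + n − 1]``; the next window starts ``v`` base pairs later.  Window
size may alternatively be expressed as a fixed number of segregating
sites, in which case consecutive windows advance by ``v`` segregating
sites and a window's bp bounds are the coordinates of its first and last
segregating site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from . import stats
from .matrix import HaplotypeMatrix

logger = logging.getLogger("popwin")

__all__ = [
    "WindowSpec",
    "Window",
    "WindowResult",
    "generate_windows_bp",
    "generate_windows_segsites",
    "run_analysis",
    "results_to_dataframe",
]


@dataclass(frozen=True)
class WindowSpec:
    """Segment bounds plus window geometry.

    ``size`` and ``increment`` are in base pairs when ``mode == "bp"`` and
    in segregating-site counts when ``mode == "segsites"``.  Coordinates
    are 1-based and inclusive throughout.
    """

    start: int
    end: int
    size: int
    increment: int
    mode: str = "bp"

    def __post_init__(self) -> None:
        if self.mode not in ("bp", "segsites"):
            raise ValueError(f"unknown window mode {self.mode!r}")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.size < 1:
            raise ValueError("window size must be ≥ 1")
        if self.increment < 1:
            raise ValueError("window increment must be ≥ 1")


@dataclass(frozen=True)
class Window:
    """One concrete window: bp bounds plus the matrix rows it contains."""

    lo: int
    hi: int
    site_rows: np.ndarray

    @property
    def span_bp(self) -> int:
        return self.hi - self.lo + 1


@dataclass
class WindowResult:
    """All statistics for one (population, window) pair."""

    window: Window
    population: str
    s: int
    hap_number: int
    hd: float
    big_pi: float
    pi_per_bp: float
    theta_w: float
    tajimas_d: float | None


def generate_windows_bp(
    spec: WindowSpec,
    positions: np.ndarray,
    emit_partial: bool = False,
) -> list[Window]:
    """Windows [p+jv, p+jv+n−1] for j = 0, 1, … while they fit the segment.

    A trailing span shorter than ``n`` is dropped unless ``emit_partial``,
    in which case it is emitted truncated at the segment end (its true
    span then serves as the π denominator downstream).
    """
    region = spec.end - spec.start + 1
    if spec.size > region:
        raise ValueError(
            f"no windows fit: window size {spec.size} bp exceeds segment "
            f"length {region} bp"
        )
    positions = np.asarray(positions)
    windows: list[Window] = []
    lo = spec.start
    while lo + spec.size - 1 <= spec.end:
        hi = lo + spec.size - 1
        windows.append(Window(lo, hi, _rows_between(positions, lo, hi)))
        lo += spec.increment
    if emit_partial and lo <= spec.end:
        windows.append(
            Window(lo, spec.end, _rows_between(positions, lo, spec.end))
        )
    return windows


def _rows_between(positions: np.ndarray, lo: int, hi: int) -> np.ndarray:
    i = int(np.searchsorted(positions, lo, side="left"))
    j = int(np.searchsorted(positions, hi, side="right"))
    return np.arange(i, j)


def generate_windows_segsites(
    spec: WindowSpec,
    positions: np.ndarray,
    seg_flags: np.ndarray,
) -> list[Window]:
    """Windows holding a fixed number of segregating sites.

    The j-th window contains the segregating sites with ordinals
    ``1 + j·v … n + j·v`` (1-based among segregating sites); its bp bounds
    are the coordinates of its first and last segregating site, and its
    rows include any intervening monomorphic sites.
    """
    positions = np.asarray(positions)
    seg_idx = np.flatnonzero(np.asarray(seg_flags, dtype=bool))
    total = seg_idx.size
    if total < spec.size:
        logger.warning(
            "only %d segregating site(s) in segment but window size is %d; "
            "no windows emitted", total, spec.size,
        )
        return []
    windows: list[Window] = []
    first = 0  # 0-based ordinal of the window's first segregating site
    while first + spec.size <= total:
        rows = seg_idx[first:first + spec.size]
        lo = int(positions[rows[0]])
        hi = int(positions[rows[-1]])
        windows.append(Window(lo, hi, _rows_between(positions, lo, hi)))
        first += spec.increment
    return windows


def _window_result(
    values: np.ndarray, window: Window, population: str
) -> WindowResult:
    sub = values[window.site_rows, :]
    n = sub.shape[1]
    s = stats.count_segregating_sites(sub)
    table = stats.haplotype_table(sub)
    big_pi, pi_bp = stats.window_pi(sub, window.span_bp)
    return WindowResult(
        window=window,
        population=population,
        s=s,
        hap_number=table.n_haplotypes,
        hd=stats.haplotype_diversity(table, n),
        big_pi=big_pi,
        pi_per_bp=pi_bp,
        theta_w=stats.watterson_theta(s, n),
        tajimas_d=stats.tajimas_d(big_pi, s, n),
    )


def run_analysis(
    matrix: HaplotypeMatrix,
    spec: WindowSpec,
    pooled: bool = False,
    emit_partial: bool = False,
) -> list[WindowResult]:
    """Compute every statistic for every window, per population or pooled.

    In per-population mode each population is analysed on its own columns
    only — its own N enters every formula and (in segregating-sites mode)
    its own segregating sites define the schedule.  Populations with fewer
    than two haplotypes are skipped with a warning.  Results are ordered
    population-major, window-minor.
    """
    if pooled:
        groups = {"ALL": np.arange(matrix.n_haplotypes)}
    else:
        groups = matrix.population_indices()

    results: list[WindowResult] = []
    for pop, cols in groups.items():
        if cols.size < 2:
            logger.warning(
                "population %s has %d haplotype(s); diversity statistics "
                "are undefined — skipped", pop, cols.size,
            )
            continue
        values = matrix.values[:, cols]
        if spec.mode == "bp":
            schedule = generate_windows_bp(
                spec, matrix.positions, emit_partial=emit_partial
            )
        else:
            schedule = generate_windows_segsites(
                spec, matrix.positions, stats.segregating_flags(values)
            )
        results.extend(_window_result(values, w, pop) for w in schedule)
    return results


def results_to_dataframe(results: list[WindowResult]) -> pd.DataFrame:
    """Tabulate results with one row per (population, window)."""
    return pd.DataFrame(
        {
            "population": [r.population for r in results],
            "window_start": [r.window.lo for r in results],
            "window_end": [r.window.hi for r in results],
            "S": [r.s for r in results],
            "hap_number": [r.hap_number for r in results],
            "Hd": [r.hd for r in results],
            "Pi": [r.big_pi for r in results],
            "pi_per_bp": [r.pi_per_bp for r in results],
            "theta_w": [r.theta_w for r in results],
            "tajimas_D": [r.tajimas_d for r in results],
        }
    )
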
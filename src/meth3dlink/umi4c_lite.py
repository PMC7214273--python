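"""Bait-anchored contact-profile comparison for UMI-4C style data.

Works on per-restriction-fragment unique-molecule (UMI) counts around one
bait, for two conditions. The reliable quantification range of the assay is
roughly 0.5 kb to 1 Mb from the bait, so profiles are distance-filtered
(inclusive at both bounds) before any comparison. Counts are depth-normalized
by each profile's total filtered UMIs — the minimal normalization that makes
two sequencing depths comparable — then smoothed with a centered moving
average (truncated at the edges) for trend lines, and summarized across a
series of window scales in a domainogram of differential mean contacts
(condition B minus condition A).

Differential contact at a target window is tested with a Pearson chi-square
(df = 1, no continuity correction by default — UMI totals here are large) on
the 2x2 table of UMI counts inside/outside the window per condition. When a
run tests several windows, BH adjustment across windows gives the adjusted p;
a single-window run reports adjusted = raw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigError, InputError
from .io_formats import GenomicInterval

DEFAULT_MIN_BP = 500
DEFAULT_MAX_BP = 1_000_000


@dataclass
class ContactProfile:
    """Per-fragment UMI counts around one bait for one condition."""

    bait_pos: int
    fragments: list[tuple[GenomicInterval, int]]
    condition: str

    def __post_init__(self) -> None:
        prev_end = None
        prev_chrom = None
        for iv, count in self.fragments:
            if count < 0:
                raise InputError(f"negative UMI count at {iv}")
            if prev_chrom == iv.chrom and prev_end is not None and iv.start < prev_end:
                raise InputError(f"fragments overlap or are unsorted at {iv}")
            prev_chrom, prev_end = iv.chrom, iv.end

    @property
    def total_umis(self) -> int:
        return int(sum(c for _, c in self.fragments))

    @property
    def counts(self) -> np.ndarray:
        return np.array([c for _, c in self.fragments], dtype=float)

    def normalized(self) -> np.ndarray:
        total = self.total_umis
        if total == 0:
            raise InputError("profile has zero total UMIs")
        return self.counts / total

    def grid(self) -> list[GenomicInterval]:
        return [iv for iv, _ in self.fragments]


@dataclass(frozen=True)
class Domainogram:
    """scale x fragment matrix of differential mean contacts (B - A)."""

    scales: tuple[int, ...]
    values: np.ndarray
    grid: tuple[GenomicInterval, ...]


@dataclass(frozen=True)
class ContactTestResult:
    chi2: float
    p: float
    p_adjusted: float
    table: tuple[tuple[int, int], tuple[int, int]]  # [[A_in, A_out], [B_in, B_out]]


def distance_filter(
    profile: ContactProfile,
    min_bp: int = DEFAULT_MIN_BP,
    max_bp: int = DEFAULT_MAX_BP,
) -> ContactProfile:
    """Keep fragments whose midpoint distance d from the bait satisfies
    min_bp <= d <= max_bp (inclusive at both bounds)."""
    if min_bp >= max_bp:
        raise ConfigError(f"min_bp {min_bp} must be < max_bp {max_bp}")
    kept = [
        (iv, c)
        for iv, c in profile.fragments
        if min_bp <= abs(iv.midpoint - profile.bait_pos) <= max_bp
    ]
    return ContactProfile(profile.bait_pos, kept, profile.condition)


def _truncated_moving_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; windows are truncated at the array edges."""
    kernel = np.ones(window)
    sums = np.convolve(values, kernel, mode="same")
    sizes = np.convolve(np.ones_like(values), kernel, mode="same")
    return sums / sizes


def smooth_profile(profile: ContactProfile, window_frags: int = 5) -> np.ndarray:
    """Centered moving average of depth-normalized counts (trend line)."""
    if window_frags < 1 or window_frags % 2 == 0:
        raise ConfigError("smoothing window must be a positive odd integer")
    return _truncated_moving_mean(profile.normalized(), window_frags)


def domainogram(
    prof_a: ContactProfile,
    prof_b: ContactProfile,
    scales: Sequence[int] = (1, 3, 5, 9, 15),
) -> Domainogram:
    """Differential mean contacts (normalized B - normalized A) at each scale.

    Value at (scale s, fragment i) is the mean over the s-fragment window
    centered at i of the normalized counts of B, minus the same for A. At
    scale 1 this is exactly the difference of normalized counts.
    """
    grid_a, grid_b = prof_a.grid(), prof_b.grid()
    if grid_a != grid_b:
        raise InputError("profiles must share an identical fragment grid")
    for s in scales:
        if s < 1 or s % 2 == 0:
            raise ConfigError(f"domainogram scale {s} must be a positive odd integer")
    diff_src_a = prof_a.normalized()
    diff_src_b = prof_b.normalized()
    rows = [
        _truncated_moving_mean(diff_src_b, s) - _truncated_moving_mean(diff_src_a, s)
        for s in scales
    ]
    return Domainogram(tuple(scales), np.vstack(rows), tuple(grid_a))


def fragment_index(profile: ContactProfile, chrom: str, pos1: int) -> int:
    """Index of the fragment containing a 1-based position, or -1 if none."""
    for i, (iv, _) in enumerate(profile.fragments):
        if iv.chrom == chrom and iv.start <= pos1 - 1 < iv.end:
            return i
    return -1


def per_fragment_z(prof_a: ContactProfile, prof_b: ContactProfile) -> np.ndarray:
    """Two-proportion z score per fragment (B vs A share of total UMIs).

    Unlike the raw normalized difference, this is variance-stabilized: near
    the bait, large counts carry large absolute Poisson noise, so raw
    differences there can exceed a genuine distal loop gain. Used to locate
    the strongest differential contact before formal testing.
    """
    if prof_a.grid() != prof_b.grid():
        raise InputError("profiles must share an identical fragment grid")
    a, b = prof_a.counts, prof_b.counts
    ta, tb = a.sum(), b.sum()
    if ta == 0 or tb == 0:
        raise InputError("profile has zero total UMIs")
    pooled = (a + b) / (ta + tb)
    denom = np.sqrt(np.clip(pooled * (1 - pooled), 1e-300, None) * (1 / ta + 1 / tb))
    return (b / tb - a / ta) / denom


def _window_table(
    prof_a: ContactProfile, prof_b: ContactProfile, window: tuple[int, int]
) -> tuple[tuple[int, int], tuple[int, int]]:
    lo, hi = window
    n = len(prof_a.fragments)
    if not (0 <= lo <= hi < n):
        raise InputError(f"target window {window} outside fragment grid of size {n}")
    a, b = prof_a.counts, prof_b.counts
    a_in = int(a[lo : hi + 1].sum())
    b_in = int(b[lo : hi + 1].sum())
    a_out = int(a.sum()) - a_in
    b_out = int(b.sum()) - b_in
    return ((a_in, a_out), (b_in, b_out))


def contact_test(
    prof_a: ContactProfile,
    prof_b: ContactProfile,
    target_window: tuple[int, int],
    yates: bool = False,
) -> ContactTestResult:
    """Chi-square test of differential contact at one fragment window.

    Builds the 2x2 table [[A_in, A_out], [B_in, B_out]] of UMI counts inside
    vs outside the window (inclusive fragment index range) and applies a
    Pearson chi-square with df = 1. Single-window runs report adjusted = raw.
    """
    results = contact_test_multi(prof_a, prof_b, [target_window], yates=yates)
    return results[0]


def contact_test_multi(
    prof_a: ContactProfile,
    prof_b: ContactProfile,
    windows: Sequence[tuple[int, int]],
    yates: bool = False,
) -> list[ContactTestResult]:
    """Chi-square contact tests over several windows, BH-adjusted across them."""
    if not prof_a.fragments or not prof_b.fragments:
        raise InputError("profiles are empty after filtering")
    if prof_a.grid() != prof_b.grid():
        raise InputError("profiles must share an identical fragment grid")
    raw = []
    tables = []
    for window in windows:
        table = _window_table(prof_a, prof_b, window)
        arr = np.array(table, dtype=float)
        if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
            raise InputError(
                f"degenerate 2x2 table {table} at window {window}: a margin is zero"
            )
        chi2, p, _, _ = stats.chi2_contingency(arr, correction=yates)
        raw.append((float(chi2), float(max(p, np.finfo(float).tiny))))
        tables.append(table)
    adjusted = multipletests([p for _, p in raw], method="fdr_bh")[1]
    return [
        ContactTestResult(chi2=c, p=p, p_adjusted=float(pa), table=t)
        for (c, p), pa, t in zip(raw, adjusted, tables)
    ]
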
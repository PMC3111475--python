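"""Watterson diversity estimation from dual-platform pooled read counts.

Sequencing errors on short-read platforms inflate low-count variant
classes, so a site is only accepted as segregating when its variant allele
is seen on *both* platforms, optionally more than once (``S_>1`` excludes
read singletons, ``S_>2`` read doubletons as well; errors being independent
between platforms, coincident false variants are rare).  Watterson's
estimator ``theta_hat = S / (a_n * L)`` (per kb) is then applied genome
wide, in 100 kb windows sliding by 10 kb, and summarised per 10 kb tile by
the median of the covering windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .synthetic_data import PlatformSiteCounts

SCHEME_THRESHOLDS = {"s": 1, "s_gt1": 2, "s_gt2": 3}


def harmonic_number(m: int) -> float:
    """H_m = 1 + 1/2 + ... + 1/m (a_n of Watterson's estimator is H_{n-1})."""
    return float(np.sum(1.0 / np.arange(1, m + 1))) if m >= 1 else 0.0


def watterson_theta(s_count: float, n: int, callable_length: float) -> float:
    """Watterson's theta per kb: ``1000 * S / (a_n * L)``.

    ``n`` is the number of sampled lineages and ``L`` the number of
    callable sites over which ``S`` segregating sites were observed.
    """
    if n < 2:
        raise ValueError("need n >= 2 lineages")
    if callable_length < 1:
        raise ValueError("need callable_length >= 1")
    a_n = harmonic_number(n - 1)
    return 1000.0 * s_count / (a_n * callable_length)


@dataclass
class SegregatingSiteSet:
    """Per-site calling state for one taxon pool on one chromosome.

    Carries both platforms' depths and chosen-variant counts so windowed
    statistics can re-apply their own depth rule; ``callable_mask`` and
    ``seg_mask`` reflect the calling parameters (``min_coverage``,
    ``scheme``) given at construction.
    """

    taxon: str
    chrom: str
    length: int
    n_lineages: Optional[int]
    depth1: np.ndarray
    depth2: np.ndarray
    variant1: np.ndarray
    variant2: np.ndarray
    min_coverage: int
    scheme: str

    @property
    def callable_mask(self) -> np.ndarray:
        return (self.depth1 >= self.min_coverage) & \
               (self.depth2 >= self.min_coverage)

    def segregating_mask(self, scheme: Optional[str] = None) -> np.ndarray:
        thr = SCHEME_THRESHOLDS[(scheme or self.scheme).lower()]
        return (self.variant1 >= thr) & (self.variant2 >= thr)

    @property
    def seg_mask(self) -> np.ndarray:
        return self.segregating_mask() & self.callable_mask

    @property
    def s_count(self) -> int:
        return int(np.count_nonzero(self.seg_mask))

    @property
    def callable_length(self) -> int:
        return int(np.count_nonzero(self.callable_mask))

    def theta_per_kb(self, n: Optional[int] = None) -> float:
        n = n if n is not None else self.n_lineages
        return watterson_theta(self.s_count, n, max(self.callable_length, 1))


def _variant_counts(
    counts_platform1: PlatformSiteCounts,
    counts_platform2: PlatformSiteCounts,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-platform read counts of the variant allele.

    The majority allele is defined across both platforms combined; the
    variant is the most frequent non-majority allele (additional alleles at
    multi-allelic sites are ignored).
    """
    alleles = sorted(set(counts_platform1.allele_counts)
                     | set(counts_platform2.allele_counts))
    L = counts_platform1.length
    zero = np.zeros(L, dtype=np.int64)
    if len(alleles) < 2:
        return zero.copy(), zero.copy()
    if len(alleles) == 2:
        a0, a1 = alleles
        c1a = counts_platform1.allele_counts.get(a1, zero)
        c1r = counts_platform1.allele_counts.get(a0, zero)
        c2a = counts_platform2.allele_counts.get(a1, zero)
        c2r = counts_platform2.allele_counts.get(a0, zero)
        second_is_minor = (c1a + c2a) <= (c1r + c2r)
        return (np.where(second_is_minor, c1a, c1r),
                np.where(second_is_minor, c2a, c2r))
    c1 = np.stack([counts_platform1.allele_counts.get(a, zero)
                   for a in alleles])
    c2 = np.stack([counts_platform2.allele_counts.get(a, zero)
                   for a in alleles])
    total = c1 + c2
    idx = np.arange(L)
    major = np.argmax(total, axis=0)
    rest = total.copy()
    rest[major, idx] = -1
    variant = np.argmax(rest, axis=0)
    return c1[variant, idx], c2[variant, idx]


def call_segregating_sites(
    counts_platform1: PlatformSiteCounts,
    counts_platform2: PlatformSiteCounts,
    min_coverage_per_platform: int = 6,
    scheme: str = "s_gt1",
    n_lineages: Optional[int] = None,
) -> SegregatingSiteSet:
    """Call segregating sites from the two platform tables of one pool.

    A site is callable iff its depth reaches ``min_coverage_per_platform``
    on both platforms; it is segregating under scheme ``s`` / ``s_gt1`` /
    ``s_gt2`` iff the variant allele has at least 1 / 2 / 3 reads on *both*
    platforms.
    """
    if counts_platform1.length != counts_platform2.length or \
            counts_platform1.chrom != counts_platform2.chrom:
        raise ValueError("platform tables cover different coordinates")
    if counts_platform1.length == 0:
        raise ValueError("empty input")
    if min_coverage_per_platform < 1:
        raise ValueError("min_coverage_per_platform must be >= 1")
    if scheme.lower() not in SCHEME_THRESHOLDS:
        raise ValueError(f"unknown scheme {scheme!r}")
    v1, v2 = _variant_counts(counts_platform1, counts_platform2)
    return SegregatingSiteSet(
        taxon=counts_platform1.taxon,
        chrom=counts_platform1.chrom,
        length=counts_platform1.length,
        n_lineages=n_lineages,
        depth1=np.asarray(counts_platform1.depth),
        depth2=np.asarray(counts_platform2.depth),
        variant1=v1,
        variant2=v2,
        min_coverage=int(min_coverage_per_platform),
        scheme=scheme.lower(),
    )


@dataclass
class WindowDiversity:
    chrom: str
    start: int
    end: int
    theta_per_kb: float
    callable_sites: int


@dataclass
class RegionCall:
    chrom: str
    start: int
    end: int
    median_theta: float
    n_windows: int
    low: bool


def sliding_window_theta(
    site_set: SegregatingSiteSet,
    window: int = 100_000,
    step: int = 10_000,
    min_callable: int = 10_000,
    min_read_depth: int = 4,
    n_lineages: Optional[int] = None,
) -> List[WindowDiversity]:
    """Watterson theta in sliding windows.

    A site enters a window when its depth reaches ``min_read_depth`` on
    both platforms; windows with fewer than ``min_callable`` such sites are
    omitted, as are windows extending past the chromosome end.  Window
    theta uses the window's segregating-site count (scheme of the site set)
    over its callable length.
    """
    if window < step:
        raise ValueError("window must be >= step")
    if min_callable < 0 or min_read_depth < 0:
        raise ValueError("thresholds must be >= 0")
    n = n_lineages if n_lineages is not None else site_set.n_lineages
    if n is None:
        raise ValueError("n_lineages required")
    ok = (site_set.depth1 >= min_read_depth) & \
         (site_set.depth2 >= min_read_depth)
    seg = site_set.segregating_mask() & ok
    cum_ok = np.concatenate([[0], np.cumsum(ok)])
    cum_seg = np.concatenate([[0], np.cumsum(seg)])
    out: List[WindowDiversity] = []
    start = 0
    while start + window <= site_set.length:
        L = int(cum_ok[start + window] - cum_ok[start])
        if L >= min_callable:
            s = int(cum_seg[start + window] - cum_seg[start])
            out.append(WindowDiversity(
                site_set.chrom, start, start + window,
                watterson_theta(s, n, L), L))
        start += step
    return out


def region_median_theta(
    windows: Sequence[WindowDiversity],
    cutoff: float,
    tile: int = 10_000,
    min_windows: int = 4,
) -> List[RegionCall]:
    """Median window theta per tile of ``tile`` bp.

    A tile is covered by every emitted window that fully contains it; tiles
    with fewer than ``min_windows`` covering windows are dropped, and a
    covered tile is flagged low iff its median theta is strictly below the
    cutoff.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    per_tile: Dict[Tuple[str, int], List[float]] = {}
    for w in windows:
        first = (w.start + tile - 1) // tile
        last = w.end // tile  # exclusive
        for t in range(first, last):
            per_tile.setdefault((w.chrom, t), []).append(w.theta_per_kb)
    out: List[RegionCall] = []
    for (chrom, t), thetas in sorted(per_tile.items()):
        if len(thetas) < min_windows:
            continue
        med = float(np.median(thetas))
        out.append(RegionCall(chrom, t * tile, (t + 1) * tile, med,
                              len(thetas), med < cutoff))
    return out


def windows_to_frame(windows: Sequence[WindowDiversity]) -> pd.DataFrame:
    return pd.DataFrame(
        [(w.chrom, w.start, w.end, w.theta_per_kb, w.callable_sites)
         for w in windows],
        columns=["chrom", "start", "end", "theta_per_kb", "callable_sites"])


def regions_to_frame(regions: Sequence[RegionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.chrom, r.start, r.end, r.median_theta, r.n_windows, int(r.low))
         for r in regions],
        columns=["chrom", "start", "end", "theta_per_kb", "n_windows",
                 "low_flag"])
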
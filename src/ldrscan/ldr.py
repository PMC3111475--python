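"""Low-diversity-region (LDR) detection.

The low-diversity cutoff is calibrated by whole-genome shuffling: the
genome is broken into 1 kb units, the units are permuted (by default
genome-wide across chromosomes) 200 times, and for each shuffled genome the
minimum 100 kb-window theta is recorded.  The 10th smallest of the 200
minima is the cutoff, so only 5% of neutral-shuffle genomes contain any
window below it.  Maximal runs of adjacent low 10 kb tiles form LDR
contigs, which are size-classified and intersected between taxa to give
overlapping LDRs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .diversity import RegionCall, SegregatingSiteSet, harmonic_number

SIZE_BINS: Tuple[Tuple[float, float, str], ...] = (
    (0, 100_000, "<100"),
    (100_000, 200_000, "100-200"),
    (200_000, 300_000, "200-300"),
    (300_000, 400_000, "300-400"),
    (400_000, 500_000, "400-500"),
    (500_000, 600_000, "500-600"),
    (600_000, math.inf, ">=600"),
)


def size_class(size_bp: int) -> str:
    """Size bin label; bins are left-closed right-open in bp, so every
    size maps to exactly one bin."""
    for lo, hi, label in SIZE_BINS:
        if lo <= size_bp < hi:
            return label
    raise ValueError("negative size")


@dataclass
class ShuffleCutoff:
    theta_min: np.ndarray  # per-shuffle minimum window theta
    n_shuffles: int
    rank: int

    def __post_init__(self) -> None:
        self.theta_min = np.asarray(self.theta_min, dtype=float)
        if self.rank > self.n_shuffles or self.rank < 1:
            raise ValueError("need 1 <= rank <= n_shuffles")
        if self.theta_min.size != self.n_shuffles:
            raise ValueError("theta_min length must equal n_shuffles")

    @property
    def cutoff(self) -> float:
        return float(np.sort(self.theta_min)[self.rank - 1])

    @property
    def significance(self) -> float:
        """Empirical probability that a neutral shuffle reaches the cutoff
        (rank / n_shuffles; 10 of 200 gives P = 0.05)."""
        return self.rank / self.n_shuffles


def shuffle_cutoff(
    site_sets: Sequence[SegregatingSiteSet],
    unit: int = 1000,
    n_shuffles: int = 200,
    rank: int = 10,
    window: int = 100_000,
    step: int = 10_000,
    min_callable: int = 10_000,
    min_read_depth: int = 4,
    n_lineages: Optional[int] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    per_chromosome: bool = False,
) -> ShuffleCutoff:
    """Shuffle-calibrated low-diversity cutoff for one taxon.

    ``site_sets`` holds one called site set per chromosome.  Each shuffle
    uniformly permutes the genome's 1 kb units (within chromosomes instead
    when ``per_chromosome``), re-cuts them into the original chromosome
    lengths, and records the smallest emitted 100 kb-window theta, applying
    the same callable-window rule as the real scan.  Trailing sub-unit
    chromosome remainders are excluded from the unit pool.
    """
    if isinstance(site_sets, SegregatingSiteSet):
        site_sets = [site_sets]
    if rank > n_shuffles or rank < 1:
        raise ValueError("need 1 <= rank <= n_shuffles")
    if window % unit or step % unit or window < step:
        raise ValueError("unit must divide window and step; window >= step")
    n = n_lineages if n_lineages is not None else site_sets[0].n_lineages
    if n is None:
        raise ValueError("n_lineages required")
    a_n = harmonic_number(n - 1)
    win_u = window // unit
    step_u = step // unit

    unit_s: List[np.ndarray] = []
    unit_l: List[np.ndarray] = []
    chrom_units: List[int] = []
    for ss in site_sets:
        n_u = ss.length // unit
        if per_chromosome and n_u < win_u:
            raise ValueError("chromosome shorter than one window")
        ok = (ss.depth1 >= min_read_depth) & (ss.depth2 >= min_read_depth)
        seg = ss.segregating_mask() & ok
        m = n_u * unit
        unit_l.append(np.add.reduceat(ok[:m], np.arange(0, m, unit)))
        unit_s.append(np.add.reduceat(seg[:m], np.arange(0, m, unit)))
        chrom_units.append(n_u)
    if sum(chrom_units) < win_u:
        raise ValueError("genome shorter than one window")
    s_all = np.concatenate(unit_s).astype(np.int64)
    l_all = np.concatenate(unit_l).astype(np.int64)
    if rng is None:
        rng = np.random.default_rng(seed)

    bounds = np.cumsum([0] + chrom_units)
    theta_min = np.empty(n_shuffles)
    for rep in range(n_shuffles):
        if per_chromosome:
            perm = np.concatenate([
                bounds[i] + rng.permutation(chrom_units[i])
                for i in range(len(chrom_units))
            ])
        else:
            perm = rng.permutation(s_all.size)
        s_p = s_all[perm]
        l_p = l_all[perm]
        best = math.inf
        for i in range(len(chrom_units)):
            cs = np.concatenate([[0], np.cumsum(s_p[bounds[i]:bounds[i + 1]])])
            cl = np.concatenate([[0], np.cumsum(l_p[bounds[i]:bounds[i + 1]])])
            starts = np.arange(0, chrom_units[i] - win_u + 1, step_u)
            if starts.size == 0:
                continue
            L = cl[starts + win_u] - cl[starts]
            S = cs[starts + win_u] - cs[starts]
            emitted = L >= min_callable
            if emitted.any():
                theta = 1000.0 * S[emitted] / (a_n * L[emitted])
                best = min(best, float(theta.min()))
        theta_min[rep] = best
    return ShuffleCutoff(theta_min=theta_min, n_shuffles=n_shuffles,
                         rank=rank)


@dataclass
class LDRContig:
    taxon: str
    chrom: str
    start: int
    end: int

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def size_class(self) -> str:
        return size_class(self.size)


def detect_ldr_contigs(
    region_calls: Sequence[RegionCall],
    cutoff: float,
    taxon: str = "",
) -> List[LDRContig]:
    """Merge maximal runs of adjacent low tiles into LDR contigs.

    Tiles dropped by the coverage rule are absent from ``region_calls`` and
    therefore break runs; contigs never span chromosomes.
    """
    contigs: List[LDRContig] = []
    current: Optional[LDRContig] = None
    for rc in sorted(region_calls, key=lambda r: (r.chrom, r.start)):
        if rc.median_theta < cutoff:
            if (current is not None and current.chrom == rc.chrom
                    and current.end == rc.start):
                current.end = rc.end
            else:
                current = LDRContig(taxon, rc.chrom, rc.start, rc.end)
                contigs.append(current)
        else:
            current = None
    return contigs


@dataclass
class SizeClassSummary:
    counts: Dict[str, int]
    pct_genome_below_200kb: float
    pct_genome_at_least_200kb: float


def size_classify(
    contigs: Sequence[LDRContig],
    genome_size: int,
) -> SizeClassSummary:
    """Contig counts per size bin and LDR genome fractions (percent) below
    and at or above 200 kb."""
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    counts = {label: 0 for _, _, label in SIZE_BINS}
    small = large = 0
    for c in contigs:
        counts[c.size_class] += 1
        if c.size < 200_000:
            small += c.size
        else:
            large += c.size
    return SizeClassSummary(
        counts=counts,
        pct_genome_below_200kb=100.0 * small / genome_size,
        pct_genome_at_least_200kb=100.0 * large / genome_size,
    )


Interval = Tuple[str, int, int]


def overlap_ldrs(
    contigs_a: Sequence[LDRContig],
    contigs_b: Sequence[LDRContig],
) -> List[Interval]:
    """Intersections of two taxa's LDR contigs (overlapping LDRs), merged
    when adjacent; empty intersections are omitted."""
    def as_sorted(contigs):
        return sorted(((c.chrom, c.start, c.end) for c in contigs))

    a = as_sorted(contigs_a)
    b = as_sorted(contigs_b)
    out: List[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        ca, sa, ea = a[i]
        cb, sb, eb = b[j]
        if ca != cb:
            if ca < cb:
                i += 1
            else:
                j += 1
            continue
        lo, hi = max(sa, sb), min(ea, eb)
        if lo < hi:
            if out and out[-1][0] == ca and out[-1][2] >= lo:
                out[-1] = (ca, out[-1][1], max(out[-1][2], hi))
            else:
                out.append((ca, lo, hi))
        if ea <= eb:
            i += 1
        else:
            j += 1
    return out


def bottom_fraction_ldrs(
    region_calls: Sequence[RegionCall],
    fraction: float = 0.05,
) -> List[RegionCall]:
    """The retained tiles with the lowest median theta, totalling the given
    fraction of all retained tiles (ties broken by coordinate)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    k = int(math.floor(fraction * len(region_calls) + 1e-9))
    ranked = sorted(region_calls,
                    key=lambda r: (r.median_theta, r.chrom, r.start))
    return ranked[:k]
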
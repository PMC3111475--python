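"""Coalescent generator for three-taxon pooled-sequencing experiments.

Emulates the data underlying a domestication scan of two selfing cultivars
(``I``, ``J``) and their outcrossing wild progenitor (``R``):

* genealogies are simulated under an *independent* (both cultivars derived
  separately from the wild taxon at time ``T_d``) or *sequential* (a single
  domestication episode at ``T_d'`` followed by an I/J split) demographic
  model;
* the coalescent is split into two phases.  From the present back to
  domestication, selfing suppresses recombination and every sub-segment of a
  locus shares one genealogy.  Beyond domestication the wild population
  recombines freely, which is approximated by partitioning the locus into
  non-recombining sub-segments whose ancestral genealogies are conditionally
  independent given the lineages surviving at the domestication time;
* infinite-sites mutations are overlaid on the genealogy;
* selective sweeps spread by introgression are injected by copying one donor
  haplotype over a region;
* pooled sequencing on two error-prone platforms is emulated with Poisson
  coverage and independent per-platform substitution errors.

All times are in units of ``4*N_R`` generations and ``theta = 4*N_R*mu`` per
site (the usual ``ms`` convention).  Population sizes are haploid-lineage
counts; only the ratios ``N_I/N_R`` and ``N_J/N_R`` enter the rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .candidates import GeneModel

INDEPENDENT = "independent"
SEQUENTIAL = "sequential"

#: default haploid lineage counts: selfing cultivars contribute one lineage
#: per accession, the outcrossing wild taxon two per accession.
DEFAULT_SAMPLE_SIZES: Dict[str, int] = {"J": 21, "I": 22, "R": 46}

DEFAULT_PLATFORMS: Tuple[str, str] = ("GA", "SOLiD")


# ---------------------------------------------------------------------------
# demographic model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DemographicModel:
    """Three-taxon domestication demography.

    Parameters
    ----------
    topology:
        ``"independent"`` (I and J domesticated separately from R at
        ``t_d``) or ``"sequential"`` (one domestication at ``t_d_prime``;
        I and J split afterwards at ``t_split``).
    n_r, n_i, n_j:
        Population sizes in haploid-lineage units; ``n_r`` sets the time
        scale, so the defaults are expressed relative to ``n_r = 1``.  The
        J default reproduces the observed severe diversity loss of that
        cultivar; the I default is a compromise (see docs/methods.md): a
        single-epoch founder model cannot give I both near-wild diversity
        and the appreciable per-site wild/cultivar differentiation the
        conditional Fst analysis relies on, so a moderate bottleneck is
        used.
    t_mrca:
        Illustrative time of the most recent common ancestor of the three
        taxa; must exceed the domestication time.  The ancestral population
        coalesces freely, so ``t_mrca`` only bounds validation.
    t_d, t_d_prime:
        Domestication time of the active topology; exactly one must be set.
    t_split:
        Sequential topology only: the (more recent) I/J split time,
        ``0 < t_split < t_d_prime``.  Defaults to ``t_d_prime / 2``.
    n_c:
        Size of the common cultivar population between ``t_split`` and
        ``t_d_prime`` (sequential topology); defaults to ``n_i``.
    selfing_rate:
        Post-domestication selfing fraction; effective recombination after
        domestication is ``recomb_rate * (1 - selfing_rate)``.
    recomb_rate:
        Scaled per-site recombination rate ``rho = 4*N_R*r`` in the wild
        (pre-domestication) phase.
    mut_rate_theta:
        Scaled per-site mutation rate ``theta = 4*N_R*mu``.
    """

    topology: str = INDEPENDENT
    n_r: float = 1.0
    n_i: float = 0.05
    n_j: float = 0.015
    t_mrca: float = 1.0
    t_d: Optional[float] = 0.01
    t_d_prime: Optional[float] = None
    t_split: Optional[float] = None
    n_c: Optional[float] = None
    selfing_rate: float = 1.0
    recomb_rate: float = 0.03
    mut_rate_theta: float = 0.004

    def __post_init__(self) -> None:
        if self.topology not in (INDEPENDENT, SEQUENTIAL):
            raise ValueError(f"unknown topology: {self.topology!r}")
        for name in ("n_r", "n_i", "n_j"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.topology == INDEPENDENT:
            if self.t_d is None or self.t_d_prime is not None:
                raise ValueError("independent topology uses t_d only")
        else:
            if self.t_d_prime is None or self.t_d is not None:
                raise ValueError("sequential topology uses t_d_prime only")
            if self.t_split is None:
                object.__setattr__(self, "t_split", self.t_d_prime / 2.0)
            if not 0.0 < self.t_split < self.t_d_prime:
                raise ValueError("need 0 < t_split < t_d_prime")
        if not 0.0 < self.domestication_time < self.t_mrca:
            raise ValueError("need 0 < domestication time < t_mrca")
        if not 0.0 <= self.selfing_rate <= 1.0:
            raise ValueError("selfing_rate must be in [0, 1]")
        if self.recomb_rate < 0 or self.mut_rate_theta < 0:
            raise ValueError("rates must be >= 0")

    @property
    def domestication_time(self) -> float:
        return self.t_d if self.topology == INDEPENDENT else self.t_d_prime

    @property
    def cultivar_size(self) -> float:
        return self.n_c if self.n_c is not None else self.n_i

    @classmethod
    def from_generations(
        cls,
        *,
        topology: str = INDEPENDENT,
        n_r: float,
        n_i: float,
        n_j: float,
        t_mrca_gen: float,
        t_dom_gen: float,
        t_split_gen: Optional[float] = None,
        mu_per_site: float,
        r_per_site: float = 0.0,
        selfing_rate: float = 1.0,
        n_c: Optional[float] = None,
    ) -> "DemographicModel":
        """Build a model from absolute sizes and times in generations.

        The scaled model depends only on size ratios and on times divided by
        ``4*n_r``, so jointly rescaling all sizes and all generation times
        leaves every scaled summary statistic unchanged in distribution.
        """
        scale = 4.0 * n_r
        t_dom = t_dom_gen / scale
        kwargs = dict(
            topology=topology,
            n_r=1.0,
            n_i=n_i / n_r,
            n_j=n_j / n_r,
            t_mrca=t_mrca_gen / scale,
            selfing_rate=selfing_rate,
            recomb_rate=scale * r_per_site,
            mut_rate_theta=scale * mu_per_site,
            n_c=None if n_c is None else n_c / n_r,
        )
        if topology == INDEPENDENT:
            kwargs.update(t_d=t_dom, t_d_prime=None)
        else:
            kwargs.update(
                t_d=None,
                t_d_prime=t_dom,
                t_split=None if t_split_gen is None else t_split_gen / scale,
            )
        return cls(**kwargs)


@dataclass(frozen=True)
class IntrogressionEvent:
    """Transfer of ``[start, end)`` from one taxon into another.

    ``recipient == donor`` models a within-taxon selective sweep (all
    recipient haplotypes are replaced by one donor haplotype).  ``time`` is
    the age of the transfer in ``4*N_R`` units and controls the amount of
    post-transfer mutation accumulated on the recipient copies; it must
    predate domestication of both taxa for the scenario to be coherent.
    """

    donor: str
    recipient: str
    start: int
    end: int
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.end <= self.start or self.start < 0:
            raise ValueError("need 0 <= start < end")
        if self.time < 0:
            raise ValueError("time must be >= 0")


# ---------------------------------------------------------------------------
# genealogies
# ---------------------------------------------------------------------------

@dataclass
class SegmentGenealogy:
    """Genealogy of one non-recombining sub-segment ``[start, end)``.

    Edges are stored as (descendant-leaf bitmask, branch length) pairs; the
    root edge is omitted.
    """

    start: int
    end: int
    masks: List[int]
    lengths: np.ndarray

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())


@dataclass
class LocusGenealogy:
    taxa: Dict[str, int]
    locus_length: int
    segments: List[SegmentGenealogy]

    @property
    def n_total(self) -> int:
        return sum(self.taxa.values())


def _coalesce_epoch(lineages, rel_size, t, t_end, rng, masks, lengths):
    """Coalesce ``lineages`` (list of ``(mask, birth_time)``) at the Kingman
    rate ``k(k-1)/rel_size`` from ``t`` until ``t_end`` (``None`` = MRCA)."""
    k = len(lineages)
    while k >= 2:
        wait = rng.exponential(rel_size / (k * (k - 1)))
        if t_end is not None and t + wait > t_end:
            return t_end
        t += wait
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        mi, ti = lineages[i]
        mj, tj = lineages[j]
        masks.append(mi)
        lengths.append(t - ti)
        masks.append(mj)
        lengths.append(t - tj)
        lineages[i] = (mi | mj, t)
        lineages[j] = lineages[-1]
        lineages.pop()
        k -= 1
    return t if t_end is None else t_end


def _geometric_breakpoints(length: int, mean_bp: float, rng) -> List[int]:
    if not math.isfinite(mean_bp) or mean_bp <= 0:
        return []
    cuts: List[int] = []
    x = rng.exponential(mean_bp)
    while x < length:
        pos = int(x)
        if 0 < pos < length and (not cuts or pos > cuts[-1]):
            cuts.append(pos)
        x += rng.exponential(mean_bp)
    return cuts


def _phase1_forest(model, taxa, rng):
    """Simulate the shared selfing-phase forest from the present back to the
    domestication time.  Returns (closed edges, surviving lineages)."""
    masks: List[int] = []
    lengths: List[float] = []
    pops: Dict[str, list] = {}
    offset = 0
    for taxon, n in taxa.items():
        pops[taxon] = [(1 << (offset + i), 0.0) for i in range(n)]
        offset += n
    rel = {"R": model.n_r, "I": model.n_i, "J": model.n_j}
    t_dom = model.domestication_time
    if model.topology == INDEPENDENT:
        for taxon, lin in pops.items():
            _coalesce_epoch(lin, rel.get(taxon, model.n_r), 0.0, t_dom,
                            rng, masks, lengths)
    else:
        t_split = model.t_split
        for taxon, lin in pops.items():
            _coalesce_epoch(lin, rel.get(taxon, model.n_r), 0.0, t_split,
                            rng, masks, lengths)
        cultivar = pops.pop("I", []) + pops.pop("J", [])
        if cultivar:
            _coalesce_epoch(cultivar, model.cultivar_size, t_split, t_dom,
                            rng, masks, lengths)
            pops["IJ"] = cultivar
        for taxon, lin in list(pops.items()):
            if taxon not in ("IJ",):
                _coalesce_epoch(lin, rel.get(taxon, model.n_r), t_split,
                                t_dom, rng, masks, lengths)
    survivors = [lin for lin_list in pops.values() for lin in lin_list]
    return masks, lengths, survivors


def two_phase_genealogy(
    model: DemographicModel,
    locus_length: int,
    taxon_sample_sizes: Mapping[str, int] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    mean_segment_bp: Optional[float] = None,
) -> LocusGenealogy:
    """Two-phase coalescent for one locus.

    Phase 1 runs from the present to the domestication time with selfing-
    suppressed recombination: with the default ``selfing_rate = 1`` every
    sub-segment shares one genealogical history below the domestication
    time.  Phase 2 partitions the locus into geometrically spaced
    non-recombining sub-segments (mean spacing
    ``1 / (recomb_rate * t_dom)`` unless ``mean_segment_bp`` is given) and
    coalesces the surviving lineages independently per sub-segment in the
    ancestral wild population.
    """
    if locus_length <= 0:
        raise ValueError("locus_length must be positive")
    if taxon_sample_sizes is None:
        taxon_sample_sizes = DEFAULT_SAMPLE_SIZES
    taxa = {t: int(n) for t, n in taxon_sample_sizes.items() if n > 0}
    if not taxa or any(n < 1 for n in taxa.values()):
        raise ValueError("need at least one taxon with >= 1 sample")
    if rng is None:
        rng = np.random.default_rng(seed)
    t_dom = model.domestication_time
    if mean_segment_bp is None:
        mean_segment_bp = (
            1.0 / (model.recomb_rate * t_dom) if model.recomb_rate > 0
            else math.inf
        )
    # phase-1 blocks: residual recombination while selfing
    eff_r = model.recomb_rate * (1.0 - model.selfing_rate)
    block_mean = 1.0 / (eff_r * t_dom) if eff_r > 0 else math.inf
    block_cuts = _geometric_breakpoints(locus_length, block_mean, rng)
    block_bounds = [0] + block_cuts + [locus_length]

    segments: List[SegmentGenealogy] = []
    for b0, b1 in zip(block_bounds[:-1], block_bounds[1:]):
        p1_masks, p1_lengths, survivors = _phase1_forest(model, taxa, rng)
        seg_cuts = _geometric_breakpoints(b1 - b0, mean_segment_bp, rng)
        seg_bounds = [b0] + [b0 + c for c in seg_cuts] + [b1]
        for s0, s1 in zip(seg_bounds[:-1], seg_bounds[1:]):
            masks = list(p1_masks)
            lengths = list(p1_lengths)
            _coalesce_epoch(list(survivors), model.n_r, t_dom, None,
                            rng, masks, lengths)
            segments.append(
                SegmentGenealogy(s0, s1, masks, np.asarray(lengths)))
    return LocusGenealogy(taxa=dict(taxa), locus_length=locus_length,
                          segments=segments)


# ---------------------------------------------------------------------------
# haplotypes
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeSample:
    """0/1 haplotype matrix at segregating positions of one locus.

    Rows are haplotypes grouped by taxon in the order of ``taxa``; columns
    correspond to the strictly increasing ``positions`` (0-based offsets
    within ``[0, locus_length)``).
    """

    taxa: Dict[str, int]
    positions: np.ndarray
    matrix: np.ndarray
    locus_length: int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.shape != (self.n_total, self.positions.size):
            raise ValueError("matrix shape does not match taxa/positions")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_total(self) -> int:
        return sum(self.taxa.values())

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    def taxon_slice(self, taxon: str) -> slice:
        start = 0
        for t, n in self.taxa.items():
            if t == taxon:
                return slice(start, start + n)
            start += n
        raise KeyError(taxon)

    def taxon_matrix(self, taxon: str) -> np.ndarray:
        return self.matrix[self.taxon_slice(taxon)]

    def drop_monomorphic(self) -> "HaplotypeSample":
        counts = self.matrix.sum(axis=0)
        keep = (counts > 0) & (counts < self.n_total)
        return HaplotypeSample(self.taxa, self.positions[keep],
                               self.matrix[:, keep], self.locus_length)


def _mask_rows(mask: int, n: int) -> np.ndarray:
    return np.array([i for i in range(n) if (mask >> i) & 1], dtype=np.intp)


def overlay_mutations(
    genealogy: LocusGenealogy,
    mut_rate_theta: float,
    locus_length: Optional[int] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> HaplotypeSample:
    """Drop infinite-sites mutations on a genealogy.

    Mutation counts per sub-segment are Poisson with mean
    ``theta_site * segment_bp * total_branch_length`` (branch lengths in
    ``4*N_R`` units), each mutation landing on an edge with probability
    proportional to its length and at a distinct uniform position.
    """
    if mut_rate_theta < 0:
        raise ValueError("mut_rate_theta must be >= 0")
    if locus_length is None:
        locus_length = genealogy.locus_length
    if rng is None:
        rng = np.random.default_rng(seed)
    n = genealogy.n_total
    all_pos: List[np.ndarray] = []
    all_cols: List[np.ndarray] = []
    edge_assign: List[Tuple[SegmentGenealogy, np.ndarray]] = []
    for seg in genealogy.segments:
        span = seg.end - seg.start
        lam = mut_rate_theta * span * seg.total_length
        nmut = int(rng.poisson(lam)) if lam > 0 else 0
        if nmut == 0:
            continue
        nmut = min(nmut, span)  # infinite-sites cap on distinct positions
        probs = seg.lengths / seg.lengths.sum()
        edges = rng.choice(len(seg.masks), size=nmut, p=probs)
        pos = seg.start + rng.choice(span, size=nmut, replace=False)
        order = np.argsort(pos)
        all_pos.append(pos[order])
        edge_assign.append((seg, edges[order]))
    if not all_pos:
        return HaplotypeSample(genealogy.taxa, np.empty(0, dtype=np.int64),
                               np.empty((n, 0), dtype=np.uint8), locus_length)
    positions = np.concatenate(all_pos)
    matrix = np.zeros((n, positions.size), dtype=np.uint8)
    col0 = 0
    for seg, edges in edge_assign:
        for e in np.unique(edges):
            rows = _mask_rows(seg.masks[e], n)
            cols = col0 + np.flatnonzero(edges == e)
            matrix[rows[:, None], cols] = 1
        col0 += edges.size
    sample = HaplotypeSample(genealogy.taxa, positions, matrix, locus_length)
    return sample.drop_monomorphic()


def simulate_locus(
    model: DemographicModel,
    locus_length: int,
    taxon_sample_sizes: Mapping[str, int] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    mean_segment_bp: Optional[float] = None,
) -> HaplotypeSample:
    """Convenience wrapper: genealogy plus mutation overlay."""
    if rng is None:
        rng = np.random.default_rng(seed)
    gen = two_phase_genealogy(model, locus_length, taxon_sample_sizes,
                              rng=rng, mean_segment_bp=mean_segment_bp)
    return overlay_mutations(gen, model.mut_rate_theta, rng=rng)


# ---------------------------------------------------------------------------
# sweeps and introgression
# ---------------------------------------------------------------------------

def inject_sweep_introgression(
    sample: HaplotypeSample,
    event: IntrogressionEvent,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    donor_index: Optional[int] = None,
    mut_rate_theta: float = 0.0,
) -> HaplotypeSample:
    """Replace recipient haplotypes by one donor haplotype within a region.

    Inside ``[event.start, event.end)`` every recipient haplotype becomes a
    copy of a single donor haplotype (a hard selective sweep of the
    introgressed segment); sites outside the region are untouched.  With
    ``mut_rate_theta > 0`` and ``event.time > 0``, post-transfer mutations
    are added privately to each recipient copy at rate
    ``theta_site * region_bp * time`` per haplotype.
    """
    if event.end > sample.locus_length:
        raise ValueError("event region outside locus")
    if rng is None:
        rng = np.random.default_rng(seed)
    donor_rows = sample.taxon_slice(event.donor)
    recip_rows = sample.taxon_slice(event.recipient)
    if donor_index is None:
        donor_index = int(rng.integers(donor_rows.stop - donor_rows.start))
    donor_row = donor_rows.start + donor_index
    in_region = (sample.positions >= event.start) & \
                (sample.positions < event.end)
    matrix = sample.matrix.copy()
    cols = np.flatnonzero(in_region)
    matrix[recip_rows][:, cols] = sample.matrix[donor_row, cols][None, :]
    positions = sample.positions
    if mut_rate_theta > 0 and event.time > 0:
        new_pos: List[int] = []
        new_rows: List[int] = []
        lam = mut_rate_theta * (event.end - event.start) * event.time
        existing = set(positions.tolist())
        for row in range(recip_rows.start, recip_rows.stop):
            for _ in range(int(rng.poisson(lam))):
                p = int(event.start +
                        rng.integers(event.end - event.start))
                if p in existing:
                    continue
                existing.add(p)
                new_pos.append(p)
                new_rows.append(row)
        if new_pos:
            extra = np.zeros((sample.n_total, len(new_pos)), dtype=np.uint8)
            extra[new_rows, np.arange(len(new_pos))] = 1
            positions = np.concatenate([positions, np.array(new_pos)])
            matrix = np.concatenate([matrix, extra], axis=1)
            order = np.argsort(positions)
            positions = positions[order]
            matrix = matrix[:, order]
    out = HaplotypeSample(sample.taxa, positions, matrix,
                          sample.locus_length)
    return out.drop_monomorphic()


def inject_shared_sweep(
    sample: HaplotypeSample,
    start: int,
    end: int,
    donor: str = "I",
    recipients: Sequence[str] = ("I", "J"),
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> HaplotypeSample:
    """Sweep one donor haplotype through several taxa over ``[start, end)``.

    Models a segment selected in the donor subspecies and introgressed into
    the other cultivar: the same donor haplotype replaces all haplotypes of
    every recipient taxon, so the region is a low-diversity region in both
    cultivars and identical between them.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    donor_slice = sample.taxon_slice(donor)
    donor_index = int(rng.integers(donor_slice.stop - donor_slice.start))
    out = sample
    for recipient in recipients:
        out = inject_sweep_introgression(
            out, IntrogressionEvent(donor, recipient, start, end),
            rng=rng, donor_index=donor_index)
        # the donor haplotype keeps its row content, so the same index
        # remains valid across successive injections
    return out


def plant_divergent_site(
    sample: HaplotypeSample,
    pos: int,
    derived_taxa: Sequence[str] = ("I", "J"),
) -> HaplotypeSample:
    """Insert a site fixed for the derived allele in ``derived_taxa`` and
    for the ancestral allele elsewhere (an (I, J)-versus-R diagnostic
    site)."""
    if not 0 <= pos < sample.locus_length:
        raise ValueError("pos outside locus")
    if pos in set(sample.positions.tolist()):
        raise ValueError("position already segregating")
    col = np.zeros((sample.n_total, 1), dtype=np.uint8)
    for taxon in derived_taxa:
        col[sample.taxon_slice(taxon)] = 1
    positions = np.concatenate([sample.positions, [pos]])
    matrix = np.concatenate([sample.matrix, col], axis=1)
    order = np.argsort(positions)
    return HaplotypeSample(sample.taxa, positions[order], matrix[:, order],
                           sample.locus_length)


# ---------------------------------------------------------------------------
# pooled platform reads
# ---------------------------------------------------------------------------

@dataclass
class PlatformSiteCounts:
    """Per-site allele read counts for one taxon pool on one platform.

    ``allele_counts`` maps allele label to a dense array over every site of
    the locus (length ``length``); monomorphic sites simply have zero
    counts for the non-reference allele.
    """

    taxon: str
    platform: str
    chrom: str
    length: int
    allele_counts: Dict[str, np.ndarray]

    @property
    def depth(self) -> np.ndarray:
        out = np.zeros(self.length, dtype=np.int64)
        for arr in self.allele_counts.values():
            out = out + arr
        return out


def simulate_pooled_platform_reads(
    sample: HaplotypeSample,
    mean_coverage: float = 30.0,
    error_rate_per_platform: Sequence[float] = (0.005, 0.005),
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    platforms: Sequence[str] = DEFAULT_PLATFORMS,
    chrom: str = "chr1",
    exact: bool = False,
) -> Dict[str, Tuple[PlatformSiteCounts, ...]]:
    """Emulate pooled sequencing of each taxon on two platforms.

    Per site and platform the read depth is Poisson(``mean_coverage``); each
    read is drawn from the pool's haplotype frequencies and then flipped
    independently with the platform's substitution error rate (errors are
    independent between platforms, the property that the combined-platform
    singleton filter exploits).  With ``exact=True`` each haplotype
    contributes exactly one error-free read per platform, i.e. observed
    counts equal haplotype counts — the sequencing-noise-free limit used by
    estimator-recovery checks.
    """
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be > 0")
    errs = tuple(error_rate_per_platform)
    if len(errs) != len(platforms):
        raise ValueError("one error rate per platform required")
    if any(not 0.0 <= e < 1.0 for e in errs):
        raise ValueError("error rates must be in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    L = sample.locus_length
    out: Dict[str, Tuple[PlatformSiteCounts, ...]] = {}
    for taxon, n_t in sample.taxa.items():
        sub = sample.taxon_matrix(taxon)
        alt_n = np.zeros(L, dtype=np.int64)
        if sample.n_sites:
            alt_n[sample.positions] = sub.sum(axis=0)
        tables = []
        for platform, err in zip(platforms, errs):
            if exact:
                depth = np.full(L, n_t, dtype=np.int64)
                alt = alt_n.copy()
            else:
                depth = rng.poisson(mean_coverage, size=L)
                true_alt = rng.binomial(depth, alt_n / n_t)
                if err > 0:
                    alt = (rng.binomial(true_alt, 1.0 - err)
                           + rng.binomial(depth - true_alt, err))
                else:
                    alt = true_alt
            tables.append(PlatformSiteCounts(
                taxon=taxon, platform=platform, chrom=chrom, length=L,
                allele_counts={"0": depth - alt, "1": alt}))
        out[taxon] = tuple(tables)
    return out


# ---------------------------------------------------------------------------
# multi-locus genomes
# ---------------------------------------------------------------------------

@dataclass
class GenomeDataset:
    """A genome assembled from independently simulated loci.

    Loci are laid out consecutively on one chromosome; ``introgressed``
    lists the indices of loci carrying the shared (two-history) sweep and
    ``planted_sites`` any diagnostic sites planted for the candidate
    screen, as ``(locus_index, position_within_locus)``.
    """

    loci: List[HaplotypeSample]
    locus_length: int
    model: DemographicModel
    introgressed: List[int] = field(default_factory=list)
    planted_sites: List[Tuple[int, int]] = field(default_factory=list)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def genome_length(self) -> int:
        return self.n_loci * self.locus_length

    def introgressed_intervals(self) -> List[Tuple[int, int]]:
        """Merged genome coordinates of the injected loci."""
        out: List[Tuple[int, int]] = []
        for idx in sorted(self.introgressed):
            start = idx * self.locus_length
            end = start + self.locus_length
            if out and out[-1][1] == start:
                out[-1] = (out[-1][0], end)
            else:
                out.append((start, end))
        return out


def simulate_genome(
    model: DemographicModel,
    n_loci: int,
    locus_length: int = 10_000,
    taxon_sample_sizes: Mapping[str, int] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    mean_segment_bp: Optional[float] = None,
) -> GenomeDataset:
    """Simulate ``n_loci`` independent loci under one demographic history."""
    if rng is None:
        rng = np.random.default_rng(seed)
    loci = [
        simulate_locus(model, locus_length, taxon_sample_sizes, rng=rng,
                       mean_segment_bp=mean_segment_bp)
        for _ in range(n_loci)
    ]
    return GenomeDataset(loci=loci, locus_length=locus_length, model=model)


def make_two_history_genome(
    model: DemographicModel,
    n_loci: int,
    locus_length: int = 10_000,
    n_spans: int = 10,
    span_loci: int = 1,
    taxon_sample_sizes: Mapping[str, int] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    donor: str = "I",
    mean_segment_bp: Optional[float] = None,
) -> GenomeDataset:
    """Genome with a single-history background plus shared introgressed LDRs.

    The background follows ``model`` (independent domestication by
    default); ``n_spans`` runs of ``span_loci`` consecutive loci each are
    overwritten with a shared sweep (one donor haplotype fixed in both
    cultivars), giving those regions a second, sequential-like history.
    """
    if n_spans * span_loci > n_loci:
        raise ValueError("introgressed spans exceed genome size")
    if rng is None:
        rng = np.random.default_rng(seed)
    dataset = simulate_genome(model, n_loci, locus_length,
                              taxon_sample_sizes, rng=rng,
                              mean_segment_bp=mean_segment_bp)
    # evenly spaced spans keep them non-adjacent so each stays a distinct LDR
    gap = n_loci // n_spans
    starts = [s * gap for s in range(n_spans)]
    injected: List[int] = []
    for s in starts:
        for k in range(span_loci):
            idx = s + k
            dataset.loci[idx] = inject_shared_sweep(
                dataset.loci[idx], 0, locus_length, donor=donor, rng=rng)
            injected.append(idx)
    dataset.introgressed = injected
    return dataset


def pooled_counts_for_genome(
    dataset: GenomeDataset,
    mean_coverage: float = 30.0,
    error_rate_per_platform: Sequence[float] = (0.005, 0.005),
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    chrom: str = "chr1",
    exact: bool = False,
    platforms: Sequence[str] = DEFAULT_PLATFORMS,
) -> Dict[str, Tuple[PlatformSiteCounts, ...]]:
    """Concatenate per-locus pooled read tables into whole-chromosome ones."""
    if rng is None:
        rng = np.random.default_rng(seed)
    taxa = dataset.loci[0].taxa
    G = dataset.genome_length
    errs = tuple(error_rate_per_platform)
    out: Dict[str, Tuple[PlatformSiteCounts, ...]] = {}
    seg_pos = np.concatenate([
        i * dataset.locus_length + locus.positions
        for i, locus in enumerate(dataset.loci) if locus.n_sites
    ]) if dataset.loci else np.empty(0, dtype=np.int64)
    for taxon, n_t in taxa.items():
        seg_alt = np.concatenate([
            locus.taxon_matrix(taxon).sum(axis=0)
            for locus in dataset.loci if locus.n_sites
        ]) if seg_pos.size else np.empty(0, dtype=np.int64)
        tables = []
        for platform, err in zip(platforms, errs):
            if exact:
                depth = np.full(G, n_t, dtype=np.int64)
                alt = np.zeros(G, dtype=np.int64)
                alt[seg_pos] = seg_alt
            else:
                depth = rng.poisson(mean_coverage, size=G)
                # allele sampling only at segregating sites; platform
                # errors genome-wide (scalar-p draws are cheap)
                true_alt = np.zeros(G, dtype=np.int64)
                true_alt[seg_pos] = rng.binomial(depth[seg_pos],
                                                 seg_alt / n_t)
                if err > 0:
                    alt = rng.binomial(depth - true_alt, err)
                    alt[seg_pos] += rng.binomial(true_alt[seg_pos],
                                                 1.0 - err)
                else:
                    alt = true_alt
            tables.append(PlatformSiteCounts(
                taxon=taxon, platform=platform, chrom=chrom, length=G,
                allele_counts={"0": depth - alt, "1": alt}))
        out[taxon] = tuple(tables)
    return out


# ---------------------------------------------------------------------------
# annotation fixtures
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def make_annotation_fixture(
    genome_length: int,
    n_genes: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    chrom: str = "chr1",
    cds_length_range: Tuple[int, int] = (300, 900),
    gene_positions: Optional[Sequence[int]] = None,
) -> Tuple[str, List[GeneModel]]:
    """Random reference sequence plus non-overlapping gene models.

    Genes are placed on alternating strands; every third gene is split into
    two CDS exons (with an intron that is not a multiple of three, so codon
    phase across exons is exercised).  CDS lengths are always divisible by
    three.  ``gene_positions`` optionally pins gene start coordinates.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    base_codes = np.frombuffer(_BASES.encode(), dtype=np.uint8)
    seq = bytes(base_codes[rng.integers(4, size=genome_length)]).decode()
    genes: List[GeneModel] = []
    if n_genes == 0:
        return seq, genes
    lo, hi = cds_length_range
    max_span = hi + 100
    if gene_positions is None:
        slot = genome_length // n_genes
        if slot < max_span + 10:
            raise ValueError("cannot pack genes into genome_length")
        gene_positions = [g * slot + 5 for g in range(n_genes)]
    for g, start in enumerate(gene_positions):
        cds_len = 3 * int(rng.integers(lo // 3, hi // 3 + 1))
        strand = "+" if g % 2 == 0 else "-"
        if g % 3 == 2 and cds_len >= 60:
            split = 3 * int(rng.integers(6, cds_len // 3 - 5)) + 1
            intron = 50
            cds = ((start, start + split),
                   (start + split + intron, start + cds_len + intron))
        else:
            cds = ((start, start + cds_len),)
        if cds[-1][1] > genome_length:
            raise ValueError("cannot pack genes into genome_length")
        genes.append(GeneModel(
            gene_id=f"gene{g:04d}", transcript_id=f"gene{g:04d}.1",
            chrom=chrom, strand=strand, cds=cds))
    return seq, genes
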
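"""Population differentiation: distances, Weir Fst, and the D statistic.

The central question is whether overlapping low-diversity regions of the
two cultivars share one evolutionary history with the genomic background or
carry a second (introgressed) history.  Per-site pairwise Fst is estimated
with the Weir moment (ANOVA) estimator for haploid allele-frequency data;
the empirical CDF of Fst(I, J) inside candidate regions is compared with
the genome background at sites pre-conditioned on strong wild/cultivar
differentiation (Fst(R, I) >= 0.5), and the largest vertical distance
between the two CDFs — a two-sample Kolmogorov–Smirnov statistic, written
D — is calibrated against coalescent simulations of single-history
genomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import synthetic_data as sd
from .diversity import harmonic_number
from .synthetic_data import (DemographicModel, GenomeDataset,
                             HaplotypeSample, PlatformSiteCounts)

TAXA = ("R", "I", "J")
PAIRS = (("I", "J"), ("R", "I"), ("R", "J"))


# ---------------------------------------------------------------------------
# per-site frequencies and Fst
# ---------------------------------------------------------------------------

def weir_fst(p_a, n_a, p_b, n_b, clamp: bool = True):
    """Weir moment estimator of Fst for haploid allele-frequency data.

    Between/within mean-squares form for two populations of ``n_a`` and
    ``n_b`` sampled lineages with allele frequencies ``p_a`` and ``p_b``;
    estimates are clamped into [0, 1] unless ``clamp=False``.  Accepts
    scalars or arrays; a site monomorphic in the pooled pair is undefined
    (NaN for arrays, an error for scalars).
    """
    scalar = np.isscalar(p_a)
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    n_a = np.asarray(n_a, dtype=float)
    n_b = np.asarray(n_b, dtype=float)
    if np.any(n_a < 2) or np.any(n_b < 2):
        raise ValueError("haploid sample sizes must be >= 2")
    n_tot = n_a + n_b
    n_c = n_tot - (n_a ** 2 + n_b ** 2) / n_tot
    p_bar = (n_a * p_a + n_b * p_b) / n_tot
    msp = n_a * (p_a - p_bar) ** 2 + n_b * (p_b - p_bar) ** 2
    msg = (n_a * p_a * (1 - p_a) + n_b * p_b * (1 - p_b)) / (n_tot - 2)
    denom = msp + (n_c - 1) * msg
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(denom > 0, (msp - msg) / np.where(denom > 0, denom, 1),
                       np.nan)
    if clamp:
        fst = np.clip(fst, 0.0, 1.0)
    if scalar:
        fst = float(fst)
        if math.isnan(fst):
            raise ValueError("Fst undefined for a pooled-monomorphic site")
    return fst


def site_frequencies(
    counts_by_taxon: Mapping[str, Sequence[PlatformSiteCounts]],
    min_depth: int = 10,
    chrom: str = "chr1",
    offset: int = 0,
) -> pd.DataFrame:
    """Filtered per-site allele frequencies for the three taxon pools.

    Platforms are combined per taxon.  Sites are dropped unless covered by
    at least ``min_depth`` reads in every taxon, and sites whose minor
    allele appears exactly once in the pooled three-taxon read counts (a
    likely sequencing error) or not at all are discarded.  Frequencies are
    of the pooled-majority allele among the top two pooled alleles.
    """
    taxa = list(counts_by_taxon)
    for t in TAXA:
        if t not in counts_by_taxon:
            raise ValueError(f"missing taxon {t!r}")
    alleles = sorted({a for tabs in counts_by_taxon.values()
                      for tab in tabs for a in tab.allele_counts})
    L = next(iter(counts_by_taxon.values()))[0].length
    zero = np.zeros(L, dtype=np.int64)
    per_taxon = {
        t: [
            sum((tab.allele_counts.get(a, zero)
                 for tab in counts_by_taxon[t]), zero)
            for a in alleles
        ]
        for t in taxa
    }
    pooled = [sum(per_taxon[t][k] for t in taxa)
              for k in range(len(alleles))]
    if len(alleles) == 2:
        major = (pooled[1] > pooled[0]).astype(np.intp)
    else:
        major = np.argmax(np.stack(pooled), axis=0)
    idx = np.arange(L)
    if len(alleles) > 1:
        if len(alleles) == 2:
            variant = 1 - major
        else:
            rest = np.stack(pooled)
            rest[major, idx] = -1
            variant = np.argmax(rest, axis=0)
    else:
        variant = major
    depth = {t: sum(per_taxon[t][k] for k in range(len(alleles)))
             for t in taxa}

    def _pick(arrs, which):
        if len(alleles) == 2:
            return np.where(which == 1, arrs[1], arrs[0])
        return np.stack(arrs)[which, idx]

    maj = {t: _pick(per_taxon[t], major) for t in taxa}
    var = {t: _pick(per_taxon[t], variant) for t in taxa}
    pooled_var = sum(var.values())
    keep = pooled_var >= 2  # discards pooled singletons and monomorphics
    for t in TAXA:
        keep &= depth[t] >= min_depth
        keep &= (maj[t] + var[t]) > 0
    pos = np.flatnonzero(keep)
    data = {"chrom": chrom, "pos": pos + offset}
    for t in TAXA:
        m, v = maj[t][pos], var[t][pos]
        data[f"p_{t}"] = m / (m + v)
        data[f"depth_{t}"] = depth[t][pos]
    return pd.DataFrame(data)


def site_frequencies_exact(
    sample: HaplotypeSample,
    min_depth: int = 10,
    chrom: str = "chr1",
    offset: int = 0,
) -> pd.DataFrame:
    """Noise-free analogue of :func:`site_frequencies`: frequencies taken
    directly from the haplotype pools (each haplotype one read)."""
    counts = {t: sample.taxon_matrix(t).sum(axis=0) for t in sample.taxa}
    sizes = {t: n for t, n in sample.taxa.items()}
    derived = sum(counts.values())
    n_tot = sum(sizes.values())
    minor = np.minimum(derived, n_tot - derived)
    keep = minor >= 2
    for t in TAXA:
        if sizes.get(t, 0) < min_depth:
            keep &= False
    pos = np.flatnonzero(keep)
    data = {"chrom": chrom, "pos": sample.positions[pos] + offset}
    for t in TAXA:
        data[f"p_{t}"] = 1.0 - counts[t][pos] / sizes[t]  # majority = ancestral
        data[f"depth_{t}"] = sizes[t]
    return pd.DataFrame(data)


def site_frequencies_read_sampled(
    sample: HaplotypeSample,
    mean_coverage: float = 30.0,
    error_rates: Sequence[float] = (0.005, 0.005),
    min_depth: int = 10,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    chrom: str = "chr1",
    offset: int = 0,
) -> pd.DataFrame:
    """Pool-seq frequency table restricted to the locus's segregating sites.

    Reads are drawn per platform (Poisson depth, binomial allele sampling,
    independent substitution errors) at the segregating positions only and
    combined across platforms, then passed through the usual depth and
    pooled-singleton filters.  This is the fast path for simulation
    replicates, where error-only artifact sites would merely dilute the
    background Fst CDF.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    S = sample.n_sites
    depth: Dict[str, np.ndarray] = {}
    alt: Dict[str, np.ndarray] = {}
    for t in TAXA:
        f = sample.taxon_matrix(t).mean(axis=0) if S else np.empty(0)
        d_tot = np.zeros(S, dtype=np.int64)
        a_tot = np.zeros(S, dtype=np.int64)
        for err in error_rates:
            d = rng.poisson(mean_coverage, S)
            a_true = rng.binomial(d, f)
            if err > 0:
                a = (rng.binomial(a_true, 1.0 - err)
                     + rng.binomial(d - a_true, err))
            else:
                a = a_true
            d_tot += d
            a_tot += a
        depth[t], alt[t] = d_tot, a_tot
    pooled_alt = sum(alt.values())
    pooled_depth = sum(depth.values())
    minor = np.minimum(pooled_alt, pooled_depth - pooled_alt)
    keep = minor >= 2
    for t in TAXA:
        keep &= depth[t] >= min_depth
    pos = np.flatnonzero(keep)
    data = {"chrom": chrom, "pos": sample.positions[pos] + offset}
    for t in TAXA:
        data[f"p_{t}"] = 1.0 - alt[t][pos] / depth[t][pos]
        data[f"depth_{t}"] = depth[t][pos]
    return pd.DataFrame(data)


def add_pairwise_fst(
    freqs: pd.DataFrame,
    sample_sizes: Mapping[str, int] = None,
) -> pd.DataFrame:
    """Append Weir Fst columns (fst_IJ, fst_RI, fst_RJ) to a frequency
    table, treating each pool as ``sample_sizes[taxon]`` haploid lineages."""
    if sample_sizes is None:
        sample_sizes = sd.DEFAULT_SAMPLE_SIZES
    out = freqs.copy()
    # every table site is polymorphic across the pooled three taxa, so a
    # pair that shares one fixed allele shows no differentiation: the
    # moment estimator is 0/0 there and is resolved to Fst = 0
    for a, b in PAIRS:
        vals = weir_fst(
            out[f"p_{a}"].to_numpy(), sample_sizes[a],
            out[f"p_{b}"].to_numpy(), sample_sizes[b])
        out[f"fst_{a}{b}"] = np.nan_to_num(vals, nan=0.0)
    return out


def conditional_sites(records: pd.DataFrame,
                      min_fst_ri: float = 0.5) -> pd.DataFrame:
    """Keep sites sufficiently differentiated between R and I
    (``fst_RI >= min_fst_ri``); threshold 0 keeps every site."""
    return records[records["fst_RI"].fillna(-1.0) >= min_fst_ri] \
        if min_fst_ri > 0 else records


# ---------------------------------------------------------------------------
# distances and the D statistic
# ---------------------------------------------------------------------------

def genetic_distance(p1, p2) -> float:
    """Mean of ``p1*q2 + p2*q1`` across SNP positions.

    Equals the probability that two sequences drawn one from each
    population differ at a site, averaged over the segment's SNPs; ranges
    from 0 (same fixed allele) to 1 (fixed difference everywhere).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.size == 0 or p1.shape != p2.shape:
        raise ValueError("need matching, non-empty frequency arrays")
    return float(np.mean(p1 * (1 - p2) + p2 * (1 - p1)))


def ecdf_d_statistic(values_subset, values_background) -> float:
    """Largest vertical distance between two empirical CDFs (the
    two-sample Kolmogorov–Smirnov statistic)."""
    x = np.sort(np.asarray(values_subset, dtype=float))
    y = np.sort(np.asarray(values_background, dtype=float))
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    grid = np.concatenate([x, y])
    fx = np.searchsorted(x, grid, side="right") / x.size
    fy = np.searchsorted(y, grid, side="right") / y.size
    return float(np.abs(fx - fy).max())


@dataclass
class DStatResult:
    observed_d: float
    null_d: np.ndarray
    conditioning: str = "fst_RI>=0.5"

    def __post_init__(self) -> None:
        self.null_d = np.asarray(self.null_d, dtype=float)

    @property
    def max_null(self) -> float:
        return float(self.null_d.max()) if self.null_d.size else math.nan

    @property
    def p_value(self) -> float:
        """Empirical p with add-one smoothing:
        ``(1 + #{null >= observed}) / (1 + #null)``."""
        return (1 + int(np.sum(self.null_d >= self.observed_d))) / \
               (1 + self.null_d.size)


# ---------------------------------------------------------------------------
# the simulated-genome D pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DPipelineConfig:
    """Shared settings for computing the conditional D on a simulated or
    observed multi-locus dataset.

    Loci are ranked by the designation taxon's singleton-filtered Watterson
    theta; the lowest ``bottom_fraction`` are the LDR analogues.  D
    compares the Fst CDF of pair ``d_pair`` at conditioned sites inside the
    LDR analogues with the conditioned genomic background.
    """

    n_loci: int = 250
    locus_length: int = 10_000
    sample_sizes: Tuple[Tuple[str, int], ...] = (("J", 21), ("I", 22),
                                                 ("R", 46))
    bottom_fraction: float = 0.05
    cond_min_fst_ri: float = 0.5
    min_depth: int = 10
    d_pair: str = "fst_IJ"
    #: taxa whose per-locus theta designates LDR analogues: with several
    #: taxa a locus ranks by its *largest* theta among them, so the bottom
    #: fraction is low in all of them (the overlapping-LDR analogue);
    #: ("I",) reproduces the indica-alone designation
    designate_taxa: Tuple[str, ...] = ("I", "J")
    exact_counts: bool = False
    mean_coverage: float = 30.0
    error_rates: Tuple[float, float] = (0.005, 0.005)
    #: ancestral-phase sub-segment spacing for replicate genomes: shorter
    #: than the generator's T_d-based default because lineages dwell in
    #: the recombining wild population for coalescent times of order one,
    #: not T_d, and per-locus genealogical variance should reflect that
    mean_segment_bp: Optional[float] = 1250.0

    @property
    def sizes(self) -> Dict[str, int]:
        return dict(self.sample_sizes)


def _locus_theta_and_fst(locus: HaplotypeSample, config: DPipelineConfig,
                         rng: np.random.Generator) -> Tuple[float,
                                                            pd.DataFrame]:
    """Designation theta (largest singleton-filtered Watterson theta among
    the designation taxa's haplotype pools) and the locus's frequency
    table."""
    sizes = config.sizes
    theta = 0.0
    for taxon in config.designate_taxa:
        counts = locus.taxon_matrix(taxon).sum(axis=0)
        s_gt1 = int(np.sum((counts >= 2) & (counts <= sizes[taxon] - 2)))
        theta = max(theta, 1000.0 * s_gt1 /
                    (harmonic_number(sizes[taxon] - 1) * locus.locus_length))
    if config.exact_counts:
        freqs = site_frequencies_exact(locus, min_depth=config.min_depth)
    else:
        freqs = site_frequencies_read_sampled(
            locus, config.mean_coverage, config.error_rates,
            min_depth=config.min_depth, rng=rng)
    return theta, freqs


def conditional_d_for_dataset(
    dataset: GenomeDataset,
    config: DPipelineConfig = DPipelineConfig(),
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> float:
    """Bottom-fraction LDR designation + conditioning + D on one dataset."""
    if rng is None:
        rng = np.random.default_rng(seed)
    thetas = []
    tables = []
    for locus in dataset.loci:
        theta, freqs = _locus_theta_and_fst(locus, config, rng)
        thetas.append(theta)
        tables.append(freqs)
    order = np.lexsort((np.arange(len(thetas)), np.asarray(thetas)))
    k = max(1, int(math.floor(config.bottom_fraction * len(thetas))))
    ldr_idx = set(order[:k].tolist())
    sizes = config.sizes
    background = add_pairwise_fst(pd.concat(tables, ignore_index=True),
                                  sizes)
    subset = add_pairwise_fst(
        pd.concat([tables[i] for i in sorted(ldr_idx)], ignore_index=True),
        sizes)
    background = conditional_sites(background, config.cond_min_fst_ri)
    subset = conditional_sites(subset, config.cond_min_fst_ri)
    bg = background[config.d_pair].dropna().to_numpy()
    su = subset[config.d_pair].dropna().to_numpy()
    if su.size == 0 or bg.size == 0:
        return 0.0
    return ecdf_d_statistic(su, bg)


def simulate_null_D(
    models: Sequence[DemographicModel],
    reps_per_model: int,
    pipeline_config: DPipelineConfig = DPipelineConfig(),
    seed: Optional[int] = None,
    observed_d: float = math.nan,
) -> DStatResult:
    """Null distribution of the conditional D under single-history genomes.

    Each replicate simulates a fresh multi-locus three-taxon dataset under
    one demographic history and runs the same LDR-designation,
    conditioning and D computation applied to observed data.  Replicates
    are pooled across the supplied parameter combinations, so pass one
    model per combination to explore.
    """
    if not models or reps_per_model < 1:
        raise ValueError("need >= 1 model and >= 1 replicate")
    rng = np.random.default_rng(seed)
    null: List[float] = []
    cfg = pipeline_config
    for model in models:
        for _ in range(reps_per_model):
            dataset = sd.simulate_genome(
                model, cfg.n_loci, cfg.locus_length, cfg.sizes, rng=rng,
                mean_segment_bp=cfg.mean_segment_bp)
            null.append(conditional_d_for_dataset(dataset, cfg, rng=rng))
    return DStatResult(observed_d=observed_d, null_d=np.asarray(null),
                       conditioning=f"fst_RI>={cfg.cond_min_fst_ri}")


def default_null_models(
    base: Optional[DemographicModel] = None,
) -> List[DemographicModel]:
    """A small grid of single-history demographies for the null: both
    topologies crossed with two japonica bottleneck strengths."""
    if base is None:
        base = DemographicModel()
    out = []
    for n_j in (base.n_j, 4 * base.n_j):
        out.append(replace(base, n_j=n_j))
        out.append(DemographicModel(
            topology=sd.SEQUENTIAL, n_r=base.n_r, n_i=base.n_i, n_j=n_j,
            t_mrca=base.t_mrca, t_d=None,
            t_d_prime=base.domestication_time,
            selfing_rate=base.selfing_rate, recomb_rate=base.recomb_rate,
            mut_rate_theta=base.mut_rate_theta))
    return out


# ---------------------------------------------------------------------------
# per-region one-sided KS tests
# ---------------------------------------------------------------------------

@dataclass
class RegionTestResult:
    region: Tuple[str, int, int]
    n_sites: int
    p_vs_RI: float
    p_vs_RJ: float
    testable: bool

    def significant(self, alpha: float = 0.05) -> bool:
        return self.testable and self.p_vs_RI < alpha and \
            self.p_vs_RJ < alpha


def region_ks_test(
    region_records: pd.DataFrame,
    region: Tuple[str, int, int] = ("chr1", 0, 0),
    alpha: float = 0.05,
    min_sites: int = 10,
    method: str = "asymp",
) -> RegionTestResult:
    """One-sided KS tests that Fst(I,J) in a region is stochastically
    smaller than both Fst(R,I) and Fst(R,J) there.

    The region is significant (at the nominal, uncorrected ``alpha``) only
    when both one-sided p-values fall below ``alpha``; regions with fewer
    than ``min_sites`` usable records in any comparison are reported as
    untestable, never significant.  ``method`` selects the asymptotic or
    exact one-sided KS distribution.
    """
    ij = region_records["fst_IJ"].dropna().to_numpy()
    ri = region_records["fst_RI"].dropna().to_numpy()
    rj = region_records["fst_RJ"].dropna().to_numpy()
    if min(ij.size, ri.size, rj.size) < min_sites:
        return RegionTestResult(region, int(ij.size), math.nan, math.nan,
                                False)
    # alternative="greater": the CDF of the first sample lies above the
    # second's, i.e. Fst(I,J) values are stochastically smaller
    p_ri = stats.ks_2samp(ij, ri, alternative="greater", method=method).pvalue
    p_rj = stats.ks_2samp(ij, rj, alternative="greater", method=method).pvalue
    return RegionTestResult(region, int(ij.size), float(p_ri), float(p_rj),
                            True)


def significant_regions(
    fst_table: pd.DataFrame,
    regions: Sequence[Tuple[str, int, int]],
    alpha: float = 0.05,
    min_sites: int = 10,
    method: str = "asymp",
    correction: Optional[str] = None,
) -> List[RegionTestResult]:
    """Run :func:`region_ks_test` for every (chrom, start, end) region of a
    genome-wide Fst site table.

    ``correction="bh"`` replaces each comparison's p-values with
    Benjamini–Hochberg adjusted values across the testable regions; the
    default keeps the nominal, uncorrected level.
    """
    out = []
    for chrom, start, end in regions:
        recs = fst_table[(fst_table["chrom"] == chrom)
                         & (fst_table["pos"] >= start)
                         & (fst_table["pos"] < end)]
        out.append(region_ks_test(recs, (chrom, start, end), alpha,
                                  min_sites, method))
    if correction == "bh":
        testable = [r for r in out if r.testable]
        if testable:
            for attr in ("p_vs_RI", "p_vs_RJ"):
                adj = stats.false_discovery_control(
                    [getattr(r, attr) for r in testable], method="bh")
                for r, p in zip(testable, adj):
                    setattr(r, attr, float(p))
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    return out
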
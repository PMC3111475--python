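"""End-to-end orchestration of the domestication scan.

``ldr_scan`` runs the per-taxon diversity stage (site calling, sliding
windows, 10 kb region calls, shuffle-calibrated cutoff, LDR contigs) and
intersects the two cultivars' contigs into overlapping LDRs.
``overlapping_ldr_analysis`` adds the Fst table and the per-region
one-sided KS tests, and ``candidate_screen_experiment`` wires the whole
chain — including a synthetic annotation and planted diagnostic sites —
into a repeatable recovery experiment for the candidate-gene screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import candidates as cand
from . import differentiation as diff
from . import diversity as dv
from . import ldr as ldrmod
from . import synthetic_data as sd


@dataclass
class TaxonScan:
    site_set: dv.SegregatingSiteSet
    windows: List[dv.WindowDiversity]
    regions: List[dv.RegionCall]
    cutoff: ldrmod.ShuffleCutoff
    contigs: List[ldrmod.LDRContig]


@dataclass
class ScanResult:
    taxa: Dict[str, TaxonScan]
    overlaps: List[Tuple[str, int, int]]

    def size_summary(self, taxon: str, genome_size: int):
        return ldrmod.size_classify(self.taxa[taxon].contigs, genome_size)


def ldr_scan(
    counts_by_taxon: Mapping[str, Sequence[sd.PlatformSiteCounts]],
    sample_sizes: Mapping[str, int] = None,
    min_coverage: int = 6,
    scheme: str = "s_gt1",
    window: int = 100_000,
    step: int = 10_000,
    min_callable: int = 10_000,
    min_read_depth: int = 4,
    n_shuffles: int = 200,
    rank: int = 10,
    unit: int = 1000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    cultivars: Tuple[str, str] = ("I", "J"),
) -> ScanResult:
    """Diversity scan and LDR detection for every taxon pool."""
    if sample_sizes is None:
        sample_sizes = sd.DEFAULT_SAMPLE_SIZES
    if rng is None:
        rng = np.random.default_rng(seed)
    taxa: Dict[str, TaxonScan] = {}
    for taxon, tables in counts_by_taxon.items():
        n = sample_sizes[taxon]
        site_set = dv.call_segregating_sites(
            tables[0], tables[1], min_coverage, scheme, n_lineages=n)
        windows = dv.sliding_window_theta(
            site_set, window, step, min_callable, min_read_depth)
        cutoff = ldrmod.shuffle_cutoff(
            [site_set], unit=unit, n_shuffles=n_shuffles, rank=rank,
            window=window, step=step, min_callable=min_callable,
            min_read_depth=min_read_depth, rng=rng)
        regions = dv.region_median_theta(windows, cutoff.cutoff, tile=step)
        contigs = ldrmod.detect_ldr_contigs(regions, cutoff.cutoff, taxon)
        taxa[taxon] = TaxonScan(site_set, windows, regions, cutoff, contigs)
    a, b = cultivars
    overlaps = ldrmod.overlap_ldrs(taxa[a].contigs, taxa[b].contigs) \
        if a in taxa and b in taxa else []
    return ScanResult(taxa=taxa, overlaps=overlaps)


def overlapping_ldr_analysis(
    counts_by_taxon: Mapping[str, Sequence[sd.PlatformSiteCounts]],
    scan: ScanResult,
    sample_sizes: Mapping[str, int] = None,
    min_depth: int = 10,
    alpha: float = 0.05,
    min_sites: int = 10,
) -> Tuple[pd.DataFrame, List[diff.RegionTestResult]]:
    """Genome-wide Fst table plus KS significance of overlapping LDRs."""
    if sample_sizes is None:
        sample_sizes = sd.DEFAULT_SAMPLE_SIZES
    freqs = diff.site_frequencies(counts_by_taxon, min_depth=min_depth,
                                  chrom=next(iter(
                                      counts_by_taxon.values()))[0].chrom)
    fst_table = diff.add_pairwise_fst(freqs, sample_sizes)
    tests = diff.significant_regions(fst_table, scan.overlaps, alpha,
                                     min_sites)
    return fst_table, tests


def distance_pattern(
    dataset: sd.GenomeDataset,
    min_depth: int = 10,
) -> Dict[str, float]:
    """Mean pairwise genetic distances inside the injected regions and in
    the single-history background (the CDF contrast of the two-history
    signature)."""
    injected = set(dataset.introgressed)
    frames = {"ldr": [], "bg": []}
    for i, locus in enumerate(dataset.loci):
        table = diff.site_frequencies_exact(locus, min_depth=min_depth)
        frames["ldr" if i in injected else "bg"].append(table)
    out: Dict[str, float] = {}
    for kind, tables in frames.items():
        if not tables:
            continue
        table = pd.concat(tables, ignore_index=True)
        for a, b in diff.PAIRS:
            out[f"d_{a}{b}_{kind}"] = diff.genetic_distance(
                table[f"p_{a}"], table[f"p_{b}"])
    return out


# ---------------------------------------------------------------------------
# end-to-end candidate recovery experiment
# ---------------------------------------------------------------------------

ALT_MAP = {"A": "C", "C": "A", "G": "T", "T": "G"}


@dataclass
class CandidateExperiment:
    planted_genes: List[str]
    candidate_genes: List[str]
    recovered: List[str]
    outside_planted: List[str]
    n_significant_regions: int
    report: cand.RegionCandidateReport
    scan: ScanResult = field(repr=False)


def candidate_screen_experiment(
    seed: int,
    n_loci: int = 150,
    locus_length: int = 10_000,
    n_spans: int = 2,
    span_loci: int = 15,
    n_genes: int = 30,
    model: Optional[sd.DemographicModel] = None,
    sample_sizes: Mapping[str, int] = None,
    mean_coverage: float = 30.0,
    error_rates: Tuple[float, float] = (0.005, 0.005),
    n_shuffles: int = 200,
    thr_high: float = 0.8,
    thr_low: float = 0.1,
    edge_margin: int = 40_000,
) -> CandidateExperiment:
    """Simulate a genome with shared introgressed sweeps, plant one
    nonsynonymous (I,J)-versus-R diagnostic site per introgressed span,
    run the full scan + KS + Fst-triplet screen, and report recovery.

    Candidate genes located outside every introgressed span are listed in
    ``outside_planted`` (the screen's false positives; genes other than
    the planted one *inside* a swept span can legitimately qualify, since
    the sweep itself creates diagnostic sites).
    """
    if model is None:
        model = sd.DemographicModel()
    if sample_sizes is None:
        sample_sizes = sd.DEFAULT_SAMPLE_SIZES
    rng = np.random.default_rng(seed)
    dataset = sd.make_two_history_genome(
        model, n_loci, locus_length, n_spans=n_spans, span_loci=span_loci,
        taxon_sample_sizes=sample_sizes, rng=rng)
    genome_length = dataset.genome_length
    sequence, genes = sd.make_annotation_fixture(genome_length, n_genes,
                                                 rng=rng)
    reference = {"chr1": sequence}
    spans = dataset.introgressed_intervals()

    # one planted diagnostic site per span, in a gene well inside it: the
    # >=4-covering-window rule trims detected regions near span edges
    planted_genes: List[str] = []
    for span_start, span_end in spans:
        gene = next(g for g in genes
                    if g.start >= span_start + edge_margin
                    and g.end <= span_end - edge_margin)
        for pos, alt in cand.iter_nonsynonymous_substitutions(
                gene, reference, ALT_MAP):
            locus_idx, within = divmod(pos, locus_length)
            if within in dataset.loci[locus_idx].positions:
                continue  # already segregating; take the next CDS site
            dataset.loci[locus_idx] = sd.plant_divergent_site(
                dataset.loci[locus_idx], within)
            dataset.planted_sites.append((locus_idx, within))
            planted_genes.append(gene.gene_id)
            break
        else:
            raise RuntimeError("no plantable nonsynonymous site in gene")

    counts = sd.pooled_counts_for_genome(
        dataset, mean_coverage, error_rates, rng=rng)
    scan = ldr_scan(counts, sample_sizes, n_shuffles=n_shuffles, rng=rng)
    fst_table, tests = overlapping_ldr_analysis(counts, scan, sample_sizes)
    sig = [t.region for t in tests if t.significant()]

    qual = fst_table[(fst_table["fst_RI"] > thr_high)
                     & (fst_table["fst_RJ"] > thr_high)
                     & (fst_table["fst_IJ"] < thr_low)]
    effects = {
        ("chr1", int(pos)): cand.classify_coding_effect(
            "chr1", int(pos), ALT_MAP[sequence[int(pos)]], genes, reference)
        for pos in qual["pos"]
    }
    found = cand.screen_candidate_genes(sig, fst_table, effects, genes,
                                        thr_high, thr_low)
    report = cand.single_candidate_regions(found, sig)
    by_id = {g.gene_id: g for g in genes}

    def inside_planted(gene_id: str) -> bool:
        g = by_id[gene_id]
        return any(s <= g.start and g.end <= e for s, e in spans)

    candidate_ids = [c.gene_id for c in found]
    return CandidateExperiment(
        planted_genes=planted_genes,
        candidate_genes=candidate_ids,
        recovered=[g for g in planted_genes if g in candidate_ids],
        outside_planted=[g for g in candidate_ids
                         if not inside_planted(g)],
        n_significant_regions=len(sig),
        report=report,
        scan=scan,
    )
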
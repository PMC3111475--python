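"""Candidate domestication-gene screen.

Within significant overlapping low-diversity regions, a gene is a candidate
when it carries at least one nonsynonymous site at which both cultivars are
strongly differentiated from the wild taxon but not from each other:
``Fst(I,R) > 0.8``, ``Fst(J,R) > 0.8`` and ``Fst(I,J) < 0.1`` (strict
inequalities).  Coding effects are classified against a reference sequence
and gene models with standard-codon-table translation, strand aware, using
an any-transcript rule (a substitution is nonsynonymous if it changes the
protein of any overlapping transcript).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Seq import Seq

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
NONCODING = "noncoding"


@dataclass(frozen=True)
class GeneModel:
    """One transcript's coding structure.

    ``cds`` holds 0-based half-open intervals in genomic order; the total
    CDS length must be divisible by three.  Multiple transcripts of one
    gene share a ``gene_id``.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    cds: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        ivs = tuple(sorted((int(a), int(b)) for a, b in self.cds))
        if any(b <= a for a, b in ivs):
            raise ValueError("empty CDS interval")
        if any(ivs[i][1] > ivs[i + 1][0] for i in range(len(ivs) - 1)):
            raise ValueError("overlapping CDS intervals")
        object.__setattr__(self, "cds", ivs)
        if self.cds_length % 3:
            raise ValueError("CDS length must be divisible by 3")

    @property
    def cds_length(self) -> int:
        return sum(b - a for a, b in self.cds)

    @property
    def start(self) -> int:
        return self.cds[0][0]

    @property
    def end(self) -> int:
        return self.cds[-1][1]

    def contains(self, pos: int) -> bool:
        return any(a <= pos < b for a, b in self.cds)

    def cds_offset(self, pos: int) -> Optional[int]:
        """Offset of a genomic position within the spliced CDS, measured in
        transcription direction; ``None`` if the position is not coding."""
        off = 0
        for a, b in self.cds:
            if a <= pos < b:
                genomic = off + (pos - a)
                if self.strand == "+":
                    return genomic
                return self.cds_length - 1 - genomic
            off += b - a
        return None

    def spliced_cds(self, reference: str) -> str:
        raw = "".join(reference[a:b] for a, b in self.cds)
        if self.strand == "-":
            return str(Seq(raw).reverse_complement())
        return raw


def classify_coding_effect(
    chrom: str,
    pos: int,
    alt_allele: str,
    gene_models: Sequence[GeneModel],
    reference: Mapping[str, str],
) -> str:
    """Classify a substitution as synonymous / nonsynonymous / noncoding.

    For every transcript whose CDS contains the site, the reference codon
    and the codon carrying ``alt_allele`` are translated (strand aware,
    standard nuclear codon table); the site is nonsynonymous if the amino
    acid differs in any transcript, synonymous if it is coding and
    identical in all, noncoding otherwise.
    """
    seq = reference[chrom]
    if not 0 <= pos < len(seq):
        raise ValueError("site beyond reference length")
    ref_base = seq[pos]
    if alt_allele == ref_base:
        raise ValueError("alt allele equals the reference base")
    coding = False
    for gm in gene_models:
        if gm.chrom != chrom:
            continue
        off = gm.cds_offset(pos)
        if off is None:
            continue
        coding = True
        cds = gm.spliced_cds(seq)
        if len(cds) != gm.cds_length:
            raise ValueError("CDS extends beyond reference")
        base = alt_allele
        cds_off = off
        if gm.strand == "-":
            base = str(Seq(alt_allele).reverse_complement())
        codon_i = cds_off // 3
        within = cds_off % 3
        codon = cds[3 * codon_i: 3 * codon_i + 3]
        mutated = codon[:within] + base + codon[within + 1:]
        if str(Seq(codon).translate()) != str(Seq(mutated).translate()):
            return NONSYNONYMOUS
    return SYNONYMOUS if coding else NONCODING


def iter_nonsynonymous_substitutions(
    gene: GeneModel,
    reference: Mapping[str, str],
    alt_map: Optional[Mapping[str, str]] = None,
):
    """Yield ``(pos, alt)`` CDS substitutions of ``gene`` that are
    nonsynonymous under the mapped alternate base, in genomic order.
    Used to plant diagnostic sites in fixtures."""
    if alt_map is None:
        alt_map = {"A": "C", "C": "A", "G": "T", "T": "G"}
    seq = reference[gene.chrom]
    for a, b in gene.cds:
        for pos in range(a, b):
            alt = alt_map[seq[pos]]
            if classify_coding_effect(gene.chrom, pos, alt, [gene],
                                      reference) == NONSYNONYMOUS:
                yield pos, alt


def choose_nonsynonymous_substitution(
    gene: GeneModel,
    reference: Mapping[str, str],
    alt_map: Optional[Mapping[str, str]] = None,
) -> Tuple[int, str]:
    """First CDS position of ``gene`` where the mapped alternate base is a
    nonsynonymous change."""
    for pos, alt in iter_nonsynonymous_substitutions(gene, reference,
                                                     alt_map):
        return pos, alt
    raise ValueError("gene has no nonsynonymous substitution under alt_map")


@dataclass
class CandidateGene:
    gene_id: str
    region: Tuple[str, int, int]
    sites: pd.DataFrame  # qualifying nonsynonymous sites with Fst triplets


def screen_candidate_genes(
    significant_regions: Sequence[Tuple[str, int, int]],
    fst_records: pd.DataFrame,
    effects: Mapping[Tuple[str, int], str],
    gene_models: Sequence[GeneModel],
    thr_high: float = 0.8,
    thr_low: float = 0.1,
) -> List[CandidateGene]:
    """Apply the Fst-triplet rule within significant regions.

    ``fst_records`` needs columns chrom, pos, fst_RI, fst_RJ, fst_IJ;
    ``effects`` maps (chrom, pos) to a coding-effect label.  A gene is a
    candidate iff it overlaps a significant region and contains at least
    one nonsynonymous site with ``fst_RI > thr_high``, ``fst_RJ > thr_high``
    and ``fst_IJ < thr_low``.
    """
    qual = fst_records[
        (fst_records["fst_RI"] > thr_high)
        & (fst_records["fst_RJ"] > thr_high)
        & (fst_records["fst_IJ"] < thr_low)
    ]
    if len(qual):
        qual = qual[[
            effects.get((c, int(p))) == NONSYNONYMOUS
            for c, p in zip(qual["chrom"], qual["pos"])
        ]]
    out: List[CandidateGene] = []
    by_gene: Dict[str, List[GeneModel]] = {}
    for gm in gene_models:
        by_gene.setdefault(gm.gene_id, []).append(gm)
    for gene_id, transcripts in by_gene.items():
        chrom = transcripts[0].chrom
        g_start = min(t.start for t in transcripts)
        g_end = max(t.end for t in transcripts)
        region = next(
            ((rc, rs, re) for rc, rs, re in significant_regions
             if rc == chrom and rs < g_end and g_start < re), None)
        if region is None:
            continue
        if len(qual):
            in_gene = np.array([any(t.contains(int(p)) for t in transcripts)
                                for p in qual["pos"]])
            hits = qual[(qual["chrom"] == chrom).to_numpy() & in_gene]
        else:
            hits = qual
        if len(hits):
            out.append(CandidateGene(gene_id=gene_id, region=region,
                                     sites=hits.reset_index(drop=True)))
    out.sort(key=lambda c: (c.region, c.gene_id))
    return out


@dataclass
class RegionCandidateReport:
    n_regions: int
    n_zero: int
    n_single: int
    n_multi: int
    single_candidate_genes: List[str]


def single_candidate_regions(
    candidates: Sequence[CandidateGene],
    significant_regions: Sequence[Tuple[str, int, int]],
) -> RegionCandidateReport:
    """Count significant regions with zero / one / several candidate genes
    (single-candidate regions pinpoint one gene per introgressed segment)."""
    per_region: Dict[Tuple[str, int, int], List[str]] = {
        tuple(r): [] for r in significant_regions}
    for cand in candidates:
        per_region.setdefault(tuple(cand.region), []).append(cand.gene_id)
    singles = sorted(
        genes[0] for region, genes in per_region.items() if len(genes) == 1)
    counts = [len(g) for g in per_region.values()]
    return RegionCandidateReport(
        n_regions=len(per_region),
        n_zero=sum(c == 0 for c in counts),
        n_single=sum(c == 1 for c in counts),
        n_multi=sum(c >= 2 for c in counts),
        single_candidate_genes=singles,
    )
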
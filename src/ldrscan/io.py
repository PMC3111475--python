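"""Readers and writers for the pipeline's plain-text interchange formats.

Site counts travel as TSV (chrom, pos, taxon, platform, allele, count;
0-based positions, zero counts omitted), windows / regions / contigs as
BED-compatible TSV (0-based half-open), haplotypes as ms-style text,
cutoff reports and demography configs as YAML, references as FASTA and
gene models as GFF3 (1-based inclusive on disk, 0-based half-open in
memory).
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .candidates import GeneModel
from .diversity import RegionCall, WindowDiversity
from .ldr import LDRContig, ShuffleCutoff
from .synthetic_data import DemographicModel, HaplotypeSample, \
    PlatformSiteCounts


# ---------------------------------------------------------------------------
# site-count TSV
# ---------------------------------------------------------------------------

def write_site_counts(
    tables: Iterable[PlatformSiteCounts],
    path,
) -> None:
    rows = []
    for tab in tables:
        for allele, counts in sorted(tab.allele_counts.items()):
            pos = np.flatnonzero(counts)
            rows.append(pd.DataFrame({
                "chrom": tab.chrom, "pos": pos, "taxon": tab.taxon,
                "platform": tab.platform, "allele": allele,
                "count": counts[pos]}))
    frame = (pd.concat(rows, ignore_index=True) if rows else
             pd.DataFrame(columns=["chrom", "pos", "taxon", "platform",
                                   "allele", "count"]))
    frame.sort_values(["chrom", "pos", "taxon", "platform", "allele"]) \
        .to_csv(path, sep="\t", index=False)


def read_site_counts(
    path,
    length_by_chrom: Optional[Mapping[str, int]] = None,
) -> Dict[str, Dict[str, Tuple[PlatformSiteCounts, ...]]]:
    """Returns ``{chrom: {taxon: (platform tables...)}}`` with dense
    per-site arrays; lengths default to the largest position + 1."""
    frame = pd.read_csv(path, sep="\t",
                        dtype={"chrom": str, "taxon": str, "platform": str,
                               "allele": str})
    out: Dict[str, Dict[str, Tuple[PlatformSiteCounts, ...]]] = {}
    for chrom, cframe in frame.groupby("chrom"):
        L = (length_by_chrom[chrom] if length_by_chrom
             else int(cframe["pos"].max()) + 1)
        per_taxon: Dict[str, List[PlatformSiteCounts]] = {}
        for (taxon, platform), sub in cframe.groupby(["taxon", "platform"],
                                                     sort=True):
            alleles = {}
            for allele, asub in sub.groupby("allele"):
                arr = np.zeros(L, dtype=np.int64)
                arr[asub["pos"].to_numpy()] = asub["count"].to_numpy()
                alleles[allele] = arr
            per_taxon.setdefault(taxon, []).append(PlatformSiteCounts(
                taxon=taxon, platform=platform, chrom=chrom, length=L,
                allele_counts=alleles))
        out[chrom] = {t: tuple(v) for t, v in per_taxon.items()}
    return out


# ---------------------------------------------------------------------------
# BED-style tables
# ---------------------------------------------------------------------------

def write_windows_bed(windows: Sequence[WindowDiversity], path) -> None:
    pd.DataFrame(
        [(w.chrom, w.start, w.end, w.theta_per_kb) for w in windows],
        columns=["chrom", "start", "end", "theta_per_kb"],
    ).to_csv(path, sep="\t", index=False, header=False)


def write_regions_bed(regions: Sequence[RegionCall], path) -> None:
    pd.DataFrame(
        [(r.chrom, r.start, r.end, r.median_theta, r.n_windows, int(r.low))
         for r in regions],
        columns=["chrom", "start", "end", "theta", "n_windows", "low"],
    ).to_csv(path, sep="\t", index=False, header=False)


def write_contigs_bed(contigs: Sequence[LDRContig], path) -> None:
    pd.DataFrame(
        [(c.chrom, c.start, c.end, c.taxon, c.size_class) for c in contigs],
        columns=["chrom", "start", "end", "taxon", "size_class"],
    ).to_csv(path, sep="\t", index=False, header=False)


def write_intervals_bed(intervals: Sequence[Tuple[str, int, int]],
                        path) -> None:
    pd.DataFrame(intervals, columns=["chrom", "start", "end"]) \
        .to_csv(path, sep="\t", index=False, header=False)


def read_intervals_bed(path) -> List[Tuple[str, int, int]]:
    frame = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                        names=["chrom", "start", "end"],
                        dtype={"chrom": str})
    return [tuple(r) for r in frame.itertuples(index=False)]


# ---------------------------------------------------------------------------
# YAML: cutoffs and demography configs
# ---------------------------------------------------------------------------

def write_cutoff_yaml(cutoff: ShuffleCutoff, path) -> None:
    payload = {
        "cutoff": cutoff.cutoff,
        "rank": cutoff.rank,
        "n_shuffles": cutoff.n_shuffles,
        "significance": cutoff.significance,
        "theta_min": [float(x) for x in cutoff.theta_min],
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_cutoff_yaml(path) -> ShuffleCutoff:
    payload = yaml.safe_load(Path(path).read_text())
    return ShuffleCutoff(theta_min=np.asarray(payload["theta_min"]),
                         n_shuffles=payload["n_shuffles"],
                         rank=payload["rank"])


def load_demography(source) -> DemographicModel:
    """Build a :class:`DemographicModel` from a YAML file or mapping with a
    ``demography:`` block mirroring the model fields."""
    if isinstance(source, (str, Path)):
        source = yaml.safe_load(Path(source).read_text())
    block = source.get("demography", source)
    return DemographicModel(**block)


# ---------------------------------------------------------------------------
# ms-style haplotype text
# ---------------------------------------------------------------------------

def write_ms(samples: Sequence[HaplotypeSample], path,
             header: str = "ldrscan") -> None:
    """ms-style output: per locus a ``segsites:`` line, relative
    ``positions:`` and one 0/1 row per haplotype."""
    lines = [header, ""]
    for sample in samples:
        lines.append("//")
        lines.append(f"segsites: {sample.n_sites}")
        if sample.n_sites:
            rel = sample.positions / sample.locus_length
            lines.append("positions: " +
                         " ".join(f"{p:.6f}" for p in rel))
            for row in sample.matrix:
                lines.append("".join(map(str, row)))
        lines.append("")
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# FASTA / GFF3
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="")
               for chrom, seq in sequences.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_gff3(genes: Sequence[GeneModel], path) -> None:
    """GFF3 with gene / mRNA / CDS features, 1-based inclusive."""
    lines = ["##gff-version 3"]
    for gm in genes:
        start, end = gm.start + 1, gm.end
        lines.append("\t".join([
            gm.chrom, "ldrscan", "gene", str(start), str(end), ".",
            gm.strand, ".", f"ID={gm.gene_id}"]))
        lines.append("\t".join([
            gm.chrom, "ldrscan", "mRNA", str(start), str(end), ".",
            gm.strand, ".", f"ID={gm.transcript_id};Parent={gm.gene_id}"]))
        cds = gm.cds if gm.strand == "+" else tuple(reversed(gm.cds))
        phase = 0
        for a, b in cds:
            lines.append("\t".join([
                gm.chrom, "ldrscan", "CDS", str(a + 1), str(b), ".",
                gm.strand, str(phase),
                f"ID={gm.transcript_id}.cds;Parent={gm.transcript_id}"]))
            phase = (3 - ((b - a) - phase) % 3) % 3
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path) -> List[GeneModel]:
    """Parse gene models from GFF3 (via an in-memory gffutils database)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            merge_strategy="create_unique",
                            keep_order=True)
    genes: List[GeneModel] = []
    for mrna in db.features_of_type("mRNA"):
        cds = tuple(sorted(
            (c.start - 1, c.end)
            for c in db.children(mrna, featuretype="CDS")))
        if not cds:
            continue
        parents = list(db.parents(mrna, featuretype="gene"))
        gene_id = parents[0].id if parents else mrna.id
        genes.append(GeneModel(
            gene_id=gene_id, transcript_id=mrna.id, chrom=mrna.seqid,
            strand=mrna.strand, cds=cds))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes
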
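# Methods

`ldrscan` re-implements, at desk scale, a population-genomic scan for
domestication genes in a three-taxon design: two selfing cultivated
subspecies (`I`, indica-like, and `J`, japonica-like) and their outcrossing
wild progenitor (`R`).  The scientific question is whether genomic regions
of jointly reduced diversity in the two cultivars carry a different
genealogy from the genomic background — the signature of a segment swept in
one subspecies and spread to the other by introgression — and, where they
do, which genes they implicate.

## The model

### Diversity estimation from pooled reads

Each taxon is sequenced as a DNA pool on two short-read platforms.  Because
platform errors are independent between technologies, a site is accepted as
segregating only when its variant allele is seen on both platforms; the
`s_gt1` scheme additionally requires at least two variant reads per
platform (excluding read singletons) and `s_gt2` at least three.  The
variant allele at a site is the most frequent allele differing from the
combined-platform majority; further alleles at multi-allelic sites are
ignored.  Diversity is Watterson's estimator per kb,

    theta_hat = 1000 * S / (a_n * L),    a_n = 1 + 1/2 + ... + 1/(n-1),

with `n` the number of sampled lineages (one per selfing cultivar
accession, two per outcrossing wild accession; 21 / 22 / 46 by default) and
`L` the number of callable sites (depth >= 6 on both platforms for global
estimates).  Windowed estimates use 100 kb windows sliding by 10 kb; a
window is emitted only when at least 10,000 of its sites have depth >= 4 on
both platforms, and its `L` is that callable count, so coverage gaps do not
masquerade as low diversity.  Each 10 kb tile is summarised by the median
theta of the (up to ten) windows fully containing it, dropped when fewer
than four windows cover it.

### Low-diversity regions

The low-diversity cutoff is calibrated per taxon by shuffling: the genome
is cut into 1 kb units, the units are permuted genome-wide (a
per-chromosome variant is available), windows are recomputed under the same
callable rule, and the smallest emitted window theta is recorded.  Over 200
shuffles, the 10th smallest minimum is the cutoff, so a homogeneous genome
produces a sub-cutoff window in only ~5% of shuffles.  Tiles with median
theta strictly below the cutoff are low; maximal runs of adjacent low tiles
form LDR contigs (uncalled tiles break runs; contigs never span
chromosomes).  Contigs are binned by size into left-closed bins
(<100, 100–200, ..., >=600 kb) with genome fractions reported below/above
200 kb, and the two cultivars' contigs are intersected into *overlapping
LDRs*.

### Differentiation and the two-history test

Per-site allele frequencies combine both platforms and keep sites with
depth >= 10 in all three taxa whose pooled minor-allele count is at least
two (pooled singletons are likely errors).  Pairwise differentiation is the
Weir moment (ANOVA) estimator for haploid allele-frequency data,

    Fst_hat = (MSP - MSG) / (MSP + (n_c - 1) * MSG),

with the between/within mean squares computed from (p_i, n_i); estimates
are clamped into [0, 1], and a site where one pair shares a single fixed
allele — which is 0/0 for the estimator but polymorphic across the pooled
three taxa — is reported as Fst = 0 for that pair (no differentiation).
The mean frequency distance `p1*q2 + p2*q1` over SNPs gives the genetic
distance between two pools.

Genealogical contrast: at sites pre-conditioned on strong wild/indica
differentiation (Fst(R,I) >= 0.5, where the models are distinguishable),
the empirical CDF of Fst(I,J) inside candidate regions is compared with the
genomic background; the largest vertical distance between the two CDFs (a
two-sample Kolmogorov–Smirnov statistic) is the D statistic.  Its null
distribution comes from coalescent simulation: each replicate simulates a
multi-locus three-taxon genome under a *single* demographic history, ranks
loci by the larger of the two cultivars' singleton-filtered thetas,
designates the bottom 5% as LDR analogues (the overlapping-LDR analogue:
low in both cultivars; an indica-alone designation is configurable), and
recomputes D through the identical conditioning path.  The empirical
p-value is `(1 + #{null >= observed}) / (1 + #null)`.  Individual
overlapping LDRs are tested by two one-sided two-sample KS tests — Fst(I,J)
stochastically smaller than Fst(R,I) and than Fst(R,J) — significant only
when both p-values fall below the nominal 5% level, uncorrected (a
Benjamini–Hochberg option exists but is off by default, preserving the
nominal-level design).

### Candidate genes

Within significant regions, a gene is a candidate when it contains at least
one *nonsynonymous* site with Fst(I,R) > 0.8, Fst(J,R) > 0.8 and
Fst(I,J) < 0.1 (strict inequalities).  Coding effects translate the
reference and substituted codon strand-aware through the spliced CDS
(standard nuclear codon table); a substitution is nonsynonymous if it
changes the protein of *any* overlapping transcript.  Regions represented
by a single candidate gene are reported separately, since one introgression
can fragment into several adjacent LDRs.

## The synthetic-data generator

### Two-phase coalescent

Times are in units of `4*N_R` generations and `theta = 4*N_R*mu` per site
(`ms` conventions); population sizes are haploid-lineage counts entering
the rates only through ratios.  The coalescent runs in two phases:

1. **Selfing phase** (present back to the domestication time): selfing
   suppresses recombination, so one genealogy is shared by the whole locus
   (residual recombination `r*(1 - selfing_rate)` opens independent
   phase-1 blocks; the default `selfing_rate = 1` gives none).  Under the
   *independent* topology both cultivars coalesce separately inside their
   bottlenecked populations until `t_d`; under the *sequential* topology
   the cultivars merge at `t_split` into a common cultivar population
   (size `n_c`, default `n_i`) that joins the wild population at
   `t_d_prime`.  A literal reading in which the domestication time and the
   I/J split coincide would make the two topologies identical, so the
   split is an explicit, earlier event (default `t_d_prime / 2`).
2. **Wild phase**: beyond domestication the locus is partitioned into
   non-recombining sub-segments at geometric breakpoints, and the lineages
   surviving the selfing phase coalesce independently per sub-segment in
   the ancestral wild population (size `N_R`).  The default spacing is
   `1 / (recomb_rate * t_dom)`; the D-pipeline overrides it to 1250 bp
   because lineages dwell in the recombining wild population for
   coalescent times of order one rather than `t_dom`, and between-locus
   genealogical variance should reflect that.  The spacing is an explicit
   knob on every entry point.

The MRCA time `t_mrca` bounds validation only — the ancestral population
coalesces freely to its MRCA, which is what a trifurcation at the
domestication time implies.  Infinite-sites mutations are overlaid Poisson
(rate `theta` per unit branch length per site) at distinct uniform
positions.  `DemographicModel.from_generations` converts absolute sizes
and generation times into scaled units; jointly rescaling all sizes and
times leaves every scaled summary unchanged.

### Default demography

Defaults: `n_i = 0.05`, `n_j = 0.015` (relative to `n_r = 1`),
`t_d = 0.01`, `t_mrca = 1`, `recomb_rate = 0.03`/site,
`mut_rate_theta = 0.004`/site (wild diversity 4/kb).  The japonica-like
bottleneck reproduces that cultivar's severe observed diversity loss
(about a quarter of wild diversity).  The indica-like value is a
deliberate compromise: under a single-epoch founder model, diversity
retention and wild/cultivar differentiation are two faces of the same
drift, so a near-wild indica diversity ratio would leave essentially no
site with Fst(R,I) >= 0.5 and the conditional analysis would have no
resolution.  Real wild-rice structure supplies that differentiation
without the diversity cost; modelling such structure is out of scope, so
the default accepts an understated indica diversity ratio (~0.65 rather
than ~0.9) in exchange for a workable conditioned site set (~0.3% of
read-sampled sites).  This is the generator's main infidelity to real
data, and it means passing tests demonstrate the machinery of the
conditional analysis, not the realism of wild-population structure.

### Sweeps, reads, annotation

Introgressed sweeps copy one donor haplotype over all recipient haplotypes
within a region (optionally adding private post-transfer mutations at rate
`theta * time` per copy); the shared two-history construction fixes the
same donor haplotype in both cultivars, creating a region that is an LDR
in both and nearly identical between them.  Pooled reads are Poisson
coverage (30X per platform by default) with binomial allele sampling and
independent symmetric substitution errors per platform (0.5% default); an
`exact` mode makes each haplotype contribute exactly one error-free read
per platform — the sequencing-noise-free limit used where an analytic
haplotype-level expectation is the yardstick, because read-count singleton
filters at finite coverage are only a stochastic proxy for haplotype
singleton classes.  Annotation fixtures are random sequences with
non-overlapping genes on both strands, every third gene split into two
CDS exons with a phase-breaking intron, CDS lengths divisible by three.

## Problem sizes

Chosen once for desk-scale runs: estimator recovery uses 500 x 10 kb loci
(n = 22, theta 4/kb); the error-filter contrast 100 x 10 kb loci; the
conditional-D analysis 250 x 10 kb-locus genomes with ten injected 20 kb
introgressed LDRs (4% of the genome, near the real-data share), a
200-replicate null pooled over four single-history demographies (both
topologies x two japonica bottlenecks) and 50 calibration genomes; the
distance contrast 20 genomes of 60 loci; the end-to-end candidate screen
20 replicates of a 1.2 Mb genome (two 120 kb introgressed spans, 24 genes,
one planted diagnostic site per span, full 200-shuffle calibration per
taxon).  In the end-to-end screen the planted gene is placed at least
40 kb inside its span because the four-covering-window rule trims detected
regions near span edges.

## Numerical and design choices

- Ties: a tile whose median theta equals the cutoff is *not* low (strict
  inequality); the median of an even window count is the mean of the two
  central values; bottom-fraction ties break by coordinate.
- Windows never extend past chromosome ends; trailing sub-1 kb remainders
  are excluded from the shuffle unit pool.
- The shuffle pools units genome-wide (the documented alternative keeps
  units within chromosomes, behind a flag).
- Weir estimates below 0 clamp to 0 (differentiation is reported on
  [0, 1]).
- One-sided KS p-values use the asymptotic distribution by default; the
  exact small-sample method is a flag.
- The D statistic compares site-level CDFs (each SNP one observation), not
  window-level ones.
- In simulation replicates the frequency tables are sampled at segregating
  positions only; error-only artifact sites dilute both CDFs without
  informing the contrast, and the whole-genome read path (used by the
  scan) retains them.
- The synthetic pipeline maps the binary alleles to nucleotides through a
  fixed substitution map (A<->C, G<->T) when coding effects are needed;
  real nucleotide data bypass this.

## Known limitations

- No wild-population structure or gene flow after domestication; the
  independent-topology background therefore under-represents real
  wild/cultivar differentiation (see above).
- Loci are simulated independently: linkage does not extend across locus
  boundaries, so LDR-contig length distributions are not realistic beyond
  the injected span lengths.
- No indels, no diploid genotypes, no phasing, no read-level quality
  scores; platform errors are symmetric and site-independent.
- The candidate screen assumes the qualifying site lies within the gene
  body and the gene overlaps the significant region (where the site sits
  relative to the region is not further constrained).
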
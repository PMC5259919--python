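# Methods

## Coordinates, regions and bins

All coordinates are 0-based half-open (BED convention).  A gene's TSS
is its interval start on the + strand and the interval end on the −
strand; promoters are the 2 kb immediately upstream of the TSS.  CpG
island *shores* are the 2-kb flanks of each island and *shelves* the
next 2 kb outward (the widths follow the common UCSC/Irizarry
convention); islands are subtracted from shores, and islands + shores
from shelves, so the three classes are pairwise disjoint even when
neighbouring islands are close.  Introns are gene bodies minus exons,
per gene.

The methylation matrix is addressed by a fixed, non-overlapping grid of
100-bp bins.  A bin receives a region label when it overlaps ≥ 1 bp of
an interval of that class (multi-labelling allowed), and the derived
labels `promoter_CpGI` / `promoter_shore` mark bins overlapping the
base-pair-level intersection of those classes; unlabelled bins are
`intergenic`.  The ≥ 1 bp rule is the simplest one consistent with
scoring a TFBS by "all bins overlapping" it; bin/interval overlap is
plain integer arithmetic on the grid, so no interval index is needed.

## Differential methylation and DMRs

Per bin, the two subtypes are compared with a Welch (unequal-variance)
two-sample *t*-test — the robust default when only "*t*-test" is
specified — and *P*-values are Bonferroni-adjusted over the bins
actually tested in that pair: bins with NaN cells or with exactly
constant values in both groups carry no hypothesis and are skipped
(counted in the result object).  Constantness is detected by exact
range (a float variance of a constant row can be ~1e-17).  Significant
means adjusted *P* < 0.05.  The hypomethylated subtype of a bin is the
group with the smaller mean; exact ties are recorded as `tie` and
excluded from hypomethylation-ratio numerators and denominators (a
measure-zero event under continuous data).

DMRs are maximal runs of adjacent significant bins sharing a direction;
`max_gap_bins` (default 0, i.e. strict adjacency) non-significant bins
may be tolerated inside a run.  Chromosome boundaries and direction
changes always split.  The three-class comparison is decomposed into
the three pairwise comparisons (Lu–BaA, Lu–BaB, BaA–BaB).

The hypomethylation ratio of region R in a pair is
`#(significant R bins hypomethylated in s) / #(significant R bins)`;
the two ratios of a pair sum to 1 whenever defined, and a region with
no significant bins reports NA rather than 0.

## Island meta-profile

Each island contributes one row: ±500 bp of flank in 100-bp steps
(absolute offsets) plus the island interior rescaled to 20 equal slices
(5 % steps; the axis prints 0–100 %).  A window's value per sample is
the length-weighted mean RMS of the bins it overlaps; windows beyond a
chromosome end are NaN and drop out of island averaging.  Islands enter
with equal weight (unweighted mean over islands), islands shorter than
the slice count are kept with a warning (slices then share bins).

The per-position subtype comparison is a one-way ANOVA whose unit is
the **per-sample island-averaged value** — averaging over islands first
avoids treating islands as independent replicates of the same sample —
with Bonferroni correction over axis positions.  Positions where any
subtype has < 2 finite values are NA and excluded from the multiplicity
count; all-constant positions report *P* = 1.

## TFBS screen

TFBS methylation is the **unweighted** mean RMS of all overlapping bins
(a site overlapping no bin is excluded and reported).  The screen keeps
a site when all four hold: Kruskal–Wallis across subtypes significant
at Benjamini–Hochberg FDR < 0.1 (BH chosen where only "FDR" is named;
constant sites have no defined test and are NA, outside the FDR
family); Spearman ρ with the target gene's expression < −0.5, computed
over **all** samples with ties mid-ranked; the site is ChIP-validated
(an input flag — motif scanning and ChIP databases are upstream
inputs, not reimplemented); and the TF's own expression is similar
across subtypes, operationalized as KW *P* ≥ 0.05 — symmetric with the
differential test used elsewhere, since no explicit criterion is
standard.  Gene-level integration keeps genes with ≥ 1 passing site,
reporting the most negative ρ, the smallest FDR, and the
hypomethylated subtype (lowest mean TFBS methylation) of the best
site, plus the fraction of genes hypomethylated in basal B.

## Mutation analysis

The caller is an explicit one-sided binomial test on count tables:
`p_error = P[X ≥ mismatches | coverage, seq_error]`, a call requiring
`p_error < 1e-6` and coverage ≥ 10 (both configurable).  Upstream
pileup machinery (BAQ, anomalous-pair filtering) is out of scope —
users with real data can supply pre-computed calls in the same table
schema.  Coverage above 250 reads is capped with proportional mismatch
subsampling.  The default `call_alpha = 1e-6` puts the calling
threshold at ~4 mismatches for 30× coverage with a 0.002 error rate:
comfortably below a heterozygous signal (~15/30) and far above what
sequencing error produces, giving an essentially zero false-positive
rate at genome scale.  `min_coverage = 10` is a conventional site
floor; no depth floor is standard for this assay.

Mutation rate per methylation stratum (width 0.05 on RMS, last stratum
closed at 1.0) is mutated / eligible **site-sample observations** — the
denominator counts observations with adequate coverage, not all
genomic CpGs, because affinity capture only covers methylated regions
and an uncovered site is unobservable.  Empty strata are NA, not 0.
Stratum membership pre-rounds `rms / width` at 9 decimals so boundary
values (0.3 / 0.05 = 5.999…) land in their stratum.  The subtype
comparison per stratum is a one-way ANOVA on per-sample rates (pooled
subtype rates would leave ANOVA without replicates), Bonferroni over
testable strata.

A site is subtype-specific when its carrier fraction is ≥ 30 % in one
subtype and < 10 % in each of the other two; with these thresholds at
most one subtype can match, and the configuration is rejected if
`min_in ≤ max_out`.  Samples without an eligible observation count as
non-carriers.  Regional counts increment every region class a site's
bin carries; the per-region subtype test is ANOVA on per-sample carried
counts, Bonferroni over regions.

## Concordance

Both technologies are averaged over non-overlapping 2-kb windows
anchored at each target region's start: mean beta over contained CpGs
(unweighted, not coverage-weighted) and mean RMS over overlapping
bins.  Windows lacking either side are dropped and counted.  Pearson
*r* is reported per sample and averaged; identical paired vectors take
an exact fast path returning 1.0 (floating-point `pearsonr` is
otherwise 1–3 ulp away from unity).  The closed-form attenuation
`r = σ²ₛ / √((σ²ₛ+σ²ₐ)(σ²ₛ+σ²_b))` for two noisy readouts of a shared
signal is exposed for calibration checks.

## The synthetic study

The generator emulates a 30-cell-line three-subtype affinity-capture
study at desk scale.  Defaults (the study conditions): 10 samples per
subtype; 2 chromosomes × 300 kb; 50 non-overlapping islands (500–1000
bp) whose 2-kb flanks yield exactly 2,000 shore bins; 30 genes whose
promoter coincides with one shore of their anchor island (alternating
strand), each with 3 exons, UTRs, and 2 TFBS planted inside
promoter∩shore from a pool of 8 TFs.

Methylation: RMS = clamp(region mean + subtype effect + N(0, 0.1)) to
[0, 1] — truncated normal rather than beta noise for direct control of
effect sizes.  Region baselines: islands 0.25 (methyl-protected),
shores 0.45, shelves 0.40, gene bodies 0.70 (gene-body methylation is
canonically high; this also populates the upper methylation strata so
the hypermethylated mutation analysis has support), intergenic 0.35.
Luminal and basal A receive a +0.25 boundary peak on the first shore
bin at each island end; basal B instead receives −0.3 on 200 planted
shore bins, always including the TFBS bins of the 20 coupled genes.
At these settings the per-bin effect is d = 3, so the *t*-test operates
near power 1 and recovery results are seed-robust.

Expression: coupled genes = baseline − 5 × (mean promoter-TFBS RMS) +
N(0, 0.3); uncoupled targets and the TFs themselves are baseline +
noise, subtype-invariant by construction (so the TF-similarity filter
is satisfiable).  Mutations: 4,000 CpG sites scattered over bins;
background probability per site-sample from a serializable rate model —
default linear in RMS (0.005 + 0.02·RMS) with a +0.02 basal-A bonus
below RMS 0.5 and +0.03 basal-B bonus above 0.7; 25 planted
subtype-specific sites per subtype with 30–60 % carriers, placed with
regional bias (basal A: island-related bins outside gene bodies;
basal B: intronic bins outside island flanks; luminal: elsewhere) and
kept free of background mutations so the planted carrier pattern is
exact.  Coverage ~ Poisson(30) capped at 250; mutated observations
draw mismatches at VAF 0.5 or 1.0, others at error rate 0.002
(≈ Q27; only a quality floor, not an error rate, is standard).
Bisulfite betas = clamp(bin RMS + N(0, 0.1)) at CpGs spaced 200 bp over
20 4-kb regions centred on islands, for 2 samples per subtype.

Randomness is split into per-stage child generators spawned from the
seed, so two runs emit byte-identical files and a change in one stage's
options cannot perturb another stage's draws.  What the generator does
**not** emulate: read-level data, copy-number and capture-efficiency
bias, correlated noise along the genome, batch effects, germline
variation.  Passing tests therefore demonstrate that the statistical
machinery recovers planted structure under clean noise assumptions —
not that real MBDCap-seq artefacts are handled.

## Problem sizes and numerical choices

The default study (6,000 bins × 30 samples, 4,000 sites × 30
observations) keeps every stage under a few seconds; the validation
suite uses 200-replicate null simulations at 500 bins for family-wise
error control and 3,000-site uniform-RMS designs (≥ 2,000 observations
per stratum) for rate-recovery checks.  Matrices are written at 17
significant digits and parsed with round-trip float precision, so
emitted files reload losslessly.  The pipeline manifest omits output
paths, making reruns byte-identical across directories.

## Known limitations

* The bins→DMRs reduction rule is adjacency-based; no gap tolerance is
  claimed to match any particular external tool.
* Spearman ρ is computed across all samples; a within-subtype
  correlation would ask a different (conditional) question.
* The binomial caller ignores strand, mapping quality and indels; it is
  a calling rule on count tables, not a variant caller.
* Metaprofile ANOVA on rescaled positions mixes islands of different
  lengths into shared percent coordinates; absolute-coordinate effects
  narrower than a slice are diluted.
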
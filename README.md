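# shoremeth

Subtype-resolved analysis of CpG-island-**shore** methylation and CpG
mutation patterns from binned affinity-capture (MBDCap-seq-style)
methylomes, built for studies that compare sample groups — here the
luminal, basal A and basal B subtypes of breast-cancer cell lines.

Affinity-capture methylation sequencing yields a relative methylation
score (RMS ∈ [0, 1]) per fixed 100-bp genomic bin per sample.  Starting
from that matrix plus interval annotation (CpG islands, genes, TFBS), a
gene-expression matrix, and a per-CpG pileup table, the package answers
five questions a group-comparison methylome study asks:

1. **Differential methylation** — per-bin Welch *t*-tests between
   subtype pairs with Bonferroni-adjusted *P* < 0.05, merged runs of
   significant bins as DMRs, counts per genomic region class
   (CpGI / shore / shelf / promoter / exon / intron / UTR / intergenic),
   and the *hypomethylation ratio*: among significant bins of a region,
   the fraction whose lower group mean belongs to a given subtype.
2. **Island meta-profile** — each island rescaled to percent
   coordinates with ±500 bp flanks, per-subtype mean curves, and
   position-wise one-way ANOVA (Bonferroni) localizing where subtypes
   diverge (the island/shore boundary).
3. **TFBS–expression coupling** — TFBS methylation = mean RMS of the
   100-bp bins overlapping the site; sites kept when differentially
   methylated across subtypes (Kruskal–Wallis, BH FDR < 0.1), inversely
   correlated with their target gene's expression (Spearman ρ < −0.5),
   ChIP-validated, and from a TF whose own expression is
   subtype-invariant (KW *P* ≥ 0.05).
4. **Methylation-stratified mutation rates** — a one-sided binomial
   caller on (coverage, mismatch) counts, mutation rate = mutated /
   eligible site-sample observations per RMS stratum of width 0.05,
   subtype comparison per stratum by ANOVA (Bonferroni); plus
   *subtype-specific* mutations (carried by ≥ 30 % of one subtype's
   samples and < 10 % of each other subtype) counted per region class.
5. **Cross-technology concordance** — Pearson *r* between bisulfite
   beta values and binned RMS averaged over shared 2-kb windows.

A deterministic synthetic-study generator (`shoremeth.simulate`) emits
all inputs with the structure these analyses assume — basal-B shore
hypomethylation, luminal/basal-A boundary methylation peaks,
methylation-coupled expression, methylation- and subtype-dependent
mutation probabilities — together with truth tables, so every stage is
validated end-to-end with no external data.

## Worked example

```bash
python analysis/01_simulate_study.py
python analysis/02_shore_dmr_analysis.py
```

prints

```
study seed 42: 6000 bins, 30 samples, 2000 shore bins
planted: 200 hypomethylated shore bins (basal B), 20 inverse-coupled genes, 75 subtype-specific mutation sites
luminal-basalA: 0 significant bins -> 0 DMRs
luminal-basalB: 163 significant bins -> 131 DMRs
  shore: 100.0% of significant bins hypomethylated in basal B
basalA-basalB: 167 significant bins -> 131 DMRs
  shore: 100.0% of significant bins hypomethylated in basal B
```

i.e. on a 30-sample study with a planted −0.3 RMS basal-B effect on 200
of 2,000 shore bins, the two basal-B-containing comparisons recover
~165 significant bins each and essentially every significant shore bin
is hypomethylated in basal B, while the untouched luminal/basal-A pair
stays empty.  The remaining drivers (`03`–`07`) reproduce the boundary
meta-profile peak (strongest ANOVA signal at the −100 bp position),
recover all 20 inverse-coupled genes with no false positives, show the
basal-A mutation excess at low/intermediate methylation and the basal-B
excess at hypermethylated sites, the regional enrichment of
subtype-specific mutations (basal A in island-related regions, basal B
in introns), and a cross-technology Pearson *r* averaging ≈ 0.71.

The same pipeline runs from a single command on simulated or real
inputs (`shoremeth run-all --seed 42 --outdir results/run`, or
`--inputs <dir>` for tables in the documented schema), writing every
stage's TSV/BED outputs plus a reproducibility manifest.

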
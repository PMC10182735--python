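# hsrscan

Detection, recurrence analysis and dating of introgressed haplotype
blocks in hybrid populations, from phased genotype data.

## The problem

When two diverged sister species hybridize, the admixed population
carries mosaics of chromosome segments from both parental gene pools.
Given phased haplotypes for the admixed ("query") individuals and two
species reference panels, `hsrscan` answers three questions:

1. **Where are the introgressed blocks?**  Each query haplotype is
   scored in non-overlapping 20 kb windows by the ratio of its minimum
   Hamming distances to the two reference panels,

   r = d_A / d_B,  d_X = min over panel-X haplotypes of the number of
   mismatching alleles in the window.

   Windows where max(d_A, d_B) < 20 carry too little signal and are
   filtered.  The genome-wide mean ratio r̄ is the mean over query
   haplotypes of (mean d_A)/(mean d_B); windows with r ≤ r̄/8 are called
   species-A **high-similarity regions** (HSRs), windows with r ≥ 8·r̄
   species-B HSRs, and same-origin calls less than 50 kb apart are
   combined into contiguous regions.

2. **Is their placement random?**  With f_i the fraction of the callable
   genome (windows with between-species F_ST > 0.15) covered by
   haplotype i's HSRs, the expected number of bases where all n query
   haplotypes carry an HSR is (∏ f_i)·S_callable; expected bases at any
   overlap count k follow the binomial C(n,k)·F^k·(1−F)^(n−k)·S_callable
   with F = max f_i.  Excess recurrence is reported as
   M = log₂(observed/expected).

3. **How old are the blocks?**  Each HSR is dated with a recombination
   clock: a chromosome-length tract decays forward in time, one
   crossover per generation with probability min(1, G Morgans), placed
   proportionally to the local recombination rate; the age estimate is
   the first generation at which the surviving tract around the HSR
   midpoint is smaller than the observed HSR.  Generations convert to
   years with a generation time of 2.4 years.

Supporting statistics — windowed π, d_xy and Hudson F_ST, high-F_ST
enrichment of recurrent regions (binomial test), exon density and
recombination-rate contrasts — round out the pipeline.

A synthetic-data module generates phased datasets with the full
statistical structure the analysis assumes (two diverged species panels,
admixed queries with known block positions, a heterogeneous 100 kb
recombination map, toy exon annotation), so the whole pipeline runs and
is tested end to end without any external data.

## Worked example

Run the full synthetic pipeline (simulate → scan → overlap → diversity →
enrichment → dating) on the default design — one 10 Mb chromosome,
16 + 8 reference haplotypes, 8 query haplotypes carrying ~25% species-A
ancestry:

```bash
hsrscan run --seed 1 --out demo
```

prints

```
hsrscan pipeline report
=======================

mean distance ratio     : 0.816
call thresholds (lo/hi) : 0.102 / 6.525
HSR calls (A/B)         : 119 / 0
HSR bases (A/B)         : 19740000 / 0
mean pi A / pi B        : 0.00028 / 0.00028
mean dxy / FST          : 0.00428 / 0.935
S_callable              : 10000000
truth F1 (origin A)     : 1.000
true admixture fraction : 0.264
median age              : 1208 generations (~3 kYA)
```

Reading this: the query haplotypes average a distance ratio of 0.82, so
A-origin calls require r ≤ 0.102 and B-origin calls r ≥ 6.53.  The scan
calls 119 species-A HSRs covering 19.74 Mb of the 80 Mb of haploid query
genome (24.7%, matching the planted 26.4% within the scan's 20 kb
resolution; block-level F1 against the known truth is 1.0).  Between the
panels d_xy is 0.43% and mean 5 kb-window F_ST 0.94, so the whole 10 Mb
is callable.  The dated blocks have a median age of ~1,200 generations —
young, as expected for tracts planted at their current length rather
than decayed from whole chromosomes.

Individual stages are available as `hsrscan simulate / scan / stats /
overlap / age`, and as plain library calls (`hsrscan.score_windows`,
`hsrscan.call_hsrs`, `hsrscan.estimate_age`, ...).

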
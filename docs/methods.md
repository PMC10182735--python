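# Methods

## Scope and coordinates

`hsrscan` implements a windowed haplotype distance-ratio scan for
introgressed regions (HSRs), a binomial random-placement null for their
recurrence across haplotypes, windowed diversity statistics (π, d_xy,
Hudson F_ST) with downstream enrichment/contrast tests, a
recombination-clock dating simulator, and a synthetic hybrid-population
generator that exercises all of it end to end.  Read alignment, variant
calling, statistical phasing, PCA/admixture inference, topology
weighting and tree building are out of scope; the pipeline starts from a
phased VCF.

All coordinates are 0-based, half-open internally (BED convention);
VCF/GFF3 1-based conventions are converted at the file boundary only.
Strand is ignored throughout (every statistic here is strand-symmetric).

## The scan

* **Windows.** Fixed 20 kb genomic tiles from position 0, trailing
  partial window retained.  Genomic (not SNP-count) tiling keeps the
  window grid independent of local SNP density; the 20 kb default is
  motivated by an expected ~100 SNPs per window at ~5 SNPs/kb.
* **Distances.** Per (haplotype, window): minimum Hamming distance to
  each reference panel over the window's shared site set.  Sites with
  any missing or unphased call are dropped at load time rather than
  imputed, so all haplotypes are compared on identical site sets.
* **Low-diversity filter.** A window is uninformative for a haplotype
  when max(d_A, d_B) < 20; the filter is applied per (haplotype,
  window), using that haplotype's own distances.  An "across all
  haplotypes" variant would only differ in windows that are borderline
  for some haplotypes; the per-haplotype rule is the more conservative
  reading and is what the implementation tests.
* **Ratio and thresholds.** r = d_A/d_B, with d_B = 0 and d_A > 0
  giving +∞ (unambiguous identity to one panel; d_A = d_B = 0 is always
  filtered).  The genome-wide mean r̄ is the mean over haplotypes of
  (mean unfiltered d_A)/(mean unfiltered d_B) — a ratio of means per
  haplotype, then averaged — not a mean of window ratios, which would be
  dominated by low-diversity windows.  Calls use r ≤ r̄/8 (origin A) and
  r ≥ 8·r̄ (origin B); equality counts as called.  The 8-fold band is
  wide enough that, at ~100 SNPs per window, crossing it by chance
  sorting of alleles is vanishingly rare; the null-specificity test
  bounds the desk-scale false-call rate at 10⁻³.
* **Region building.** Adjacent same-origin called windows are
  concatenated and same-origin calls with gaps strictly below 50 kb are
  merged — but never across a window called for the opposite origin, so
  A and B calls can never overlap on one haplotype.  Call boundaries
  stay on the 20 kb grid; no sub-window refinement is attempted.

## Recurrence null

Per origin, a run-length track counts how many query haplotypes cover
each base with an HSR.  The null assumes independent haplotypes and
uniform placement over the callable genome — windows with
between-species F_ST > 0.15 (strict), where ancestry can be assigned
confidently; windows with undefined F_ST are non-callable.  The
full-overlap expectation is (∏ f_i)·S_callable with f_i measured against
the callable mask (the same denominator the expectation multiplies by);
the per-k expectation is binomial with F = max f_i, a deliberately
conservative choice.  Recurrent regions use exact count = k by default;
an at-least-k mode exists for binned analyses.  M = log₂(obs/exp) is
computed unrounded and displayed to one decimal.

## Diversity statistics

π and d_xy are classical averages of pairwise differences per accessible
site; denominators are accessible bases per window (window length for
the synthetic data, which emits no invariant records but records
accessibility in the manifest).  F_ST is the Hudson estimator as a ratio
of sums across sites — chosen for its well-defined two-population,
small-sample behavior; published analyses using other estimators (e.g.
pixy's defaults) may differ numerically near thresholds, so no exact
replication of threshold masses is claimed.  A pooled minor-allele
frequency filter of 0.05 applies to F_ST only, never to π/d_xy
denominators.  Monomorphic windows get missing F_ST and are excluded
from the callable mask (conservative).

Enrichment of overlap-count bins in high-F_ST windows (> 0.6 per 5 kb
window, roughly a top-percentile cut in a strongly diverged pair)
assigns each 5 kb window the overlap count at its midpoint and uses an
exact binomial tail with success probability equal to the genome-wide
high-F_ST window fraction; a mid-p option is available.  Exon density
clips edge exons to the region — exact, unlike conventions that count
whole overlapping exons and overestimate slightly.  The
recombination-rate contrast reports length-weighted means and a Welch
t-test over per-map-window rates.

## Recombination clock

Forward decay of an initially chromosome-length tract: each generation,
at most one crossover occurs, with probability p = min(1, G) where G is
the chromosome's genetic length in Morgans (this matches the expected
crossover count for chromosomes under one Morgan while honoring the
one-per-generation cap).  Crossover position is sampled with per-base
probability proportional to local cM/Mb (uniform within a 100 kb map
window).  A crossover inside the surviving tract truncates it on the
side away from the focal point — the HSR physical midpoint — and
crossovers outside the tract are ignored (once the flanks are
non-introgressed, they cannot re-enter).  The replicate's estimate is
the first generation at which the tract is shorter than the observed
HSR; replicates hitting the cap (default 5×10⁵ generations, safely above
the 10⁵ display range) are censored at the cap.  Each HSR gets 100
replicates with a stream derived from (seed, HSR index); summaries are
per-HSR medians and a cohort median that includes beyond-cap loci.
Since truncation always keeps the focal side, the tract after t
generations depends only on the set of crossover positions, which gives
a fast order-free forward sampler (`tract_size_after`) used for
self-consistency checks: tracts decayed to t* = 2000 generations are
re-dated with median within a factor 2 of t*, and on a uniform map the
mean surviving tract matches the 2G/(t·p) closed form within Monte-Carlo
error.  Observed sizes are physical bp; the map enters only through
crossover placement.  Ages convert to years at 2.4 years/generation
(Pacific herring); the kYA display rounds to the nearest thousand years.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the scan relies on,
not coalescent history (no genealogies, no selection, no diploid
genotype error).  Sites arise by a Poisson process at 5×10⁻³/bp
(~100 SNPs per 20 kb window).  Each site is either a species-fixed
difference or a shared polymorphism with Balding–Nichols species
frequencies (ancestral p ~ Beta(1,1), divergence F default 0.2).  The
fixed-difference fraction defaults to the value that makes expected
per-site d_xy hit the 0.43% target given the SNP density (≈ 0.79).

One deliberate consequence: with ~0.43% d_xy packed into ~5 SNPs/kb,
within-species diversity is arithmetically capped well below the
0.2–0.3% seen in real panels of this divergence — realized π is ~0.03%.
(Each SNP can contribute at most 0.5 to π but must average ~0.86 to
d_xy, forcing most sites into the fixed class, which contributes nothing
to π.)  Real data escape the cap by having far more rare variants than a
two-class frequency model; the scan is insensitive to this because it
keys on between-species signal, but absolute π levels from the synthetic
data should not be read as realistic.  π remains monotone in its
controlling parameter (divergence F), which is what the tests check.

Query haplotypes are species-B draws from the realized panel
frequencies, with two refinements:

* At species-diagnostic sites (opposite fixation in the two panels) the
  background carries the species-A allele with probability
  `ils_fraction` (default 0.4), emulating incomplete lineage sorting and
  the old divergence between an admixed population and the reference
  panel of its own species.  Without this, the query background is
  nearly identical to the B panel, the ratio denominator collapses
  (d_B ≈ 0 windows appear) and the B-threshold engulfs the genome once
  admixture drags r̄ down.  At 0.4 the null-run mean ratio lands around
  1.5 — the regime the method is designed for, where both distances are
  comparable and the 8-fold band is far from the background.
* Introgressed blocks form a stationary Boolean process (Poisson starts,
  exponential lengths, mean 100 kb — comparable to empirically called
  HSR sizes), with the start rate −ln(1−admix_prop)/mean so expected
  coverage is exactly `admix_prop` (default 0.25).  Inside a block the
  haplotype copies one species-A panel haplotype with per-site copy
  error 10⁻⁴, so blocks are near-identical, not identical, to a donor.

The recombination map draws gamma-distributed (shape 0.6) 100 kb window
rates rescaled so each chromosome's genetic length is exact (default
2.1 cM/Mb × physical length); a uniform profile is available.  Toy exons
cover ~8.9% of the genome in ~250 bp pieces.  Everything is
deterministic given (config, seed).

## Problem sizes and numerical choices

Default end-to-end runs, tests and the acceptance script use one 10 Mb
chromosome with 16/8/8 haplotypes (~50,000 SNPs) — large enough that
every window-level property is measured on ~500 windows and 100+ blocks
while a full pipeline run takes seconds; the clock self-consistency
experiment uses 50 tracts × 100 replicates.  Thresholds (20 kb, 20,
8-fold, 50 kb, 0.15, 0.6, 5 kb, 2.4 y) are all surfaced as config
fields with the defaults above.  Interval merging is strict at the gap
threshold (a gap of exactly 50 kb is not merged).  Ratio ties at the
call thresholds count as called.  Negative Hudson F_ST values are kept
(unbiased estimators go slightly negative) and only matter through the
strict > comparisons.  JSON/TSV outputs avoid timestamps so a rerun with
the same seed is byte-identical.

## Known limitations

* The null model assumes haplotype independence; the two haplotypes of
  one diploid individual are in reality correlated, which inflates
  observed recurrence slightly relative to the null (matching the
  modeled assumption, not removing it).
* The clock's one-crossover-per-generation Bernoulli is an approximation
  for chromosomes over one Morgan; dating is also conditional on the
  HSR being a single surviving tract, so it over-estimates ages when
  called regions merge several tracts.
* The generator's two-class frequency model understates within-species
  π (above) and contains no LD beyond the planted blocks.
* Exact numerical agreement with analyses based on other F_ST estimators
  is not claimed; the 0.15/0.6 threshold masses depend on the estimator.
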
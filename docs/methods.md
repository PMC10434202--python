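# Methods

This note documents the models, conventions and numerical choices behind
`lohscan`, and what the synthetic-data generator does and does not
emulate.

## Input model and coordinates

The pipeline starts at per-SNP homolog-specific observations of one
diploid isolate: either sequencing allele depths (TSV with `chrom, pos,
w_depth, y_depth`, or a VCF whose AD field is split by matching REF/ALT
against the SNP map's W/Y alleles) or SNP-microarray hybridization
ratios.  Read alignment and raw variant calling are upstream and out of
scope.  All coordinates are 1-based inclusive (SGD convention); BED
exports are 0-based half-open.  The packaged genome fixture uses the real
sacCer3 chromosome lengths and centromere intervals; its ~50,000-site SNP
list and its Ty/repeat intervals are synthetic (deterministically
generated at realistic density), since only positions — not sequence —
enter any computation.

## Relative coverage

For each SNP, `RC_h = depth_h / N` per homolog *h*, with the normalizer
*N* the **median** per-SNP total coverage over SNPs outside repeat
intervals.  On this scale 0 / 1 / 2 copies sit at RC 0 / 0.5 / 1, and on
a fully heterozygous noiseless genome `mean(RC_W + RC_Y) = 1` exactly.
The median rather than the mean keeps the scale anchored when a sizeable
fraction of the genome is aneuploid: with two monosomic chromosomes
(~25% of the genome) the mean total coverage drops by ~12% and drags
every RC value upward, pushing retained two-copy homologs across the
upper state threshold; the median is unaffected for aberrant fractions
below one half (`compute_rc(..., robust=False)` restores the plain
mean).  Repeat-overlapping SNPs stay in the profile, flagged, but never
enter the normalizer.  Array hybridization ratios map onto the same
scale by nearest level (0.2 → 0, 1.0 → 0.5, 1.5 → 1; thresholds at 0.6
and 1.25, ties rounding up), with raw ratios retained.

## Segmentation and event calling

1. **Smoothing** — running median over 5 consecutive SNPs (configurable,
   odd; ends use shrunken windows).  Median, not mean: robust to isolated
   mismapped sites.
2. **State assignment** — thresholds at 0.25 / 0.75 / 1.25 (midpoints
   between the expected levels) give per-SNP states 0–3 per homolog.
3. **Run merging** — runs shorter than `min_snps = 3` merge into the
   longer neighbor.  Three SNPs is the floor at which a gene-conversion
   tract of a few kb is still visible at the strain's ~1 SNP / 240 bp
   density.
4. **Confirmation** — each run's *unsmoothed* RC mean must fit its own
   level better than a neighbor's, else the run is reassigned.  This
   removes runs manufactured by the running median out of noise while
   leaving genuine short tracts (whose raw mean sits at their level)
   untouched.
5. **Boundary refinement** — each transition is re-localised on the raw
   profile by minimal absolute misfit within one smoothing window, since
   the running median shifts transitions by up to half a window.

Joint (W, Y) states over maximal regions are mapped to the taxonomy (see
README).  A whole-chromosome call (trisomy, monosomy, UPD) requires the
aberrant state over ≥ 95% of the chromosome's SNPs, tolerating edge
noise; below that the call degrades to segmental events.  Joint states
outside the taxonomy are reported as `UNCLASSIFIED` rather than dropped;
regions of unclassifiable state shorter than `min_snps` are treated as
noise slivers — when the regions flanking such a sliver carry the same
joint state they are coalesced across it (a noise dip inside one long
event), otherwise the sliver is suppressed.  `UNCLASSIFIED` regions are
diagnostic output, not taxonomy calls: evaluation against simulated
truth scores classified calls only (`match_events(...,
count_unclassified=True)` reverses this).

A terminal-LOH call with a same-direction interstitial tract within 10
SNPs of its breakpoint is merged with it and flagged
conversion-associated (class B5).  The B1/B2 vs B3/B4 split records
whether the homozygous tract is confined to one arm or spans the
centromere; since the published class diagram does not define these
subclasses in text, the mapping is configurable (`taxonomy=` remap).

**Breakpoints.**  Each within-chromosome transition is reported as the
interval between the last SNP in the old state and the first SNP in the
new state (clamped to position 1 or the chromosome length at ends), with
the midpoint as point estimate.  When raw RC is available the interval
additionally widens over sites whose state assignment is ambiguous
(neither level fits better by a 0.25 RC margin): at a 1↔2-copy boundary
single sites misassign with probability a few percent, and the widened
interval restores calibrated containment of the true breakpoint without
affecting clean 0↔2 LOH boundaries, which stay at consecutive SNPs.

**Translocation pairing.**  Terminal duplications pair directly;
terminal deletions pair via their retained complements (the mechanism —
ectopic recombination followed by nondisjunction — leaves the two
retained pieces fused).  A hypothesis requires exactly one
centromere-bearing fragment; the predicted product size is the sum of
fragment lengths.  With several candidates the pairing minimising total
unexplained fragment length wins, ties broken by chromosome order;
leftovers are reported unresolved.

## Rates and statistics

* `rate = n_events / total_divisions`, with
  `total_divisions = Σ n_isolates × cycles × colonies_per_cycle × 25`
  (25 divisions per colony formed from a single cell).  The furfural
  design counts **two** colony formations per cycle — the selection
  plating plus the purification plating — giving 50 divisions/cycle
  (11,350 divisions for 28×8 + 3×1 isolate-cycles); the untreated design
  counts one (10,000 divisions for 20×20).  This two-platings accounting
  is a reconstruction: it is the unique denominator consistent with all
  the published rates, but it is not stated explicitly in the source
  protocol.  Per-base rates divide additionally by the 24-Mb diploid
  genome.  Rates are reported to 2 significant figures with full
  precision retained; published fold changes are ratios of the
  *reported* rates, so `RateEstimate.rate_2sf` reproduces them.
* **Fisher's exact test** (`fisher_exact_2x2`, via `scipy`) is two-sided
  by the point-probability rule: the sum of hypergeometric probabilities
  of tables no more probable than the observed one.  Stated explicitly
  because two-sided conventions differ; the test suite cross-checks it
  against an exact rational-arithmetic enumeration.
* **Region enrichment** uses the χ² statistic over the in-/out-of-region
  cells, df = 1, *no* continuity correction, with expected counts rounded
  to 2 significant figures (their reported precision) before the
  statistic — the convention under which the canonical worked example
  (4 observed vs 1.2 expected of 53 events in a 557,567-bp region of
  24 Mb) gives χ² = 6.68 and p = 0.0097; the exact expectation (1.2313)
  would give χ² = 6.37, p = 0.0116.  Both the exact and reported
  expectations are returned; `round_expected_to=None` disables the
  rounding.  With ~1 expected count the χ² approximation is marginal;
  the exact binomial tail is the cross-check in the tests.
* **Mutation spectra** collapse substitutions by strand symmetry into
  six base-pair classes (CG>TA, CG>AT, CG>GC, TA>CG, TA>AT, TA>GC);
  spectra are compared by Fisher's test on the oxidation-signature
  classes (CG>TA + CG>AT) versus the rest.
* **Mutant frequencies** are per-culture ratios; the median across
  parallel cultures is the headline summary (robust to fluctuation-test
  jackpots) with the mean reported alongside.  No maximum-likelihood
  fluctuation estimator is attempted.
* No multiple-testing correction is applied anywhere, matching the
  analysis being reproduced.

## Synthetic-data generator

The generator emulates the study conditions: ~50,000 SNP sites over 16
chromosomes; per-homolog read depth Poisson with mean
`mean_depth × copies / 2` at a diploid baseline of 50 reads/site; array
ratios at levels 0.2 / 1.0 / 1.5 plus Gaussian noise (σ = 0.05); events
spiked either explicitly or at per-division rates (defaults: the
published furfural-condition rates, with aneuploidy split by the
observed trisomy:monosomy:UPD proportions), accumulated over 400
divisions per isolate (8 cycles × 2 platings × 25); six-class SNV
spectra with 60% (furfural) or 48% (untreated) oxidation-class mass.
Breakpoints snap to inter-SNP midpoints so truth is exact at SNP
resolution; interstitial tract lengths are uniform on 2–50 kb (the
gene-conversion scale); terminal events cover between `min_snps` and 90%
of a chromosome's SNPs so they remain distinguishable from
whole-chromosome events; conflicting placements are re-drawn so realised
counts stay Poisson.  Same seed ⇒ bit-identical outputs.

Deliberately **not** modelled: mapping/GC bias, mappability artifacts
beyond the repeat mask, read-level errors, chromatid-level mechanism of
paired deletions, and clonal mixtures.  Passing the round-trip tests
therefore demonstrates correctness of the calling logic under Poisson
counting noise, not robustness to alignment artifacts in real reads.

## Problem sizes used in tests

The packaged fixture and its invariants run at the full ~50k-SNP
density.  Monte-Carlo checks (recall/precision over ≥200 spiked events,
breakpoint containment, 20-replicate rate recovery) run on 4–8k-SNP maps:
the statistics under test — event counts, containment, rates — depend on
events per isolate, not SNP density, and events remain tens to hundreds
of SNPs long at the reduced density.

## Known limitations

* Events smaller than the SNP spacing (or spanning < 3 SNPs) are
  invisible by construction.
* The aneuploidy rule (≥ 95% of SNPs) cannot represent a chromosome
  carrying both a whole-chromosome change and a further segmental event.
* The 5-FOA / sectored-colony frequency arithmetic is plain per-culture
  division; rates derived from selective plating need a fluctuation
  estimator for rigorous inference.
* Translocation hypotheses are coordinate arithmetic under the
  monocentric constraint; they predict product sizes but not junction
  sequences.
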
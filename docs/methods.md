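# Methods

This note documents the statistical machinery in `sweepscan`, the choices
made where the design was genuinely open, and what the synthetic-data
studies do and do not demonstrate.

## Data model and site filtering

All statistics operate on a `HaplotypeMatrix`: phased, biallelic, fully
called haplotypes for one chromosome, recoded so that 0 is the ancestral
and 1 the derived allele. Ancestral states are resolved, in priority
order, from an explicit TSV, from the VCF INFO `AA` tag (first field,
case-folded), or by assuming REF ancestral with a per-site
`ancestral_known = False` flag. Sites whose resolved ancestral allele
matches neither REF nor ALT are dropped and logged; multiallelic records
are dropped whole (never decomposed); biallelic indels are retained.
Sites with any missing or unphased genotype are dropped rather than
imputed, because haplotype-identity statistics require complete phase.
Hemizygous samples (e.g. male X) contribute one haplotype row, and every
pair count uses the actual number of rows.

Hardy–Weinberg filtering uses the exact conditional test (the sum of
probabilities of all heterozygote counts no more probable than the one
observed, no mid-p correction). It is computed **per population** and a
site fails when any population's p falls below `hwe_alpha = 1e-6`:
pooled testing on structured samples would reject sound sites through
the Wahlund effect. The scan stages additionally require minor-allele
frequency ≥ 0.05; the differentiation stage does not.

## EHH, iHS and xp-EHH

EHH for a carrier set at distance x is the fraction of carrier pairs
identical at every marker from the core out to x. The implementation
refines identity groups marker by marker, so monotone non-increase holds
by construction. The point at distance 0 is 1 by definition. For
**unconditional** curves (both alleles pooled, as used by xp-EHH) the
core site's own alleles never split the groups: the statistic compares
the homozygosity decay of the flanking haplotypes, matching the behaviour
of the standard scan software. The alternative (splitting at the core)
makes an incomplete sweep *reduce* the test population's homozygosity at
exactly the swept sites and flips the expected sign of xp-EHH there; we
verified this empirically on planted sweeps before fixing the convention.

iHH integrates the EHH curve over map distance by trapezoids, summing
both directions, including the terminal trapezoid that ends at the first
point at or below the cutoff (`ehh_cutoff = 0.05`). Map distance comes
from a genetic map when supplied and otherwise from physical positions at
a constant 1 cM/Mb. Spans wider than `gap_scale_bp = 20 kb` contribute
area scaled by `gap_scale_bp / gap`; a span wider than `max_gap_bp =
200 kb` discards the site. Curves that reach the end of the data before
decaying to the cutoff mark the site `truncated`; truncated sites are
excluded from scoring by default (`trunc_ok` includes them), the standard
treatment near chromosome ends.

Raw iHS is `ln(iHH_derived / iHH_ancestral)`. **Sign convention:**
positive means unusually extended derived haplotypes. The classic
literature statistic is oriented the other way; only |iHS| enters any
threshold here, but the orientation is stated because downstream
consumers of the sign (beneficial-allele assignment) depend on it.

Raw xp-EHH is `ln(iHH_test / iHH_ref)` over the site set shared by the
two populations (matched on chrom+position). The integration span for
both populations is fixed where the *pooled* two-population EHH decays to
the cutoff, which makes the statistic exactly antisymmetric under
population swap. Positive values mean longer haplotypes — stronger
recent selection — in the test population.

## Standardization, significance, windows

Raw iHS depends on derived-allele frequency, so scores are z-scored
within 100 equal-width derived-frequency bins (the usual genome-wide
normalization default); xp-EHH uses a single bin. Bin moments use the
population denominator n. Bins with fewer than two scores or zero spread
leave their records unscored (`unstd_bin`). Empirical p-values are
two-sided ranks of |standardized score| against the pooled distribution
(minimum attainable p = 1/N), because the significance thresholds —
|iHS| > 2.75 and |xp-EHH| > 2.806, both corresponding to empirical
p < 0.01 on genome-scale data — are symmetric. Region detection tiles
each chromosome with non-overlapping 100 kb windows anchored at
coordinate 0 and flags windows holding ≥ 20 scored SNPs beyond the iHS
threshold.

## Differentiation

Per-site pairwise FST is computed with two estimators. The Hudson
estimator is a pure function of the two derived-allele frequencies and
haplotype counts, so it can be evaluated directly from published
frequency tables; it is the estimator used for the reproduction of the
published values. The Weir–Cockerham variance-components estimator
a/(a+b+c) is computed from diploid genotype counts (haploid reduction
a/(a+b) when haplotypes do not pair into individuals). Negative per-site
estimates are clamped to zero, as in the source tables. Outliers are
one-sided high-tail empirical ranks against a genome- or simulation-wide
background at α = 0.05.

For *multi-locus* summaries (e.g. drift recovery) the package provides
the standard Hudson combination Σnum/Σden. The mean of per-site ratios
is systematically pulled toward zero by rare variants with tiny
denominators (we measured ≈0.047 versus a ratio-of-sums of ≈0.089 under
a T=20, N=100 split whose expectation is 0.0954); the ratio of sums is
the estimator with the drift expectation 1 − (1 − 1/2N)^T.

## Linkage disequilibrium

LD is computed directly on phased haplotype counts (D, D′ with the
frequency-bound Dmax, r² = D²/(pA(1−pA)pB(1−pB))); this differs from the
genotype-composite r² of unphased tools and is the cleaner quantity when
phase is known. Decay curves thin sites by seeded i.i.d. Bernoulli(0.01)
sampling, form all retained same-chromosome pairs within 200 kb, and
average r² in non-overlapping 5 kb bins; chromosomes are processed
separately and pooled into shared bins, and cross-chromosome pairs are
never formed (physical distance across a concatenation join is
meaningless). The candidate↔query linkage rule reports pairs with
r² > 0.95 plus any pair in complete LD, where D′ = 1 is detected by an
exactly empty haplotype class, not a floating tolerance.

## Candidate calling

A site is a candidate when three lines of evidence agree: |iHS| above
threshold in some population P; |xp-EHH| above threshold in a pair
involving P with the sign pointing at P (strict mode; a permissive
any-pair mode exists); and at least one pairwise-FST outlier. The
beneficial allele is the allele whose extended haplotypes drive the
signal: derived when the driving iHS is positive under this package's
orientation, ancestral otherwise — published candidate tables mix both
cases, so the designation cannot simply default to the derived allele.

## Synthetic data

The generator is a discrete-generation Wright–Fisher model over 2N
haplotypes: each offspring copies a parent haplotype pair with crossovers
at Poisson(rL) uniform positions, mutations arise at Poisson(μL) fresh
integer positions (infinite sites, so ancestral states are known by
construction), and with s > 0 parent haplotypes carrying the sweep allele
are drawn with genic weight 1+s. Sweeps are introduced as a single copy
and conditioned on reaching `target_freq` by restarting on loss (capped).
Two-population mode copies one equilibrium ancestor into two lineages; in
sweep mode the selected lineage's conditioning time sets the clock and
the neutral lineage drifts for the same number of generations, so the
samples are contemporaneous. All randomness flows from one seed through
`SeedSequence` spawn keys, so any replicate is reproducible in isolation.

Two initialization models exist. `founders` starts from identical
haplotypes and needs ~10N burn-in generations to reach mutation–drift
equilibrium. `coalescent` draws the full population from the standard
neutral coalescent with recombination at the same N, μ, r (binary
mutations on a discrete genome; sites hit more than once are discarded to
keep the 0 = ancestral coding exact) and starts the forward dynamics at
equilibrium immediately; the validation studies use it because it removes
the burn-in cost without changing the forward model under study.

Engineering notes: columns are stored unsorted during evolution (crossover
segment parity depends on positions, not storage order) and compacted
lazily; positions of lost mutations are recycled during single-population
burn-in only (after a split a position lost in one population may still
segregate in the sister population), fixed positions stay blocked, and
position-space exhaustion raises rather than degrading.

**Study conditions.** Desk-scale studies use population-scaled
parameters: θ/bp and ρ/bp near the human ~10⁻³ at small N (e.g. N = 500,
μ = r = 5·10⁻⁷), regions of 60–200 kb, samples of 40–100 haplotypes.
The planted-sweep study uses N = 1000 (2Ns = 200), a 100 kb region, and
conditioning at derived frequency 0.75.

**What the studies show — and a known limitation.** Calibration of the
standardization, drift recovery, oracle equivalence and the structural
invariants transfer directly to real data. Absolute detection *rates* do
not: the haplotype contrast a sweep leaves scales with the ratio of the
neutral coalescent timescale (∝ 2N) to the sweep duration
(≈ (2/s)·ln(2Ns)). At human Nₑ ≈ 10⁴, s = 0.1 gives a ratio of ~10², and
genuine sweeps reach standardized scores beyond ±2.75. At the largest
desk-scale forward-WF population the test budget allows (N = 1000) the
ratio is ~17, and the planted sweep site scores z_iHS ≈ 1.2 ± 0.6 and
z_xp ≈ 1.5 ± 0.6 — clearly enriched (it beats the 95th percentile of
frequency-matched neutral scores far more often than chance, and its FST
is essentially always an outlier) but short of the fixed genome-scale
thresholds. Consequently the planted-sweep study demonstrates detection
at the study's own empirical significance level, while the fixed
|iHS| > 2.75 ∧ |xp-EHH| > 2.806 intersection calls essentially nothing at
this scale — neither sweeps nor neutral sites. This is a property of the
scale, not of the implementation, and is left visible rather than papered
over by recalibrated thresholds.

The simulator also omits features of real data: no demographic history
beyond a clean split, no recombination hotspots, no background selection,
no genotyping error, and a uniform map. Passing tests therefore validate
the statistics' mechanics and calibration, not their field performance on
1000 Genomes-scale inputs.

## Numerical choices

- EHH uses exact allele equality; no missing data reaches the module.
- The walk stops at the first marker with EHH strictly below the cutoff;
  that marker is included in the curve and its trapezoid in the integral.
- Standardization sd uses the population denominator n.
- `hudson_fst` groups its two sampling-correction terms so the estimator
  is exactly symmetric in floating point.
- The HWE exact test works in log-space (gammaln) with a 1 + 1e-12 tie
  tolerance when summing probabilities no larger than the observed one.
- Windows are anchored at coordinate 0; output intervals are 0-based
  half-open.
- Empirical p-values are computed on standardized scores (the thresholds
  are quoted in standardized units).
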
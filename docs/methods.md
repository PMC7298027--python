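# Methods

This note documents the statistical methods implemented in `equipop`, the
modelling assumptions behind the synthetic-data generator, the numerical
conventions, and the choices made where the design was genuinely open.

## Data model and conventions

Genotypes are diploid alternate-allele counts in {0, 1, 2} with a reserved
missing sentinel (never 0/1/2); phased haplotypes are complete binary
matrices with exactly two rows per sample.  Coordinates are 1-based
inclusive in memory and in MAP/VCF; BED output is 0-based half-open.  Every
statistic that sees genotypes states its missing-data handling: variant-wise
deletion (per sample, per pair, or per hierarchy level) — no imputation,
except PCA's optional mean imputation behind an explicit flag (default off).

## QC filter chain

Filters run in the fixed precedence missingness → MAF → HWE, and a variant
failing several criteria is counted once under the first.  The HWE test is
the 1-df chi-square on expected genotype counts at the sample allele
frequency (monomorphic sites return p = 1).  The chi-square approximation
was chosen over the exact test: at the scale this filter operates the two
agree, and the approximation is checkable against a closed-form enumeration
oracle (the suite verifies every genotype triple with total ≤ 30 against an
erfc-based evaluation).  "Corrected for multiple testing" is implemented as
Bonferroni over the number of variants actually tested; the test subset of
samples is an explicit parameter because HWE filtering is typically run on a
designated multi-origin subgroup rather than the whole cohort.

Cohort merging intersects on (chromosome, position), reconciles swapped
allele pairs by recoding calls 2 − x, drops irreconcilable pairs, and also
drops strand-ambiguous A/T and C/G variants: without strand information a
silent mis-strand merge corrupts every downstream frequency-based statistic,
so these are removed and counted rather than guessed at.

LD pruning follows the sliding-window protocol (window 50 SNPs, step 5,
r² > 0.5 by default): while any retained pair in the window exceeds the
threshold, the later-positioned member of the highest-r² pair is removed;
ties go to the latest pair, making output order-stable and deterministic.

## Diversity and relatedness

Per-sample expected homozygosity uses the small-sample-corrected
heterozygosity 2p(1−p)·n/(n−1) summed over that sample's non-missing
variants, giving the method-of-moments F.  Fhat3 is the
correlation-between-uniting-gametes estimator
(1/m) Σⱼ [x² − (1+2p)x + 2p²] / (2p(1−p)), with MAF = 0 variants excluded
and m reduced for missing calls.  Allele frequencies for Fhat3 and IBD
default to the full input sample set — the natural choice when no external
reference panel exists — and are parameterizable.  The Fhat3 exclusion
threshold is recomputed per cohort as mean + 2·SD rather than hard-coding
any particular cohort's value.

PI_HAT comes from the standard method-of-moments IBS→IBD solution: observed
IBS 0/1/2 counts over jointly non-missing variants are equated to their
expectations given per-variant allele frequencies, solved sequentially for
P(IBD = 0, 1, 2), clamped to [0, 1] and renormalized.  The finite-sample
bias-correction factors some implementations add are omitted; at the panel
sizes used here the uncorrected estimator places duplicates at ~1.0,
parent–offspring pairs at ~0.5 and unrelated pairs under 0.1, which is what
the downstream greedy filter consumes.  That filter repeatedly drops the
sample participating in the most pairs at or above the IBD cap (ties to the
later sample) until no conflicting pair remains — deterministic, possibly
sub-optimal in removal count; the suite compares it against an exhaustive
minimum-removal search on small instances.

Group comparisons of observed heterozygosity use Levene's test for variance
heterogeneity followed by the Tukey–Kramer procedure (scipy's
implementations; only the resulting statistics are exposed).

## Differentiation

Pairwise F_ST is the Weir & Cockerham (1984) estimator: per-variant variance
components a, b, c with missing-aware per-population sample sizes, combined
as the ratio of sums over polymorphic variants.  Permutation significance
shuffles population labels over samples; p-values use the +1 correction so
the smallest attainable value is 1/(n_perm + 1).

AMOVA decomposes allele-level squared differences over the four-level
hierarchy groups / populations / individuals / allele copies.  The variance
components are obtained by the sums-of-squared-cell-totals method for
unbalanced nested random-effects designs: per variant, the nested sums of
squares and the expected-mean-square coefficients are accumulated, pooled
over variants, and the resulting triangular linear system solved top-down.
With complete data this reduces to the classical coefficients (e.g. the
within-individual SS is half the het count per variant); with missing data
each variant contributes its own design.  Φ_CT, Φ_SC, Φ_IS, Φ_IT follow
from the components; negative component estimates are reported as estimated.
Per-level permutation schemes: whole populations among groups (Φ_CT),
individuals among populations within groups (Φ_SC), and allele copies among
individuals within populations (Φ_IS) — the last implemented by reassorting
each population's allele pool per variant, which is valid because no
within-population statistic depends on which individual slot a genotype
occupies.

The pairwise estimator and the AMOVA decomposition are deliberately two
different formalisms; for biallelic SNPs their estimates are near-identical,
and the suite checks that Φ_SC recovers the simulated Balding–Nichols
parameter within Monte-Carlo error.

## PCA

Samples are rows, variants columns; each column is centered and scaled to
unit variance (ddof = 1), monomorphic columns dropped (recorded in the
result), and scores come from the SVD with percent variance as the
eigenvalue share.  Because the SVD sign is arbitrary and downstream
selection rules ("PC1 < c") are sign-dependent, each component's sign is
fixed so its largest-magnitude loading is positive; thresholds for selection
rules should be re-derived from the cluster geometry of each dataset, never
copied across datasets.

## Selection scans

**H** — at each SNP x, the mean over haplotype pairs of the shared-tract
length ℓᵢⱼ(x) = R − L, where L is the position of the nearest discordant SNP
strictly left of x (or the chromosome's first SNP if none), R the nearest
discordant SNP strictly right (or the last SNP), and ℓ = 0 when the pair is
discordant at x itself.  This truncation-at-terminal-SNPs convention is
locked by an exhaustive O(n²m²) oracle that the implementation must match
exactly.

**H12** — haplotypes grouped by exact allele-string identity within
non-overlapping windows of a fixed SNP count; with class frequencies
p₁ ≥ p₂ ≥ …, H12 = (p₁+p₂)² + Σᵢ≥₃ pᵢ², reported at the window's center
SNP.  Windows are non-overlapping (one value per window center); overlap
stride is not offered because every consumer of the track works at the
one-value-per-window granularity.

**Tajima's D** — per window, π from the derived-allele counts, θ_W = S/a₁,
and the standard variance normalization (constants a₁, a₂, b₁, b₂, c₁, c₂,
e₁, e₂); windows with no segregating site emit no value.

Before window statistics, high-density regions (>16 SNPs per 0.1 Mb, bins
anchored at position 1) are thinned to 13 SNPs per bin, evenly spaced by
rank with the bin's first and last SNP always kept — the thinning is
idempotent.

Tracks are min–max scaled to [0, 1] per statistic per group, genome-wide
over the tracks scaled together (a single genome-wide threshold per scan);
Tajima's D is negated first so sweep signals point up.  Peaks are maximal
runs of consecutive positions at or above the chosen percentile of the
scaled track (99th by default); runs closer than a merge gap (100 kb
default — an artifact parameter, configurable) are merged, intervals
spanning more than 5 Mb are discarded as broad unspecific signals, and
single-position runs are widened by half the median inter-position spacing.
Known artifact regions (e.g. centromeric LD anomalies) can be excluded by
subtracting intervals before intersection rather than by hard-coded
coordinates.  Peak intersection sweeps interval endpoints, counts how many
input peak sets cover each elementary segment, and reports maximal regions
above a support minimum, ranked by count with ties to the smallest interval.

## Local ancestry

The classifier is a window-independent naive-Bayes assignment, not a
conditional-random-field: reference groups are summarized by pseudo-count
shrunken allele frequencies ((c+1)/(k+2), so log-likelihoods are finite),
each non-overlapping window of 50 SNPs gets per-group log-likelihoods
assuming site independence, and the softmax posterior under a uniform prior
must reach 0.99 for a label — otherwise the window is unassigned.
Consecutive same-label windows merge into segments tiling the scanned span;
fractions are base-pair weighted over both haplotypes.

Ignoring within-window linkage is the main caveat: the likelihood is
overconfident when sites are correlated.  The stringent 0.99 threshold is
the working mitigation, and the validation surface is simulation recovery —
on 9-generation, 30%-admixture mosaics with donor/recipient drift 0.2
apart, labeled windows are >99% base-pair correct with ~10–15% unassigned,
and a diverged negative-control panel captures <0.1% of labeled bases.  The
window size default (50 SNPs) is set so that the expected tract scale at 9
generations (~5.6 Mb at 1 cM/Mb) spans many windows at typical array
densities.  Claims about real admixed cohorts require real reference
panels; what passing tests show is that the assignment contract (posterior
threshold, unassigned class, fraction accounting) behaves correctly when
the generating process is known.

## Synthetic data

The generator produces exactly the structure each analysis assumes, feature
by feature:

* **Structured populations** — Balding–Nichols: per-population frequencies
  Beta(p(1−F)/F, (1−p)(1−F)/F) around global frequencies drawn
  Uniform(0.05, 0.95); F = 0 degenerates to shared frequencies.  The
  standard four-population fixture uses drift values (0.01, 0.03, 0.15,
  0.30), giving pairwise differentiation spanning roughly 0.02–0.23.
* **Reference panels are linkage-free** (independent Bernoulli sites).
  Haplotype structure enters only through mosaics and sweeps, so each
  statistic's null and alternative are controlled by construction and no
  coalescent machinery is needed at desk scale.  The flip side: neutral
  backgrounds lack real LD, so scan specificity on real data (where LD
  produces chance haplotype sharing) will be somewhat lower than on these
  fixtures.
* **Admixture mosaics** — breakpoints are a Poisson process at rate
  G × r (r = 1 cM/Mb by default, uniform map; analyses are physical-distance
  based), tract sources i.i.d. from the admixture proportions, alleles
  copied verbatim from a uniformly chosen reference haplotype; truth tracts
  are recorded and are exactly consistent with the emitted alleles.
* **Sweeps** — one donor haplotype copied into ⌊carrier_fraction·n⌋ carriers
  over [pos − Exp(L), pos + Exp(L)] tracts, producing a shared core with
  decaying extent: elevated H and H12, depressed π at the locus.  Defaults:
  carrier fraction 0.6, mean one-sided tract 500 kb.
* **Neutral sites** — derived-allele count i drawn with P(i) ∝ 1/i, placed
  on a uniform random haplotype subset; under this law E[π] = E[θ_W] = 1/a₁
  per site, so windowed Tajima's D is centered at zero by construction.
* **Ascertainment** — variants with MAF at or below the floor are dropped
  (the floor set to 0 is the identity), mimicking array site selection.

All generators are pure functions of (parameters, seed); identical seeds
give byte-identical output.

## Problem sizes and defaults

The study-scale thresholds are carried as defaults throughout: MAF 0.01,
genotyping-rate cutoff 0.20, HWE α 0.005 (Bonferroni), LD 50/5/0.5, IBD cap
0.25, 20 000 permutations, 351-SNP scan windows, 99th-percentile peaks with
5 Mb broad-region exclusion, ancestry posterior 0.99, admixture age G = 9.

The test and acceptance fixtures are desk-scale renderings of those
conditions.  The sweep fixture uses a 20 Mb chromosome at 8 kb SNP spacing
(a density at which the 16-per-0.1 Mb pruning rule is inactive) with 50
haplotypes and 51-SNP windows: the window-to-sweep-tract ratio (~0.4 Mb
windows vs ~1 Mb shared cores) matches the regime in which window
statistics resolve sweeps, whereas 351-SNP windows at that spacing would
span 2.8 Mb and dilute a 500 kb signal below detectability — on real
chip-density data (SNPs every few kb before pruning) the 351-SNP default
corresponds to the same regime.  The ancestry fixture is a 100 Mb
chromosome at 10 kb spacing with 40-haplotype panels.  F_ST/AMOVA recovery
runs at 2 × 50 diploids × 5000 variants; permutation counts in tests are
99–999 (the +1-corrected p-values need no more resolution at these sizes),
while the pipeline default remains 20 000.

## Known limitations

* Arlequin-style AMOVA-based pairwise F_ST is replaced by Weir–Cockerham
  1984; for biallelic SNPs the difference is well inside the estimators'
  sampling noise, but exact numerical equality with Arlequin output is not
  a goal.
* PI_HAT omits small-sample bias corrections (above).
* The ancestry classifier ignores linkage within windows and phase-switch
  errors; it is validated as a recovery procedure, not as a reimplementation
  of a CRF-based tool.
* Tract lengths are physical (bp); no recombination-map awareness.
* The pipeline's stage cache is file-existence based: stages recompute in
  memory on every run (cheap at desk scale) and skip only the file writes,
  so "cached" guarantees byte-stable outputs rather than saved CPU.
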
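# Methods

This note documents the models, estimators, numerical conventions and
design choices behind the package, and what the synthetic-data validation
does and does not demonstrate.

## Coordinates, genotypes, missing data

All internal coordinates are 0-based half-open; conversion to VCF's
1-based convention happens only in the VCF reader/writer, and BED files
are already native. Genotypes are coded 0/1/2 (hom-ref/het/hom-alt) with
−1 for missing; a half-missing call (`./1`) is treated as fully missing —
the simplest consistent rule, and the common practice. Only bi-allelic
SNPs are ingested; multi-allelic records and indels are skipped with a
logged count. Every per-site statistic uses pairwise-complete allele
counts; a site with fewer than two non-missing alleles in a population is
skipped for that population.

## Windowed statistics

Windows slide per chromosome with starts at 0, step, 2·step, … while the
start is inside the chromosome; the final windows truncate at the
chromosome end. Defaults are 100 kb windows with a 10 kb step.

**Nucleotide diversity.** Per site, π̂ = 2p(1−p)·n/(n−1) with p the
alternate-allele frequency among the n non-missing alleles — the unbiased
mean pairwise difference. Window π is the summed site values divided by
the window's bp span (*per-bp*, not per-SNP): per-bp normalisation makes
the π-ratio scale-free, which the empirical-tail selection depends on.
Windows without SNPs report π = 0.

**Tajima's D.** Computed from genotype allele counts, treating the 2N
alleles as the sample (no phasing needed under infinite sites):
D = (π_sum − S/a₁)/√(e₁S + e₂S(S−1)) with a₁ = Σ1/i, a₂ = Σ1/i²,
b₁ = (n+1)/(3(n−1)), b₂ = 2(n²+n+3)/(9n(n−1)), c₁ = b₁ − 1/a₁,
c₂ = b₂ − (n+2)/(a₁n) + a₂/a₁², e₁ = c₁/a₁, e₂ = c₂/(a₁²+a₂). S = 0
yields an undefined value, propagated as `None`, never NaN. n < 4 is
rejected (unstable variance terms). With missing data the constants use
the population's full 2N while π_sum and S use realized per-site counts;
the synthetic data contain no missingness, so there the two coincide
exactly. Note D has a small negative expectation at finite sample sizes
even under neutrality (≈ −0.11 at n = 25, θ = 10 by simulation here); the
neutral-calibration check bounds |mean D|, it does not assert a zero mean.

**F_ST.** Hudson's estimator with per-site components
N = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1),
D = p₁(1−p₂) + p₂(1−p₁), aggregated per window as ΣN/ΣD (ratio of
averages). Chosen for robustness to unequal sample sizes and for the
closed-form Balding–Nichols limit E[F_ST] = F that the tests exploit.
Window values can be slightly negative (the estimator is unbiased around
zero); they are never clamped internally. ΣD = 0 gives an undefined
window.

**π-ratio.** π_reference/π_target per window; undefined when the target
population's π is 0. Undefined windows are excluded from threshold
computation and can never be selected. This matters for hard sweeps: a
fully fixed region has π_target = 0, so its fully-interior windows drop
out of the π-ratio scan and the sweep is detected through its flanking
windows instead. A config flag (`treat_zero_pi_as_max`) optionally treats
those windows as maximal instead; it is off by default, keeping the
empirical quantiles interpretable.

**LD r².** Phased input: classical r² = D²/(p_A p_a p_B p_b) from
haplotype frequencies. Unphased: squared Pearson correlation of genotype
dosages over pairwise-complete samples (composite/Rogers–Huff). Zero
variance at either locus is undefined and skipped. The decay curve bins
all intra-chromosome pairs at distance ≤ 1000 kb (inclusive) after a MAF
≥ 0.05 and call-rate ≥ 0.6 filter; D′ is deliberately not computed (the
analyses here report only r² decay).

## Sweep selection

The threshold for tail fraction t over N finite values is the k-th largest
with k = ⌈tN⌉, ties included downstream (selection uses ≥), so selected
counts are reproducible integers and may exceed k on ties. F_ST and
π-ratio cutoffs are resolved independently from their own distributions
and applied as a conjunction — the upper-right quadrant of the
(π-ratio, F_ST) cloud. Selected windows merge when overlapping or abutting
(configurable join gap, default 0); region F_ST/π-ratio are member maxima,
Tajima's D the member mean (undefined only if all members are undefined).
Both the quantile rule (computed after excluding undefined values) and the
resolved cutoffs are echoed in the run manifest.

## ROH detection

PLINK-style scan per sample and chromosome: every window of 50 consecutive
SNPs is a "hit" if it has ≤1 heterozygous and ≤5 missing calls; each SNP's
hit fraction is hits/windows among the windows *fully inside the
chromosome's SNP list* that cover it; SNPs at fraction ≥ 0.05 are
ROH-eligible; maximal eligible runs, split at inter-SNP gaps > 1000 kb,
become segments if they have ≥50 SNPs, span ≥100 kb, and average ≤100 kb
per SNP. Segments are half-open, first member SNP to last member position
+1; het/missing counts inside are recorded but not re-filtered. A
chromosome with fewer SNPs than the window yields no calls (logged, not an
error).

Two edge behaviors follow from the hit-fraction rule and are intentional:
the outermost SNP of a perfectly homozygous tract flanked by
heterozygosity has hit fraction 2/50 = 0.04 < 0.05, so detected boundaries
sit one SNP inside the tract; and an isolated het inside a long
homozygous run does not break the segment (every window covering it has
het count 1). The exhaustive-enumeration oracle in the tests pins both.

**F_ROH** = Σ segment lengths / L_AUTO per sample (non-autosomal segments
dropped), decomposed into left-closed length classes [0.1, 0.5), [0.5, 1),
[1, ∞) Mb; the class components sum to the total to 1e−12. A
per-chromosome variant divides by that chromosome's length.

**Common ROH** is implemented as support-depth intervals: maximal
intervals where ≥ `min_samples` (default 2) distinct samples are in ROH,
with per-sample coverage merged first so overlapping segments of one
sample cannot inflate depth. The literature uses "common ROH" loosely;
this definition is explicit and configurable.

**ROH islands**: the per-SNP ROH ratio is the fraction of a population's
samples whose ROH cover the SNP. The island threshold is the top-1%
empirical value (same k-th-largest rule) among SNPs with nonzero coverage
— computing the tail over covered SNPs only keeps the threshold meaningful
when most of the genome has zero coverage; a mode restricted to SNPs
inside ROH is available. Member SNPs within 100 kb (configurable; no
canonical value exists) merge into one island spanning first to last
member SNP.

## Synthetic data and what the tests show

The genome-scale generator draws SNP positions as a Poisson process (mean
spacing 1 kb by default), an ancestral frequency p ~ Uniform(0.05, 0.95)
per SNP, population frequencies from Balding–Nichols Beta(p(1−F)/F,
(1−p)(1−F)/F) with F = 0.2 by default (strong breed-level divergence), and
per-sample haplotypes as independent Bernoulli draws. Sweeps are planted
by resampling a region's target-population genotypes from
p′ = (1−i)·p + i·[p ≥ 0.5] (intensity i = 1 fixes every SNP); autozygous
tracts by collapsing one sample's hets to a random homozygote (probability
½ each, seeded — autozygosity of a random haplotype). Truth files record
the planted intervals and the exact planted autosomal fraction.
Everything is reproducible from a single seed; planting at intensity 0 is
the identity, and re-planting a tract is idempotent.

Deliberate simplifications: sites are independent given their frequencies
(no background LD, no recombination map), sweep intensity is
phenomenological (no selection dynamics), and there is no genotyping
error or missingness. Consequently the recovery tests demonstrate the
*estimators and detectors*, not robustness to LD structure, call errors,
or demography; LD-dependent behavior is exercised separately on
constructed duplicated-column cases and on phased coalescent output. A
separate single-locus Kingman coalescent with infinite-sites mutations
(exponential coalescence at rate k(k−1)/2, Poisson(θ/2 · branch length)
mutations) supplies the neutral replicates for Tajima's D calibration and
matches Watterson's E[S] = θa₁ and the msprime site-frequency spectrum.

**Validation problem sizes.** The suite uses sizes chosen to make each
check statistically meaningful on a single CPU in minutes: 200 random
small matrices (≤10 samples, ≤200 sites) for the π oracle at 1e−12; 50
random windows for the Tajima's D oracle at 1e−10 plus 500 neutral
replicates (n = 25, θ = 10) for calibration; ~50 k Balding–Nichols SNPs
(2 × 25 samples, F = 0.2) for F_ST recovery within ±0.02; 100 random
inputs (≤500 SNPs) for segment-exact ROH oracle agreement; a 20 Mb
chromosome at 1 kb spacing with planted tracts for ROH recovery at
fractions 0.1/0.2/0.3; and a 3 × 10 Mb genome with three planted sweeps
(intensities 0.9/0.95/1.0) for the scan's recall and precision.

**ROH recovery fixture.** Boundary precision is measured on a maximally
heterozygous background sample: on a drifted background, runs genuinely
extend outward through homozygosity-by-chance, so the planted boundary is
not identifiable to one SNP no matter the detector. With an all-het
background the boundary is information-limited only by SNP spacing, and
the detector localizes every planted tract to within one inter-SNP gap
(one SNP index) of the tract's edge SNPs, with bp-level recall ≥ 0.9 and
|F_ROH − planted fraction| ≤ 0.05.

**Sweep recovery metric.** Window-level recall is measured over planted
windows with a *defined* π-ratio: windows interior to an intensity-1.0
sweep have π_target = 0 and are excluded by the same rule that excludes
them from selection, so they cannot be recalled by construction; the
intensity-0.9/0.95 sweeps dominate the truth set. Region-level precision
at the 1% tail counts merged regions overlapping any planted interval.

## Pipeline conventions

One YAML config drives the run; every default equals the published
parameter set (window 100 kb/10 kb; the ROH block above; tails 1%/5%; LD
1000 kb/MAF 0.05/call-rate 0.6; pruning 50/10/0.1). LD pruning
(greedy, PLINK `--indep-pairwise`-style, dropping the lower-MAF SNP of the
worst pair, later position on ties) is applied before the ROH stage by
default, mirroring the published command order; a config switch applies it
to all stages or none, since pruning before ROH detection is unusual and
the original ordering is ambiguous. Undefined statistics are empty fields
in the TSVs. A rerun with the same config and seed reproduces every output
table byte-identically; the manifest records resolved thresholds, stage
row counts, seed and per-stage wall-clock (the only fields that vary
between identical reruns are the timestamp and timings).

## Known limitations

- No multi-allelic or indel support; no phasing/imputation; no haplotype
  statistics (XP-EHH/iHS).
- Weir–Cockerham F_ST is not implemented; Hudson only.
- The sweep caller's empirical-tail thresholds are relative: on a genome
  with no true sweeps it still selects the tail fraction of windows.
- Tajima's D assumes the infinite-sites count of segregating sites;
  back-mutation and sequencing error are not modelled.
- The coalescent oracle is single-locus and non-recombining by design.
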
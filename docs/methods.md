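# Methods

This note documents the models behind each stage, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions a user should know before
trusting an edge case.

## Ploidy classification from allele balance

At a heterozygous site the fraction of reads carrying the alternate
allele (BAF) is centered on the allelic dosage: 1/2 for a diploid
heterozygote, 1/3 or 2/3 for a triploid one. Classification compares
two per-site likelihood models of the alternate read count k at depth d:

- diploid: k ~ BetaBin(d, μ = 1/2, ρ)
- triploid: k ~ ½ BetaBin(d, μ = 1/3, ρ) + ½ BetaBin(d, μ = 2/3, ρ)

with one shared overdispersion ρ (parameterized so that
Var(k/d) = μ(1−μ)(1 + (d−1)ρ)/d; ρ = 0 reduces to the binomial). Using
the same ρ in both models keeps the parameter count equal, so the
comparison needs no penalty term. ρ defaults to a method-of-moments
estimate from the pooled squared BAF deviation around the nearest of
{1/3, 1/2, 2/3}, clamped to [0, 0.45].

Site selection: biallelic sites with AD-based depth ≥ 10 and BAF in
[0.10, 0.90]. The band removes homozygous calls and sequencing-error
tails while leaving the 1/3 and 2/3 modes untouched. A floor of 200
retained sites (configurable) guards against classifying strains with
too little heterozygosity; strains whose two model log-likelihoods
differ by less than 2 are flagged low-confidence. Only 2n and 3n are in
the model space — the intended panels contain nothing else — and
classification deliberately ignores aneuploidy: the genome-wide call
comes first, chromosomes are revisited afterwards.

## Chromosome copy number and aneuploidy

Per strain, window mean depths (DP) are computed over a fixed tiling
(window size configurable; 500 bp at the desk-scale genome, 50 kb at
full scale — roughly constant site count per window). A chromosome's
depth ratio is the median of its window means over the genome-wide
median of all window means; using medians makes the call robust to
local coverage excursions and means the statistic is invariant to
uniform depth rescaling. The copy number is round(ratio × ploidy), but
a chromosome may deviate from the genome ploidy only when

- |ratio × ploidy − ploidy| > 0.2 copies, and
- more than 80% of its windows deviate in the same direction.

Both thresholds are exposed in the API. They are conservative on
purpose: a whole-chromosome event moves every window coherently by a
half or third of the mean, so requiring directional consensus
suppresses false aneuploidy from noisy window means without hurting
recall (measured on synthetic panels: recall 100% of 30 simulated
whole-chromosome events, 0/170 false positives at 60×). Chromosomes
with fewer than 3 data windows inherit the genome ploidy with a logged
warning rather than guessing from a handful of windows. Sub-chromosomal
CNVs are out of scope — the depth model has no segmentation.

## Biallelic filtering, IBS and π

A site is kept when exactly two distinct alleles are observed across
the panel's genotypes and at least two genotype states remain after
diploidized projection (a site where every strain is heterozygous
carries no between-strain information under the dosage projection and
is removed). Observed allele pairs other than (ref, alt₁) are recoded
rather than dropped.

Mixed-ploidy genotypes are projected onto diploid dosage
{0,1,2,3} → {0,1,1,2} before IBS and π. This is the convention that the
standard SNP toolchain applies to such panels; it is lossy for
triploids (1 and 2 alternate copies collapse) and is documented as
such. π uses the unbiased per-site form
(nⱼ/(nⱼ−1))·2p̂ⱼ(1−p̂ⱼ) with allele copies counted as two per called
strain; `projection="true"` counts actual copies instead. The
denominator L defaults to the sum of contig lengths — a genome-wide
per-base diversity, not a per-variant-site diversity. IBS distance is
not guaranteed metric; triangle-inequality violations are possible and
deliberately not asserted.

Homozygous-SNP density counts sites where a strain is homozygous for
the non-reference allele per genomic window, then standardizes each
window across strains (population SD; zero-variance windows become
all-zero). Standardizing across strains matches the question the
heatmap answers — which strains are unusual in this region; the
alternative per-strain standardization is behind a flag.

## Multiscale bootstrap (AU) support

Cluster support follows the multiscale bootstrap: for relative scales
r ∈ {0.5, 0.6, …, 1.4}, B feature resamples of size round(r·m) are
drawn with replacement (features = SNP sites for the genetic tree, PC
columns for the fitness tree), the tree is recomputed, and each cluster
of the full-data tree is scored by its occurrence fraction BP_r
(leaf-set equality). The probit profile z_r = Φ⁻¹(1−BP_r) is fit as
v√r + c/√r by weighted least squares (weights B·φ(z)²/(BP(1−BP)), the
delta-method variance of z_r), and AU = 1 − Φ(v − c). BP is reported at
r = 1. BP values are clamped to [1/(B+1), 1 − 1/(B+1)] before the
probit.

Degenerate profiles need a convention: the two-basis fit cannot
represent a profile that is constant across scales, so a cluster whose
BP is identical at every scale (including the single-scale case) is
assigned AU = BP directly; a cluster present in every replicate at
every scale gets AU = 1, absent everywhere AU = 0. Real profiles vary
across scales and never hit this path.

## Growth rates

μ is the maximum over sliding windows of the least-squares slope of
ln(OD − blank) vs time, among windows whose every point exceeds a
minimum OD and whose fit reaches R² ≥ 0.95; if no window passes with a
positive slope the curve is flagged no-growth with μ = 0. Defaults:
13-point windows (4 h at 20-min sampling), min OD 0.03, OD floor 1e-3
before the log.

The window length deserves a note. Short windows (≈5 points) are the
intuitive choice but are noise-dominated at low OD: with additive OD
noise σ = 0.005, ln-OD noise at OD 0.05 is ≈10%, and taking the maximum
over ~100 overlapping windows selects upward noise excursions
(extreme-value bias; observed mean absolute error ≈13%). Long windows
average over the logistic bend and bias downward. Thirteen points with
a strict R² gate balances the two: on simulated panels (noise
σ = 0.005) the estimator recovers μ within 10% for ≈96% of curves with
mean absolute relative error ≈4%. Both knobs are configurable.

Fitness is the replicate-matched ratio μ_condition/μ_YPD (replicate i
divided by replicate i), then averaged over replicates — this cancels
replicate-level inoculum effects exactly; the reference column is
dropped from the analysis matrix. Mean-over-mean normalization can be
obtained by averaging rates first.

## Morphology Z-scores

Per trait, a one-way fixed-effect Gaussian model over strains is fit by
OLS with treatment coding against the reference strain; the reported
Z-score is the Wald statistic of each strain contrast,
(mean_s − mean_ref)/SE with the SE from the pooled residual variance.
The reference row is exactly zero and Z is invariant to affine
transformations of a trait. A single Gaussian family is used for all 31
traits — trait-specific error families (beta-like for ratio traits,
counts for patch numbers) would be more faithful per trait but would
make Z-scores incomparable across traits; this is a documented
simplification. Traits with zero pooled variance are dropped with a
warning.

Wilcoxon–Mann–Whitney comparisons use the exact null distribution when
n_A + n_B ≤ 30 and the data are tie-free, otherwise the normal
approximation with tie and continuity corrections; either mode can be
forced. Complete separation at n = 9 vs 11 yields the exact two-sided
floor 2/C(20,9) ≈ 1.19 × 10⁻⁵.

## PCA, PC clustering, PLS-DA, VIP

PCA centers and (by default) unit-variance-scales columns (sample SD;
constant columns dropped with a warning when scaling) and reports
explained percentages over all min(n−1, p) components, summing to 100.
PC selection takes the smallest k whose cumulative contribution ratio
reaches the threshold (default 0.90).

The fitness tree clusters strains by average linkage on Chebyshev
(maximum-coordinate) distances over the selected PC scores — the
"maximum" distance of the standard R toolchain — with AU support from
resampling PC columns. With very few selected PCs this resampling is
degenerate (resamples of 2 columns barely vary with scale); the
synthetic fitness panels are therefore generated with
strain × condition interaction structure that spreads variance over
5–8 PCs, as real panels show.

PLS-DA regresses centered class-indicator columns on autoscaled
predictors via NIPALS PLS2; per-component explained X-variance is
‖t_a‖²‖p_a‖²/‖X‖²_F × 100. VIP_j = √(p Σ_a SSY_a (w_aj/‖w_a‖)² / Σ_a SSY_a)
with SSY_a = q_a²·t_aᵀt_a; mean(VIP²) = 1 holds identically and
variables above 1 are conventionally influential.

The genotype–phenotype correlation takes, for each unordered strain
pair, the Pearson correlation of the two trait vectors, and correlates
it with genetic distance across all n(n−1)/2 pairs; the quoted P comes
from the usual t-transform and ignores pair non-independence (pairs
share strains), so a Mantel permutation option is provided. The 2×2 χ²
uses the Pearson statistic without continuity correction by default
(Yates behind a flag), df = 1, upper-tail P.

## The synthetic-data generator

The generator emulates the study design the package targets: 20 strains
in three lineages (8/9/3, the small lineage most diverged), 9 diploids
and 11 triploids, six chromosomes with full-scale lengths summing to
13.12 Mb scaled by a configurable factor (default 1/100 for fast
in-memory panels), four aneuploid triploids (three chromosome gains,
one loss), target π = 0.018, 60× mean coverage with gamma-mixed Poisson
depth (dispersion 0.15) and per-read error 0.002. A single integer seed
drives named substreams (effects, genotypes, growth, morphology), so
each generator can be rerun independently and reproducibly.

Genotypes follow a stylized shared-ancestor allele model. Each site
belongs to one category: ancestral heterozygous (45% weight — all
strains het; these drive BAF-based ploidy inference and emulate the
high heterozygosity of wild mixed-ploidy isolates), ancestral
homozygous-alternate (10%), lineage-differentiating (weight 0.15 ×
divergence per lineage; the lineage carries a derived het (60%) or
hom-alt (40%) state), and strain-private het (weight 0.01 × divergence
per strain). Sites are placed uniformly per chromosome, counts
proportional to length. The total site count is calibrated
analytically: the expected π contribution of each category under the
package's own estimator (after biallelic-segregating filtering) is
computed in closed form and the site count set to
target_π · L / E[contribution]. Measured panels land within ~2% of
target. With all divergence scalers zero the panel is clonal
(identical projected genotypes, IBS ≡ 0) and the target is
unreachable; a fallback density of 0.01 sites/bp applies.

Depth at a call scales with (chromosome copy number / genome ploidy),
so aneuploid chromosomes shift coverage by the right factor, and
heterozygous dosage on a trisomic chromosome is drawn from {1, 2},
giving the 1/3–2/3 allele-balance modes. Alternate read counts are
binomial around the allelic fraction perturbed by the error rate, and
ref + alt = DP exactly.

Growth curves are logistic, OD(t) = K/(1 + ((K−OD₀)/OD₀)e^(−μt)) plus
Gaussian noise (σ = 0.005), sampled every 20 min for 48 h (145 points),
3 replicates. Defaults chosen for realism: OD₀ = 0.05, K = 1.8
(microplate OD₆₁₀ of yeast in rich media saturates around 1.5–2), base
rate 0.40 h⁻¹ with per-category condition multipliers (carbon 0.75,
environment 0.85, toxin 0.65) over a 24-condition panel (YPD + 23).
True rates combine per-(lineage, condition) lognormal effects
(σ = 0.25 × divergence, log-effects clipped at ±0.45 — fitness ratios
between yeast lineages realistically span ~0.6–1.6×, and unclipped
tails produced biologically implausible μ near 0.9 h⁻¹), a per-strain
multiplier (σ = 0.05, cancelled by YPD normalization), and a
strain × condition interaction (σ = 0.08) that gives the fitness matrix
the spread-out PC spectrum real panels show. The reference condition is
exempt from the interaction term: a YPD-specific deviation would divide
into all 23 ratios and inject a rank-one common mode that turns single
strains into Chebyshev outliers; keeping the reference
interaction-free is a stylization, and panels normalized against a
noisy reference condition will cluster less cleanly than these
simulations suggest.

Morphology tables draw n = 5 replicates per strain × trait around
strain means composed of a fixed trait baseline, a per-strain deviation
(σ = 0.12) and an additive ploidy effect (+0.8) on the six size-class
traits for triploids — large enough that diploid and triploid strain
means separate completely, as the motivating panel's cell-size data do.

What the generator does **not** emulate: linkage disequilibrium,
recombination or any mutation-process realism; mapping artifacts,
GC-coverage bias or sub-chromosomal CNVs; lag phases, diauxie or death
phases in growth curves; plate spatial effects; trait-specific
morphology error families or cross-microscope batch effects. Passing
recovery tests on these panels shows the estimators are correct under
the stated models, not that they are robust to every artifact of real
data.

## Problem sizes

The test suite and the acceptance script run desk-scale panels: the
default 20-strain panel uses a 1/100 genome (≈131 kb, ≈17k sites), the
200-strain classification benchmark a 1/500 genome, chosen so the whole
analysis (including two B = 1000 bootstrap trees) completes in well
under a minute on one CPU while keeping ≥ 500 heterozygous-candidate
sites per strain and ≥ 40 sites per depth window — comfortably above
the floors where the methods degrade.

## Known limitations

- The diploid dosage projection discards triploid dosage information;
  IBS distances between triploids are compressed.
- The ploidy model space is {2n, 3n}; haploids or tetraploids would be
  forced into the nearer class (the likelihood gap flag is the only
  guard).
- AU values inherit Monte-Carlo error of order 1/√B; B = 1000 gives
  roughly ±0.01–0.02 near 0.95.
- The genotype–phenotype correlation P-value treats strain pairs as
  independent; use the Mantel option when the inference matters.
- The growth-rate estimator assumes a single exponential phase; diauxic
  curves yield the faster phase's rate.
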
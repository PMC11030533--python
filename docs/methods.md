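# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices and the known limitations of
`focaldel`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Gene-focused coverage model

**Binning.** Per-base depths over the target window are collected into
fixed-width bins (default 50 bp) as per-bin *means*; the final partial
bin is averaged over its actual span, so a constant-depth track yields
an exactly constant bin vector. Positions absent from the depth track
count as depth 0 and are logged. The GRCh37 window
chr5:98,190,408–98,262,740 yields 1,447 bins; the GRCh38 window
chr5:98,853,485–98,930,272 yields 1,536.

**Normalization.** Each track is divided by its own genome- (or
panel-) wide mean sequencing depth, making the two vectors directly
comparable and unit-free.

**Paired regression.** Normalized tumor bins are regressed on normal
bins by OLS with intercept. The regression is oriented *tumor on
normal* so that the slope β₀ is the tumor/normal coverage ratio — the
quantity the downstream adjustment β_t = (β − 1 + c)/c requires (β ≤ 1
under loss). The shared bin-to-bin structure (mappability, GC) spans a
wide dynamic range while the per-bin sampling noise is small, which is
what lets an OLS slope measure the ratio with little errors-in-variables
attenuation. Outliers are removed by iterative trimming of standardized
residuals |r| > 3 (at most 5 rounds, recorded in a mask); bins with
zero normal coverage never enter the fit. The intercept α is a
diagnostic: |α| > 0.1 flags a suspect fit (residual structure a pure
proportional-loss model cannot explain). σ is the standard error of the
slope.

**Housekeeping null.** Slopes of a panel of presumed copy-neutral genes
(default size 14) fitted *on the same sample pair* provide an empirical
null absorbing sample-specific technical wobble. The target slope is
scored as z = (β₀ − mean)/sd with a lower-tail normal p-value. Panel
identities are configurable (BED); the test suite uses simulated
copy-neutral windows. A zero-variance panel returns p = NaN with a
warning rather than a fabricated significance.

## 2. Cellularity and loss propagation

The cellularity posterior arrives as a grid (e.g. sequenza's contour
marginalized over ploidy). A Beta distribution is moment-matched:
with grid mean m and variance v, s₁ = m·k and s₂ = (1 − m)·k where
k = m(1 − m)/v − 1. A variance floor of 1e-6 handles near-degenerate
grids; a grid whose Beta fit would be improper (mean outside (0,1),
k ≤ 0) is rejected.

`propagate_loss` draws β ~ Normal(β₀, σ) and c ~ Beta(s₁, s₂)
independently (n = 10,000 by default, seed recorded; interval stability
is about ±0.005 at that size) and forms the loss level
1 − β_t = (1 − β)/c per draw. Draws with c < 0.05 are rejected and
resampled — the division blows up at vanishing purity and the source
method is silent on that regime — with the count logged, and the
propagation refused outright if more than half the posterior mass sits
below the cutoff. The point estimate is the median clipped to [0, 1];
66% and 95% percentile intervals are reported; raw draws are retained
unclipped for diagnostics.

The loss level is a **copy fraction**: f/2 for a heterozygous deletion
in a fraction f of tumor cells, f for a homozygous one. The formulas
imply the copy-fraction reading; zygosity is resolved separately
(below), after which f follows.

**Deletion call.** A sample is called deleted iff the housekeeping
one-sided p < 0.05 AND the 66%-interval lower bound exceeds 0.05 (both
thresholds configurable). The conjunction guards against
significant-but-immaterial slopes and against material-looking but
insignificant ones.

## 3. Subclonal LOH zygosity test

Restricted to the maximally lost subregion — found by binary
segmentation of the per-bin log coverage ratio with a Gaussian BIC
acceptance rule (two parameters per changepoint), returning the
minimum-mean segment of at least 20 bins, or the whole window when no
changepoint is accepted (flagged "no loss signal" when its mean ratio
exceeds 0.95) — germline-het SNP allele counts are scored under two
hypotheses:

* **heterozygous**: expected VAFs (1/(2 − c·f), (1 − c·f)/(2 − c·f)),
  with the lost allele unknown, giving a symmetric 50/50 binomial
  mixture per SNP;
* **homozygous**: both alleles lost equally, VAF stays 1/2 (binomial at
  p = 0.5) while total depth drops.

Each hypothesis' marginal likelihood averages the per-draw likelihood
over 2,000 joint (c, loss) draws taken from the propagated loss
distribution, solving f per hypothesis (f = 2·loss het, f = loss hom,
clipped to [0, 1]). The report is a Bayes factor; |log₁₀ BF| < 0.5 is
called indeterminate. The published description of this step defers the
statistic's exact form to supplementary material; the binomial-mixture
marginal-likelihood comparison here is a principled stand-in with the
same inputs and decision structure, and is flagged as such. Read-count
overdispersion is not modelled by default (this keeps the likelihood
exact and testable against closed forms); the binomial can be swapped
for a beta-binomial without changing the interface.

A genuinely undecidable regime exists: a fully clonal homozygous
deletion leaves no reads at the locus, so no VAF evidence distinguishes
the hypotheses — the caller returns indeterminate there, which is the
correct answer rather than a failure.

## 4. Ancestry verification

Genotype dosage matrices (0/1/2, missing imputed to the SNP mean) are
mean-centered and projected onto the top two principal components
(deterministic sign: the largest-magnitude loading of each component is
positive). Each population is modelled as a bivariate Gaussian with
**full** covariance on the PC plane — the "non-naïve" reading, i.e. the
PC correlation is modelled rather than assumed away; `diag` and
`shared` covariance structures are available for sensitivity checks.
Priors default to uniform; a singular class covariance receives a 1e-6
ridge (logged). Samples whose maximum-posterior population differs from
the declared label are flagged.

The simulator's three-population Balding–Nichols model (ancestral
frequencies uniform on (0.1, 0.9), per-population frequencies
Beta-distributed with divergence F = 0.15, 3,000 SNPs, 100 samples per
population) mirrors the panel-size and divergence regime of
continental-ancestry panels; real panels have LD, missingness structure
and admixture this model omits, so the near-perfect held-out accuracy
measured here is an upper bound, not a field estimate.

## 5. Signature refitting

Catalogs are non-negative-least-squares refits against a COSMIC-layout
signature matrix (channel rows × signature columns, columns summing
to 1); weights are reported as attributed mutation counts
(unnormalized). The active set is chosen by greedy best-improvement
forward selection: each iteration refits with every unselected
candidate added and admits the one with the largest cosine-similarity
gain, if that gain exceeds the margin (0.001). The source procedure
says only that components were tried "one by one"; best-improvement is
the order-free reading and the per-iteration trace (candidate, cosine,
gain) is recorded so the path is auditable. Forward addition only — no
removal step — as written. SBS96 catalogs are built from SNVs with ±1 bp
context under the pyrimidine-strand convention; indel and SV catalogs
are accepted pre-channelized.

Tests use a seeded sparse-Dirichlet synthetic library (concentration
0.2, well-separated columns) rather than shipping COSMIC matrices; the
refitter is layout-compatible with any COSMIC TSV.

## 6. Genomic scar scores

From allele-specific segments (A ≥ B ≥ 0) and a karyotype (lengths,
centromere intervals):

* **HRD-LOH**: segments with B = 0, A ≥ 1, longer than 15 Mb, not
  spanning a whole chromosome;
* **LST**: per arm (segments clipped at the centromere), after merging
  equal-state neighbours and iteratively discarding segments < 3 Mb,
  breakpoints between adjacent differing segments each ≥ 10 Mb;
* **ntAI**: A ≠ B segments touching a telomere and not spanning the
  centromere.

The HRD score is their sum. Adjacent same-state segments are merged
before counting, so scores are invariant to how a constant region is
split. The 15/10/3 Mb constants are exposed in the API: the source
study computed these scores with an external package whose exact rules
it does not restate, so clinical-threshold comparability depends on
matching that implementation's constants; the standard published
definitions are pinned here. Ploidy correction of the LST threshold
(subtracted in some implementations) is off by default and not
currently implemented beyond the exposed constants.

The toy karyotype (3 chromosomes of 100/80/60 Mb, 1 Mb centromeres at
the midpoints) gives the scores telomere/centromere context without
real assembly tables; real genomes have acrocentric arms and
heterochromatic gaps it ignores.

## 7. Cohort statistics

Fisher's exact test (one-sided hypergeometric tails; the usual
minimum-likelihood rule two-sided) with a zero-margin guard (p = 1,
warned); per-group deletion frequencies reported to one decimal;
overlap summaries with conditional percentages in both directions;
pairwise two-sample Mann–Whitney rank-sum tests (exact null when both
groups have n ≤ 20 and no ties, otherwise the tie-corrected normal
approximation — the groups compared are independent samples, so the
rank-sum test is the applicable Wilcoxon variant); and Pearson
correlations with SE = sqrt((1 − r²)/(n − 2)) and the two-sided t test.
P-values are unadjusted by default (matching how such cohort analyses
are reported); Benjamini–Hochberg is available via a flag.

One documented inconsistency in the motivating study's printed numbers:
its TMA EA frequency is printed as "11%" while 14/109 = 12.8%, and its
SPOP-overlap section counts 95 deleted cases where the frequency
section's groups sum to 93. The arithmetic here recomputes from the
printed counts; both printed figures are preserved verbatim only as
documentation.

## 8. What the simulator does and does not emulate

The paired-coverage generator draws per-bin total base counts from a
negative binomial (overdispersion 1e-3, i.e. a few percent CV at 60×
in 50-bp bins) around a mean carrying a lognormal bin bias (σ = 0.4)
shared between tumor and normal, with the tumor mean scaled by
1 − c·f/2 (het) or 1 − c·f (hom) inside the deleted subinterval. It
reproduces the one property the regression exploits — strong paired
correlation with a copy-ratio signal — and deliberately omits GC trend
along the genome, capture-edge effects, mapping artifacts and
segmentation breakpoint uncertainty. Passing recovery tests therefore
demonstrate the estimator's correctness under its stated model, not
robustness to every real-data pathology; the outlier trimming and the
housekeeping null are the pipeline's defenses against the latter and
are tested separately with injected artifacts.

Het-SNP counts are exact binomial draws from the same dosage model the
zygosity caller uses (one shared formula — by construction the
generator cannot drift from the likelihood). Depths are Poisson around
the truth coverage ratio with a floor of one read.

Default study conditions: 60× mean depth for both tracks, the 72,333-bp
GRCh37 gene window (1,447 bins), 30 het SNPs at 60×, cellularity grids
of 99 points with posterior SD 0.05, signature catalogs of thousands of
mutations, 3,000-SNP ancestry panels. These are the regimes the
acceptance analyses run at; problem sizes are recorded alongside every
reported number.

## 9. Numerical and design choices

* Regression orientation (tumor on normal) deliberately inverts the
  printed equation of the source method, whose downstream formula
  requires the tumor/normal ratio; recorded here as the package's
  reading of an internally inconsistent description.
* Monte-Carlo defaults: 10,000 draws (propagation), 2,000 joint draws
  (zygosity), all seeded; reports embed seeds.
* Cellularity truncation at 0.05; variance floor 1e-6 in the Beta fit.
* Binary segmentation: minimum split 5 bins, minimum reported segment
  20 bins, BIC penalty 2·log(m) per changepoint.
* Degenerate inputs fail loudly (zero catalog, zero-variance normal
  track, rank-deficient genotype matrix, n ≤ 2 correlation) rather than
  returning sentinel numerics, except where a flagged sentinel is the
  documented contract (zero-sd housekeeping panel, zero-margin Fisher).
* Coordinates are 1-based inclusive at every interface (samtools-depth
  convention); bedGraph input is converted on read; bin indices are
  0-based half-open internally.

## 10. Limitations

* The cellularity grid is consumed as given; joint cellularity–ploidy
  model selection is upstream (sequenza's job).
* The zygosity likelihood is this package's own construction (see §3);
  its Bayes-factor scale should not be compared across tools.
* Scar-score clinical thresholds are implementation-sensitive (§6).
* The cohort-scale biological findings of the motivating study (real
  WES/WGS cohorts under controlled access) are not reproducible here;
  the acceptance analyses cover the arithmetic on printed counts and
  the method's behaviour on synthetic truth.
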
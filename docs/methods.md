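# Methods

This note records the statistical models behind `chromsig`, the
assumptions they make, the defaults and why, the numerical choices,
and what the synthetic-data tests do and do not establish about real
data.

## Coordinates and consensus peaks

All intervals are 0-based half-open (BED convention); GTF input is
converted on read. A single internal convention avoids off-by-one
drift between stages.

"Found in at least k samples" is made operational as single-linkage
merging: the union of all per-sample peaks is merged wherever two
peaks share at least one base (bookended intervals do not merge), and
the occupancy of a merged region is the number of distinct samples
contributing at least one overlapping peak. Identical intervals within
one sample are deduplicated first. The occupancy therefore counts
sample support for the merged region as a whole; when samples cover
disjoint parts of a long merged region the per-base support can be
lower. Consensus output is idempotent: re-merging it at k = 1 returns
it unchanged.

Peak annotation is midpoint-based with fixed precedence promoter >
exon > intron > downstream > distal intergenic. The promoter window
defaults to 3,000 bp upstream / 0 bp downstream of the TSS and the
downstream window to 3,000 bp past the 3' end; these mirror common
annotation-tool defaults and are configurable. Target-gene assignment
uses a different, purpose-specific rule: a site is proximal to a gene
iff it overlaps the gene body or the strand-oriented 20-kb window
upstream of the TSS. Several sites may hit one gene and one site
several genes, which is why a few hundred sites typically compress to
a shorter gene list.

Per-chromosome enrichment of a peak group is an upper-tail binomial
test: k of the group's n peaks on a chromosome against the background
fraction p₀. The default background is the full consensus peak set
(enrichment relative to where this factor binds at all); a
genome-length-fraction background is selectable when the question is
enrichment relative to the whole genome. A chromosome with group peaks
but no background peaks gets p₀ floored at 1/(|background|+1) and is
flagged.

## Moderated differential binding

Counts are modelled on the log₂ counts-per-million scale,
y = log₂((count + 0.5)/libsize × 10⁶), with library size equal to the
sample's total fragment count and no control-track subtraction. The
half-count offset keeps zeros finite; it makes depth-scale invariance
approximate rather than exact, negligibly so away from zero counts.
Fragments are assigned to regions by midpoint, so a fragment can never
be double-counted at a region boundary.

The per-region two-sample test moderates variances empirically: with
pooled within-group variance s²_g on d = n_A + n_B − 2 degrees of
freedom and a scaled inverse-chi-square prior (d₀, s₀²), the posterior
variance is s̃²_g = (d₀s₀² + d·s²_g)/(d₀ + d) and
t = Δmean/(s̃_g·√(1/n_A + 1/n_B)) has d + d₀ df. The prior is
moment-matched on the log scale: the mean and variance of log s²_g are
equated with their sampling moments under the prior, using the
digamma/trigamma relations of the log-chi-square distribution; when
the observed spread of log s²_g does not exceed pure chi-square
sampling noise, d₀ = ∞ and every region shares s₀². Forcing d₀ = 0
recovers the ordinary t-test and d₀ = ∞ a pooled-variance z-like
statistic; both limits are exposed for diagnostics. With fewer than 10
regions the prior is unidentifiable and the code falls back to the
ordinary t-test with a warning. Discoveries are controlled by
Benjamini–Hochberg at q ≤ 0.10 by default.

The moderated-t-on-log-CPM route assumes roughly log-normal within-
group variation of NB counts; at the coverage levels simulated
(mean ≈ 100, dispersion 0.05) the planted-effect recall is ≥ 0.8 and
the empirical FDR stays under the nominal-plus-slack 0.15 in the test
suite, but very low counts would strain the normality assumption — an
exact NB test is deliberately out of scope.

Label-permutation robustness enumerates every distinct assignment of
the samples into groups of the original sizes (C(8,3) = 56 for
5-vs-3), reruns the full test including re-estimation of the prior,
and reports each relabeling's discovery count plus the rank of the
true labeling (1 + number of strictly better mislabelings).
Enumeration is refused above 10,000 relabelings.

Sample clustering uses 1 − Pearson correlation on log-CPM with average
linkage and a 2-group cut; correlation distance makes it invariant to
per-sample affine shifts. The enrichment-ratio classifier labels a
sample primary-like iff mean enrichment over the primary-associated
panel strictly exceeds that over the resistant-associated panel
(ratio > 1); an exact tie reads as resistant-like (documented,
arbitrary), and a zero denominator yields +inf with a flag.

## Short time-series partition

Candidate temporal profiles are all integer level sequences starting
at 0 with per-step changes in [−c, c]; there are (2c+1)^(T−1) of them.
Defaults c = 2 and m = 50 representative profiles follow the common
defaults of short-time-series profile clustering; the minimum
expression change is 0.5 on |log-ratio to time 0|. Representatives are
chosen greedily to maximize the minimum 1 − Pearson distance to the
already-chosen set, starting from the always-included flat profile
(whose correlation with anything is defined as 0, hence distance 1).
Each greedy pick also brings its mirror (negated) profile, keeping the
library closed under negation: induced and repressed patterns are then
treated exactly symmetrically, and sign-flipping the data provably
swaps the induced and repressed gene sets. Ties break by enumeration
order, making selection fully deterministic.

Genes are assigned to the best-correlated profile (zero-variance genes
to the flat profile; ties to the lowest profile id). Significance per
profile compares the observed assigned count with its expectation
under independent permutation of each gene's timepoint order —
exhaustive over all T! orders when T! ≤ 5040, otherwise 1,000 seeded
draws — through a Binomial(n, expected/n) upper tail, Bonferroni-
corrected over the m profiles at level 0.05. Because Pearson
correlation is shift-invariant, permuting the log-ratio vectors is
equivalent to permuting the underlying raw series and re-referencing,
so the null is the exchangeability of raw timepoints. Note the null a
flat gene satisfies is "log-ratios of an exchangeable raw series"
(which share the reference timepoint's noise), not i.i.d. noise pinned
to 0 at t₀.

The partition classes genes on significant profiles by the sign of the
profile's mean level; min-change-filtered genes join the unaffected
set; genes on non-significant profiles are reported but belong to no
set. On the default synthetic time course (T = 6, linear rise to
amplitude 1.0 ≈ a twofold expression change by 24 h, noise σ = 0.15
per timepoint) a planted 40/50/10 induced/unaffected/repressed split
is recovered within ±10% per class.

## Survival signature

Expression is probe-averaged and mean-centered per gene before
training. The Cox partial likelihood uses Efron's tie correction
throughout; `cox_fit` maximizes it by Newton–Raphson with
step-halving, reports standard errors from the observed information,
errors out after 100 iterations or when coefficients diverge past
|β| = 50 (monotone likelihood/separation), and its score norm at the
optimum is below 1e−6.

The elastic-net Cox solver minimizes
−(1/n)·ℓ(β) + λ(α‖β‖₁ + (1−α)‖β‖₂²/2) on internally standardized
covariates (α = 0.5 by default; the L1/L2 mix is a design choice kept
configurable). Each IRLS step builds the gradient and diagonal
curvature of the Efron partial likelihood with respect to the linear
predictor (O(n) by cumulative sums when event times are distinct,
grouped Efron sums under ties, curvature floored at 1e−10), forms the
working response, and solves the penalized weighted least squares by
cyclic coordinate descent. The λ grid is log-spaced from λ_max (the
smallest penalty with an empty active set) over 100 points down to
λ_max/100 by default, solved with warm starts; an explicit grid may
include λ = 0, solved as unpenalized Newton. At the default tolerance,
an active-set Newton polish refines every grid point until the KKT
residuals of the penalized problem — stationarity on the active set,
|score| ≤ λα off it — are at machine precision (verified < 1e−7 along
the path in the tests, and equal to the unpenalized fit at λ = 0
within 1e−4).

Nested cross-validation: the outer loop is leave-one-out; for each
held-out patient the inner 10-fold loop picks λ by minimizing the
cross-validated partial-likelihood deviance in the Verweij–van
Houwelingen form, −2(ℓ_full(β_k) − ℓ_train(β_k)) summed over folds,
which stays well defined for small fold remainders. The active set at
the chosen λ is refit by unpenalized Cox on the outer training set and
the held-out patient's prognostic index is its linear predictor under
that refit; an empty active set gives PI = 0 and is flagged. The final
model takes the arithmetic mean λ̄ of the per-fold λ's (the natural
scale was chosen over the log scale as the simpler reading; per-fold
λ's differ little under leave-one-out so the choice is second-order),
solves the full-data problem at exactly λ̄, and refits the active set
unpenalized to produce the published-style per-gene coefficients.
Two numerical guards: inner-CV fold paths are advanced λ-by-λ and stop
once the summed deviance has risen for 8 consecutive grid points past
its minimum (the curve is evaluated only within the outer training
set, so the held-out patient cannot influence its own tuning — the
inner fold assignment is likewise drawn from an RNG keyed by (seed,
outer-fold index), making the held-out PI exactly invariant to that
patient's own outcome); and unpenalized refits keep at most
n_events − 1 covariates (the largest penalized coefficients), falling
back to the penalized coefficients for a fold whose refit still
degenerates.

Risk groups split at PI = 0 with the boundary assigned to low risk.
Stratification is assessed by the standard two-group log-rank test
(Σ(O−E))²/ΣV against chi-square with 1 df. The time-horizon AUC treats
events by 60 months as cases and event-free follow-up beyond it as
controls, excluding patients censored earlier — a simple binary ROC
rather than inverse-probability-of-censoring weighting, which
overweights late-censored controls slightly and is documented as a
limitation. Multivariate adjustment fits PI jointly with Gleason
(ordinal), pathologic T stage (ordinal-coded from the parsed
stage/substage), node status (binary) and log₂ PSA. The D'Amico
classification uses the standard published thresholds (high: cT ≥ T2c
or Gleason ≥ 8 or PSA > 20; intermediate: cT2b or Gleason 7 or
PSA 10–20; else low). PCA projections fix each component's sign by
making its largest-magnitude loading positive, so score plots are
reproducible.

## Synthetic data

Every generator is a pure function of its seed and serializes its
ground truth. Peak landscapes place shared and group-specific peak
slots with spacing that prevents cross-slot merging even at maximal
jitter (±50 bp by default), over a toy two-chromosome genome, with
gene models placed so a configurable fraction of slots are
promoter/genic. Counts are negative binomial with variance
μ + φμ² (φ = 0.05, baseline mean 100, library sizes uniform around
2×10⁷, scaled by the geometric-mean-relative library size); planted
regions multiply the group-B mean by the fold change. Cohorts draw
expression i.i.d. standard normal per gene; event times are
exponential with rate h₀·exp(Σβᵢxᵢ) (h₀ = 0.01/month), and
independent exponential censoring is calibrated by root-finding so the
expected censoring fraction matches the request (default 0.75,
matching recurrence rates of prostatectomy cohorts); clinical
covariates are drawn independently, or with Gleason tied to the
linear-predictor rank in the confounded mode for adjusted-hazard
tests. The default cohort is 131 patients over a 49-gene panel with 9
signature genes, mirroring the training-cohort geometry the pipeline
was designed around; `simulate_discovery_bundle` links all generators
through one gene universe so the whole pipeline runs against known
truth.

What passing these tests shows: the algorithms recover what they are
supposed to recover under their own model assumptions, the exact
statistics agree with enumeration oracles, and the cross-validation
never leaks outcome information. What they do not show: robustness to
copy-number artifacts, probe chemistry, batch effects across cohorts,
GC or fragment-length biases in counts, non-proportional hazards, or
informative censoring — none of which the generators emulate.

## Problem sizes and tolerances in the shipped tests

The test suite and acceptance script run nested CV on 200-patient ×
100-gene cohorts with a 50-point λ grid down to λ_max/20 (the package
default grid of 100 points to λ_max/100 is finer than the deviance
curve needs at these cohort sizes); differential-binding simulations
use 2,000 regions; temporal recovery averages three seeded replicates.
Exact statistics are compared to oracles at 1e−9 or tighter; KKT
residuals at 1e−7; Cox coefficient recovery at n = 2,000 within 0.1
absolute.
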
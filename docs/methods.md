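# Methods

## The problem and the model

During focused-ultrasound (FUS) blood-brain-barrier disruption (BBBD), a
brain region is exposed simultaneously to a mechanical stimulus (circulating
microbubbles oscillating in the acoustic field) and a biochemical stimulus
(plasma constituents leaking into parenchyma). Two continuous per-animal
metrics proxy these stimuli: microbubble activation (MBA), a harmonic-emission
ratio measured by passive cavitation detection, and MR contrast enhancement
(CE). This package regresses post-treatment bulk RNA-seq counts on these
metrics to find genes whose expression tracks the *magnitude* of disruption
rather than a binary treated/untreated contrast.

Counts for gene *i* in sample *j* are modelled as negative binomial,

    K_ij ~ NB(mu_ij, alpha_i),        Var = mu + alpha mu^2,
    ln mu_ij = ln s_j + beta0_i + beta1_i x_j + (confounder terms),

with `s_j` a median-of-ratios size factor, and `x_j` one of two encodings of
the dose metric sharing the canonical log link:

- **exponential form**: `x_j = metric_j`, so expression is proportional to
  `exp(beta1 * metric)`;
- **linear form**: `x_j = ln(metric_j)`, so expression is proportional to
  `metric^beta1`, which contains straight proportionality at `beta1 = 1`.

Untreated samples are assigned metric value 1, so the linear-form covariate is
exactly 0 at baseline and the intercept is the untreated mean. This encoding
choice is the package's own: a log-link GLM admits no literal "linear in the
metric" mean without abandoning the link, and the baseline-at-1 convention
falls out naturally under `ln(metric)`.

Sex, anesthesia (KA vs Iso) and sequencing batch enter as dummy-coded
covariates (reference = lexicographically first level) whenever at least two
levels are present among the samples a model uses; single-level covariates
are dropped with a logged warning. Crossing metric (CE, MBA) x form (linear,
exponential) x timepoint (6 h, 24 h) yields the 8 model permutations. MBA
models exclude treated samples without a usable cavitation recording;
untreated samples (assigned MBA = 1) are always retained.

## The MBA metric

All hydrophone pulses of a sonication session are appended (plain
concatenation, no gap samples, rectangular window by default with a Hann
option) and Fourier transformed once, giving bin width `fs / total_samples`.
MBA is the mean of the top-5 peak amplitudes in a 200 Hz band centred on the
second harmonic (2.22 MHz) divided by the same statistic in an equally wide
reference band placed where the hydrophone is insensitive, so the denominator
tracks the noise floor and MBA ≈ 1 means no harmonic emission. Peaks are
local maxima of the magnitude spectrum within the band; if a smooth band
holds fewer than 5, the largest remaining bins pad the list, so flat bands
degrade gracefully instead of erroring. Amplitudes are linear magnitude (a dB
ratio would not be dimensionless). The reference-band centre has *no*
default: it is hardware-specific, and must be stated; the synthetic generator
uses 3.5 MHz. Requesting a band that holds fewer than 5 bins raises a
resolution error naming the acquisition length needed.

## Dispersion estimation

Per-gene dispersions are estimated in three steps, all operating on the
Cox-Reid adjusted profile likelihood `l(alpha) - 0.5 log det(X' W X)` (the
standard small-sample correction for profiling out the coefficients; without
it gene-wise MLEs are biased low and downstream tests anticonservative):

1. **raw**: method-of-moments on normalized counts seeds a GLM fit; the
   adjusted likelihood is then maximized in `ln alpha` at the fitted means by
   a vectorized golden-section search on [1e-8, 100] (all genes bracketed
   simultaneously; final bracket < 1e-4 nats).
2. **trend**: `alpha(mu) = a1/mu + a0` fitted across genes by iteratively
   reweighted regression (gamma-style weights `1/fitted^2`) with outlier
   trimming (ratio to trend outside [1e-4, 15]). If the fit is degenerate —
   non-positive coefficients, or a trend prediction more than 10x away from
   the median dispersion, which happens when base means have no spread — the
   global mean dispersion is used instead, with a warning.
3. **final**: maximum a posteriori under a log-normal prior
   `ln alpha ~ N(ln trend, 0.5^2)`. Raw estimates above 10x the trend are
   deemed genuine outliers and kept unshrunken. Everything is floored at
   1e-8.

The prior sd of 0.5 is a conventional default and configurable.

## Fitting and inference

Coefficients are fitted by iteratively reweighted least squares with Fisher
weights `mu/(1 + alpha mu)` and offset `ln s_j`, batched across genes
(stacked per-gene normal equations solved with a 1e-8 ridge for numerical
safety); convergence is `max |delta beta| < 1e-6` within 100 iterations, and
non-converged genes are flagged and reported with NA statistics. The reported
covariance is the inverse *observed* information,
`X' diag(mu (1 + alpha y) / (1 + alpha mu)^2) X`.

The metric coefficient is tested with a Wald statistic `beta1 / SE`. The bare
`wald_test` operation uses a standard-normal reference; the model driver
passes `df = n - p` so the reference is Student-t. The distinction matters:
with an estimated SE at n = 75 and ~6 parameters, normal tails are too light
by exactly the normal-vs-t ratio, which measurably inflates the realized
false discovery proportion (~0.057 vs the nominal 0.05 in our calibration
runs); with the t reference the observed FDR is controlled (~0.045).
Benjamini-Hochberg correction is applied per model across genes (8 separate
corrections, matching significance-within-model-then-merge semantics); the
implementation is the standard step-up with enforced monotonicity and NA
pass-through.

Significant genes (padj < 0.05) from each linear/exponential pair are merged
via union into 4 pools (metric x timepoint). A pooled gene's sign and
best-p come from the more significant contributing model; sign conflicts
between forms are resolved the same way and logged. UpSet accounting
partitions each direction-filtered pool union into exclusive subset bins
(every gene in exactly one bin, so bins sum to the union).

## Over-representation analysis

For each pool and direction the query is tested against a GMT collection
with the upper-tail hypergeometric `P(X >= k)`, `X ~ Hypergeom(N, K, n)`,
after intersecting set members with the universe and dropping sets outside
[10, 500] members. The universe is the set of genes actually tested in the
corresponding models (configurable); the enrichment threshold is
padj < 0.01. Redundant sets are pruned greedily from most to least
significant by member-overlap Jaccard similarity at threshold 0.7 — a
deliberately resource-free substitute for ontology-graph semantic
similarity, which requires the GO DAG and affects display only. The
surviving top-5 sets export as a bipartite gene-concept network whose gene
nodes are annotated with the subset of the 4 pools containing them.

## The synthetic generator

The generator emulates the pooled study design: 75 samples, 27 FUS-treated
with CE, 18 of those with MBA, the remainder untreated with CE = MBA = 1
exactly. (The emulated study's own marginal totals are internally
inconsistent by two samples; the generator keeps the total at 75.) For
treated samples, `(ln(CE-1), ln(MBA-1))` is bivariate normal — a shifted
log-normal pair guaranteeing metrics >= 1 so the linear form's log is always
defined — with the latent correlation calibrated by Monte-Carlo inversion so
the OLS R^2 of MBA on CE hits a target (default 0.59). The marginal
parameters (ln-mean 0.5, ln-sd 0.5) are a modelling choice; the emulated
study reports no metric marginals.

Counts are gamma-Poisson draws with `ln q = beta0 + beta1 x + covariate
offsets`; per-gene covariate coefficients are drawn `N(0, scale^2)` with
scales sex 0.2, anesthesia 0.4, batch 0.1 (anesthesia largest, mirroring its
role as the dominant driver of transcriptome-wide variability), base log-mean
`N(ln 50, 1)`, true dispersion `alpha = 3/mu + 0.05` with 0.3 log-normal
jitter, and size factors `exp(N(0, 0.2^2))`. Log-means are clamped at
`ln 1e8` with a warning. The default 2,000 genes (not a genome-scale 34k)
keeps a full pipeline run to seconds; genome scale remains a config choice.
Synthetic waveforms are a constant-phase 2.22 MHz tone plus white Gaussian
noise — enough to exercise the band-ratio metric, though real cavitation
spectra have colored noise floors, sub/ultra-harmonics and broadband bursts
that this generator does not emulate, so passing tests demonstrate metric
correctness, not robustness to real acoustic artifacts. Likewise the count
model is exactly the fitted family (NB, log link), so recovery benchmarks
demonstrate estimator calibration under correct specification, not
robustness to misspecification.

All stochastic stages derive from the single config seed; identically
configured runs are byte-identical (output headers carry the package version
and a hash of the analysis parameters, never timestamps).

## Numerical and design choices

- Size factors: classic median-of-ratios over genes positive in all samples;
  a `poscounts`-style fallback over positive entries is available when no
  such gene exists. Factors are not rescaled afterwards.
- The expression-diagnostic transform is `log2(count/sf + 1)` (a shifted log,
  not a dispersion-based variance-stabilizing closed form) — it feeds a PCA
  diagnostic only. PCA signs are fixed by making the largest-magnitude
  loading positive.
- All-zero genes are dropped (with a logged count) before normalization and
  modelling; a configurable minimum-mean filter (default 0) stands in for
  independent-filtering optimization, which is out of scope along with
  outlier count replacement.
- Degenerate designs: an all-baseline metric column (identically zero under
  the linear form) is tolerated and the model degenerates to covariates-only;
  any other rank deficiency raises an error listing the aliased columns;
  models with fewer than 3 usable samples are skipped and logged while the
  remaining permutations proceed.
- Golden-section maximization assumes a unimodal profile likelihood in
  `ln alpha`, which holds on the bracket in practice; ties in band-peak
  selection and in pruning are broken deterministically (descending
  amplitude; padj then name).

## Known limitations

- The linear/exponential encodings are nearly collinear when the metric
  spans a narrow range (ln is locally affine), so the two forms of a pair
  often flag near-identical gene sets; the pooling stage treats that overlap
  as a diagnostic, not an error.
- Wald inference with a t reference is still asymptotic in the dispersion
  estimate; at much smaller n than the emulated design, quasi-likelihood or
  exact tests would be preferable.
- The ORA universe choice (tested genes) changes p-values relative to a
  genome-wide universe; both are defensible, only one is default.
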
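# Methods

This note documents the statistical model, the numerical choices, and the
limits of what the package's tests demonstrate.

## Two-sample MR model

Each instrument SNP *k* carries a pair of summary associations: the
exposure effect X_k (log OR per effect allele for binary traits, per-SD
effect for IgE) with SE sigma_Xk, and the glioma effect Y_k (log OR) with
SE sigma_Yk, aligned to a common effect allele. Under the instrumental
variable assumptions (the SNP affects glioma only through the exposure and
is independent of confounders), Y_k = beta * X_k, and beta is the causal
log OR of glioma per unit log-odds of the exposure.

Estimators:

* **IVW** implements the ratio-pooling formulas
  `beta = sum(X Y / sY^2) / sum(X^2 / sY^2)`,
  `se = sqrt(1 / sum(X^2 / sY^2))`. The SE ignores exposure-side
  uncertainty; this is the convention that makes IVW identical to (a) a
  weighted least-squares fit of Y on X through the origin with weights
  sY^-2 and (b) a fixed-effect meta-analysis of the Wald ratios with
  first-order SEs. Both equivalences are enforced in tests at 1e-10
  relative tolerance.
* **MLE** models (X_k, Y_k) as bivariate normal with mean (xi_k,
  beta*xi_k), SDs (sigma_Xk, sigma_Yk) and error correlation rho (default
  0: non-overlapping GWAS samples). The nuisance xi_k minimise a quadratic
  and are profiled in closed form; beta is then a one-dimensional Brent
  minimisation started/bracketed at the IVW solution (objective tolerance
  1e-10). The SE is taken from the observed information: the numerical
  Hessian (central differences, relative step 1e-5) of the joint negative
  log-likelihood at the optimum, inverted, (beta, beta) element.
  Non-convergence or a non-positive-definite information matrix raises
  `ConvergenceError` with diagnostics; it is never silently absorbed.
  A `rho_sensitivity` helper refits over a user grid of rho.
* **Weighted median**: order Wald ratios theta_k = Y_k/X_k, accumulate
  normalised inverse-variance weights (first-order ratio variances), and
  interpolate the 50th weight percentile. With equal weights this is
  exactly the sample median (tested). SE/p come from a parametric
  bootstrap (default 10,000 replicates, seed 1): (X_k, Y_k) redrawn from
  normals at their observed values and SEs.
* **Mode-based estimate**: argmax of the weighted Gaussian-kernel density
  of the ratios. Bandwidth is phi times the modified Silverman rule
  0.9 * min(sd, MAD_normalised) * K^(-1/5); phi defaults to 1 and is a
  config knob. The argmax is located on a 4001-point grid spanning the
  ratios +-3 bandwidths and refined by bounded scalar minimisation
  (tolerance 1e-10), so the point estimate is deterministic. Bootstrap
  replicates use a 512-point grid without refinement (the SE does not
  benefit from sub-grid precision).
* **MR-Egger**: instruments are oriented to positive exposure effect, then
  Y is regressed on X with a free intercept and weights sY^-2 via
  statsmodels WLS. The slope is the pleiotropy-adjusted estimate, the
  intercept the average directional pleiotropy per instrument. SEs are the
  WLS SEs (they carry the usual residual-dispersion factor), and p-values
  use the t distribution with K-2 df, the regression convention; a flag
  switches to normal p-values.

For binary exposures all estimates are rescaled by ln 2 so that exp(beta)
is the glioma OR per doubling of exposure odds; IgE (per SD) is reported
unconverted. The significance ledger used in reports is 0.05 nominal,
0.0125 Bonferroni across the four traits, 0.00625 for subtype scans.

## Harmonisation and pruning

Outcome records are re-expressed on the exposure's effect allele: direct
match, label swap (sign flip), or strand complementation. Palindromic
(A/T, C/G) variants are resolved by comparing effect-allele frequencies;
they are rejected when either frequency is missing or both lie within 0.08
of 0.5 (so a frequency in [0.42, 0.58] is considered uninformative). The
0.08 window follows common two-sample MR practice. For sources that
publish both sides already aligned on one strand and allele — as the
packaged tables do — `trust_labels=True` accepts the labels at face value;
this is the pipeline default for fixtures and the reason rs6602364
(G/C, frequency 0.508) survives harmonisation there.

LD pruning is greedy: instruments are ranked by exposure |z| (ties: smaller
SE, then rsID, making the result order-independent) and kept if their r^2
with every previously kept SNP is below the threshold (default 0.001).
On clustered toy problems this matches exhaustive subset search.

CI-to-beta conversion uses the exact 0.975 normal quantile (1.959964).
Reconstructed CI bounds agree with the stored ones to within 0.015 — the
propagated effect of each printed number carrying +-0.005 rounding — and
this is the fundamental precision limit of the packaged tables: pooled
statistics recomputed from two-decimal ORs/CIs can differ from the
published values in the last printed digit or two. The discrepancy is
largest where the instrument count is small or the per-SNP outcome effects
are near zero (the IgE set, the Egger intercepts, and Q-derived I^2, which
is quadratic in the perturbed ratios); the atopic dermatitis set (17
instruments) reproduces the published estimates exactly at printed
precision. The published MLE confidence intervals are consistently
narrower than their IVW counterparts, which no variant of the stated
likelihood (observed vs expected information, profile curvature,
marginalised nuisance) reproduces; this package reports the observed-
information SE of the joint likelihood, which closely tracks the IVW SE,
and treats the published point estimates as the comparison target.

The positions stored in the fixtures are verbatim from the source,
including its internal inconsistency for rs2155219 (printed at two
different positions in two trait blocks); joins are by rsID only and never
by position.

## Pleiotropy diagnostics

Cochran's Q uses first-order ratio SEs (matching the forest-plot
meta-analysis convention); I^2 = max(0, (Q - df)/Q), reported as an
integer percentage. The HEIDI-outlier screen takes the instrument with
the largest exposure |z| as reference (ties: smaller sigma_X, then rsID),
computes d_k = theta_k - theta_ref with second-order delta variances
(exposure-side uncertainty matters for outlier detection, so it is
included here, unlike in Q), and tests d_k^2/var(d_k) against chi-square
with 1 df at threshold P <= 0.01. The default is a single pass, which on
the packaged data flags exactly rs909341 for atopic dermatitis and nothing
else; an iterated mode (remove worst, re-test) exists behind a flag.

## Simulation design

The generator mimics two case-control GWAS drawn from one population:
genotypes g_ij ~ Binomial(2, p_i), p_i ~ Uniform(0.1, 0.9); exposure odds
x_j = x0 * prod w_i^g_ij with per-allele ORs w_i drawn with replacement
from a pool; outcome odds y_j = y0 * 2^(log2 x_j * log2 v), i.e. the
outcome log-odds respond linearly to the exposure log-odds with
per-doubling OR v; statuses are Bernoulli in odds/(1+odds). Baselines
x0 = 5e-4 and y0 = 0.01 keep prevalences in the range of atopy-related
traits and glioma. The default OR pools are the per-trait published
exposure ORs shipped in the fixtures (a frozen, realistic effect-size
distribution; a user pool can be supplied).

The cohort is split into random halves; each half yields one GWAS
(exposure status in one, outcome status in the other) by per-variant
additive logistic regression, fitted by IRLS on the genotype-aggregated
3x2 count table (identical MLE to the individual-level fit, verified
against statsmodels, convergence 1e-8). Perfect separation or empty
margins mark a variant unestimable; it is dropped from that GWAS and
hence from the harmonised set. By default every case and every control in
a half enters its GWAS; explicit case/control sampling counts are
scenario fields.

Problem sizes: the desk profile used by the test suite runs 100,000
individuals and 20 replicates per scenario (seconds per scenario); a full
profile of 1,000,000 individuals and 100 replicates is available as a
preset for workstation runs. At the desk scale the exposure GWAS has a few
thousand cases and the causal scenario (v = 1.33) depresses outcome
prevalence to a few hundred cases per half, so instruments are weak:
estimates at v = 1.33 are attenuated by 15-40% (regression dilution from
noisy exposure effects) and per-replicate signs are positive in only
85-90% of replicates, while the Monte-Carlo mean of every method is
positive with overwhelming confidence (mean/MC-SE > 4). The tests
therefore check that null-scenario means lie within 3 MC-SEs of zero and
that causal-scenario means are positive at one-sided 95% confidence;
per-replicate sign-consistency is a property of the full-scale profile.
The generator draws variants independently (no LD) and includes no
pleiotropic arm — what the simulation validates is estimator behaviour
under valid instruments with binary traits, not robustness to invalid
ones, and passing tests say nothing about LD-induced instrument
correlation in real data.

## Power

Two-sided a priori power uses
`power = Phi(d - z) + Phi(-d - z)` with
`d = sqrt(n * R^2 * ratio * (1-ratio)) * |ln OR|`, n the outcome GWAS
size, ratio its case fraction, and z the alpha/2 normal quantile; both
rejection tails are counted so power -> alpha exactly as R^2 -> 0 or
OR -> 1, and the function is symmetric in OR <-> 1/OR. R^2 (exposure
variance explained by the instruments) is an input, since published
heritability estimates vary by trait and source; `snp_r_squared` gives the
standard per-SNP approximation 2p(1-p)beta^2. The first-stage F statistic
is (n-k-1)/k * R^2/(1-R^2). The implemented binary-outcome approximation
is deliberately simple and swappable; absolute power numbers depend on the
chosen R^2 and should be read comparatively.

## Determinism and seeds

All stochastic components (bootstraps, cohort generation, half-splits,
case-control sampling) consume numpy `SeedSequence`-derived generators
from a single user seed; re-running any pipeline or simulation with the
same config and seed reproduces TSV/JSON outputs byte-for-byte. Point
estimates of all five estimators are deterministic given the instruments;
only bootstrap SEs and simulation draws depend on the seed.

## Known limitations

* No multivariable MR, no individual-level 2SLS, no non-linear
  exposure-outcome models.
* Ratio-based estimators with binary exposures approximate, rather than
  exactly recover, causal odds ratios; the simulation module exists
  precisely to quantify that approximation under the assumed generative
  model.
* The packaged tables carry two-decimal printed precision; analyses
  needing more should ingest full-precision summary statistics through
  `read_instruments`.
* HEIDI screening is the outlier-removal component only; no global
  structural-model estimation is attempted.
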
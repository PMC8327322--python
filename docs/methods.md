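# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices and the known limitations of `cbkit`.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Association tests

**BIN-test.** Residue positions of rare missense variants are compared
between cases and controls.  The protein `[1, L]` is cut into
`k = max(2, round(n^0.4))` equal-length bins, `n` being the combined
case+control count of observed variant positions (round-half-up; the
floor of 2 keeps the table two-dimensional).  Positions enter once per
carrier by default — reference-panel data contribute allele counts, so
carrier multiplicity is the natural unit — with a flag for
distinct-variant mode.  The k×2 table is tested with the Pearson χ²
statistic; bins with zero combined count are dropped and the degrees of
freedom reduced to (populated bins − 1), rather than stabilised with
pseudo-counts, which keeps the statistic well defined without biasing
it.  No Yates or other small-count correction is applied; small-sample
validity is assessed empirically by the null-simulation suite (the
observed false-positive rate at α = 0.05 over 1000 desk-scale null
replicates is computed by `scripts/acceptance.py` and asserted to be
≤ 5% + 3 Monte-Carlo SE in the test suite).

**Burden test.** One-sided Fisher's exact test on the 2×2
carriers/non-carriers table, upper hypergeometric tail: only a carrier
excess in cases counts as evidence, since protective rare-missense
burdens are not an observed phenomenon in the target disease area.

**ClusterBurden.** Fisher's method, X = −2(ln p_b + ln p_c), with the
closed-form χ²₄ tail `exp(−X/2)(1 + X/2)`.  P-values are floored at
1e-300 before logs.  Independence of the components under the null — the
premise of the combination — holds structurally (the burden test
conditions on carrier totals; the BIN-test compares positions given
those totals) and is verified by simulation (Spearman ρ ≈ 0 over 1000
null replicates).  Under a disease model the two p-values are positively
correlated, as both tests gain power with the number of observed
variants; this affects joint power, not null calibration.

**Coverage adjustment.** Per-cohort binned counts are divided by the
mean proportion-≥10× coverage across the bin; burden-test cohort sizes
are multiplied by the gene-wide mean coverage (rounded).  Adjusted
counts are real-valued, which the χ² formula accepts directly.  The
comparator Anderson-Darling and Kolmogorov-Smirnov tests are run on
unadjusted raw positions (no coverage adjustment is defined for them);
scipy's k-sample AD implementation clamps its p-value to
[0.001, 0.25], which is immaterial at the α = 0.05 operating point.

**Panel scan.** Family-wise control over a gene panel is Bonferroni:
α_per_test = α_family / (3 × genes), i.e. 0.05/102 ≈ 0.00049 for a
34-gene panel; each p-value is additionally flagged at the nominal 0.05.

## Simulator

The generator produces the study conditions for calibration and power
work.  Each synthetic gene has:

* **Benign background** — a panel of candidate sites (uniform positions)
  sized so that the expected benign carriage is `benign_carrier_rate`
  per individual (default 0.06).  Each site's true population AF is
  log-uniform: AF = 10^U, U ~ Uniform(−6.5, −3.5), giving a realistic
  singleton excess without explicit drift modelling.  Cohort carrier
  counts are Binomial(N, 2·AF), so under the null the cohorts are
  exchangeable up to size.
* **Pathogenic variants** — positions uniform inside the scenario's
  cluster windows; each carriage event is its own ultra-rare variant.
  Carriage is incompletely penetrant: the fraction of cases carrying a
  pathogenic variant is `pathogenic_carrier_rate_cases` (default 0.045)
  and control carriage is set so the case:control carriage odds ratio
  equals `penetrance_or` (default 50) — pathogenic variants genuinely
  appear in controls.
* **Rarity filter** — the popmax-AF < 1e-4 filter is applied to the
  generated variants exactly as to real data.  The benign site AFs stand
  in for the reference-panel popmax AF; pathogenic variants are absent
  from the reference (missing popmax) and therefore retained.  Filtering
  on the *realised* control frequency instead would be degenerate at
  desk scale (5000 controls ⇒ any observed control variant exceeds
  1e-4), so the population-AF reading is used.  Note the filter removes
  roughly two thirds of benign *carriage* (the common tail of the
  spectrum), so the effective post-filter benign rate is ≈ 0.02.

**Scenarios.** `null` (benign only), `uniform` (pathogenic positions
uniform on [1, L]: burden without clustering), `single_cluster` and
`multi_cluster`.  Default windows are exon-sized — 6% of the protein
each (≈30 residues at L = 500) — one window at 0.20 L, or three at
0.10/0.50/0.80 L.  Window geometry matters: the generator models
discrete exonic regions of elevated pathogenic potential, and with
compact windows the binned χ² concentrates the positional signal in
one or two cells, where CDF-based tests (AD, KS) dilute it.  With wide
diffuse windows (≥15% of the protein) a single-cluster alternative is
instead mildly favourable to KS; the exon-sized default reflects the
biology the generator is meant to imitate and puts the positional tests
in a mutually discriminating regime.

**Scale and calibration.** Full scale is 5000 cases / 125 000 controls;
desk scale is 500 / 5000, the size used by the 1000-replicate
calibration studies (a single desk-scale replicate plus all five tests
runs in ~5 ms, so the acceptance suite completes in seconds).  The
default effect sizes were calibrated once, by a coarse grid measurement
of the operating landscape, so that at desk scale the burden signal of a
disease gene is overwhelming (power ≈ 1) while the positional tests sit
in mid-to-high power — the regime in which clustering information adds
value over burden alone and orderings between tests are measurable.  No
fixed effect size can hold a target power band at two scales
simultaneously, so desk scale is the calibrated operating point.
Quantitative power values are generator-dependent and are treated as
such; only orderings and calibration are asserted.

**Reproducibility.** All randomness flows from a single master seed;
replicate *i* of a study uses `SeedSequence((seed, i))`, so any
replicate can be regenerated in isolation.

## Hotspot GAM

**Model.** logit P(case) = β₀ + β₁·carrier + f(position)·carrier, fitted
to one row per carrier (response = cohort) plus two aggregated
non-carrier rows (case and control) whose frequency weights are the
non-carrier counts.  Non-carrier rows have a zeroed spline basis — the
smooth exists only inside the carrier interaction, since position is
undefined for non-carriers.  Training on all rare variants in both
cohorts (including pathogenic carriage in controls) makes the model
agnostic to prior classifications and lets it absorb incomplete
penetrance and benign background.

**Basis and penalty.** Cubic B-splines on equally spaced knots extended
three knots beyond [1, L] (the standard P-spline construction), default
dimension 10, with a second-order difference penalty on the
coefficients.  Uniform knots are used deliberately: the penalty null
space is then exactly {constant, linear-in-position}, so λ → ∞
degenerates to plain logistic regression with a linear position term — a
closed-form limiting oracle the tests exploit.  A sum-to-zero constraint
over carrier observations (null-space reparameterisation of the basis)
makes the smooth identifiable next to β₁.

**Fitting.** Penalized IRLS with step-halving on the penalized deviance;
after the stopping rule (relative objective change < 1e-12 and
coefficient change < 1e-8) two further Newton steps polish the score to
near machine precision.  Linear systems are solved by Cholesky, with a
per-coordinate relative ridge escalated only if the penalized Hessian is
numerically semi-definite (quasi-separated data).  λ is selected by
Laplace-approximate REML — minimise
−ℓ_p + ½·log|H + λS| − ½·log|λS|₊ — via bounded scalar search on
log λ ∈ [−8, 16]; GCV is available as a cheaper alternative.  The
coefficient covariance is the inverse penalized Fisher information and
the effective degrees of freedom are tr((H+λS)⁻¹H).  Quasi-complete
separation on carrier status raises an explicit error, as does fitting
fewer than 20 carrier observations (overridable): sparse positional data
produce unstable smooths.

**Prediction and evidence.** The reported quantity is the
carrier-at-x vs non-carrier contrast, log OR(x) = β₁ + f(x), with
delta-method SEs and CI = exp(log OR ± 1.96·SE).  Evidence strata are
assigned on the OR point estimate: ≥100 strong, ≥20 moderate, ≥10
supporting, ≥5 weak.  The strata are deliberately defined on the OR
scale rather than on predicted case probability: with a 1:10 (or 1:25)
case:control imbalance the probability thresholds 0.9/0.95/0.99 are not
attainable even for strong hotspots, whereas their odds equivalents
(9/19/99, i.e. ORs of roughly 10/20/100 against an even prior — see
`probability_odds_map`) transfer directly.  Haldane-corrected empirical
ORs (add 0.5 to all cells when any cell is zero; Woolf CI) are provided
for comparison with the model-based estimates.

**Coverage weights.** Each carrier row's log-likelihood weight is the
reciprocal mean 10× coverage within ±15 residues of the variant (the
"surrounding region"; 15 is an exon-half-width default), non-carrier
rows use the gene-wide mean.  Multiplying all weights by a constant at a
correspondingly scaled λ leaves point estimates unchanged and rescales
SEs, as expected of frequency weights.

## Hotspot+ and feature selection

Predictor scores enter as unpenalized linear terms interacted with
carrier status (zero for non-carriers); with an empty feature set the
model is numerically the hotspot model.  Scores enter linearly by
default (a smooth-feature switch is the obvious extension; linearity
keeps the Wald screen well-defined).  Missing scores are mean-imputed
within gene.  Selection is two-stage: (1) each of the (default 24)
candidates is tested as a single added term inside the hotspot model,
Wald p < 0.05/24 ≈ 0.002; (2) the survivors are fitted jointly and the
largest-p feature is removed until all remaining clear 0.05/m (m =
stage-1 count).  The full elimination path is reported; an empty final
set is a legitimate outcome for sparsely observed genes.  During the
screen the smoothing parameter is fixed at the feature-free REML
estimate (unpenalized linear terms barely move it; this makes a
24-candidate screen ~30× cheaper); the production fit re-estimates λ.
Marginal screening is done inside the hotspot model rather than as
score-only logistic fits so that a feature must add information beyond
burden and position.

Model comparison uses AUC over 10 random stratified 80/20
train/test splits of the carrier rows (non-carrier aggregate rows always
stay in training); repeated random splits, not disjoint 10-fold
partitions, and held-out AUC is computed on carriers only, since
non-carrier rows carry no variant-level information.  Single-class test
draws are redrawn (stratification makes this rare).

## Post hoc sample-size equivalence

Observed p-values are converted to χ² quantiles (1 df for the burden
test, 4 df for the Fisher combination — each test's reference
distribution), treated as non-centrality parameters that scale linearly
with sample size, and the multiplier c solving
power(c·λ_burden, 1 df) = power(λ_combined, 4 df) at the chosen α is
found by Brent's method on [1, 10⁴] (root residual < 1e-6, checked).
The multiplier is 1 when the burden test is already at least as strong,
and flagged unbounded beyond 10⁴.  The df convention is configurable in
principle; 1/4 is the natural default and is documented rather than
asserted against any external value.

## Numerical and degenerate-input conventions

* p-values live in (0, 1]; logs are taken after flooring at 1e-300.
* A BIN-test with fewer than two populated bins returns p = 1, df = 0,
  flagged degenerate; ClusterBurden then falls back to the burden
  p-value with the same flag.
* Identical position multisets short-circuit the comparator tests
  (KS p = 1).
* Coverage profiles default unlisted residues to 1.0 with a logged
  warning; duplicated coverage rows and out-of-range values are errors.
* Collinear feature sets are rejected by a rank check naming the set.

## What the simulator does and does not emulate

It reproduces the statistical structure the methods assume — discrete
high-risk windows, uniform benign background, ultra-rare log-uniform AF
spectrum, incomplete penetrance, popmax filtering, cohort-size
asymmetry.  It does not model: non-uniform benign positional structure
(paralog constraint, domain-specific mutability), linkage between
variants, diploid genotypes, founder haplotypes, sequencing error, or
relatedness.  Passing calibration and ordering tests on these synthetic
conditions therefore demonstrates correctness of the machinery and the
qualitative behaviour of the tests, not quantitative performance on any
real cohort; real-data power depends on the true clustering geometry
and effect sizes.

## Known limitations

* The χ² approximation is used without small-count correction; with
  very few variants the BIN-test is mildly conservative-to-anticonservative
  depending on the margin pattern (the calibration suite bounds this at
  the desk-scale operating point only).
* Penalized-spline CIs undercover near sharp discontinuities in the true
  regional burden: smoothing bias is intrinsic, and more data tighten
  the CIs faster than they shrink the bias (the step-function test
  asserts good coverage away from the jump, ~73% globally at a sharp
  OR-20 step).  Real hotspots with gradual boundaries are less affected.
* The probability→evidence mapping assumes the carrier-vs-non-carrier
  contrast is the relevant OR; other baselines (e.g. variant-specific
  priors) would shift strata.
* Bonferroni is used throughout for family-wise control; FDR variants
  are out of scope.
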
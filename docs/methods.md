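# Methods

This note documents the models, the defaults and the reasoning behind them,
what the synthetic cohorts do and do not emulate, and the package's known
limitations.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The model

The pipeline learns a *dynamic linear-Gaussian Bayesian network* over a
participant × (variable, visit-year) frame.  Columns carry roles that fix the
direction of admissible edges:

* **baseline**, **genetic**, **genetic_pc** — time-invariant, exogenous
  (never children), admissible parents of any outcome;
* **intervention** — exogenous; a time-indexed intervention (e.g. levodopa
  equivalents) may explain outcomes of the *same* year or later, so treatment
  at the time of assessment can explain the assessed outcome;
* **imaging** — exogenous; time-indexed imaging must strictly precede its
  child;
* **outcome** — the dependent variables; an outcome parent must strictly
  precede its child in time.

Under these rules every admissible graph is acyclic by construction; the
sampler nevertheless audits acyclicity on every move so that user-supplied
permissive constraint sets (same-year outcome→outcome edges) remain correct.

### Local models and scoring

A fragment is an OLS linear-Gaussian model of one child on a parent set with
at most `cap = 4` non-SNP parents and at most one coding column (additive /
dominant / recessive) per SNP — the three codings of one SNP are linearly
dependent as a triple, and the cap mirrors the enumeration depth feasible for
this family of models.  The score is

    score = −(n·log(RSS/n) + (k+2)·log n)  −  k·(2γ·log p + log((1−π)/π))

with `k` parents among `p` admissible candidates.  The first term is the
negated BIC (`score_fragment`'s default, and the package's documented score
primitive).  The learner adds two standard structure-learning regularizers:

* an EBIC-style multiplicity term, `γ = 1`, which charges each parent for
  the size of the candidate pool it was selected from;
* a Bernoulli edge-inclusion prior, default `π = 0.02`.

**Why π = 0.02.**  The ensemble targets `exp(score)` at T = 1, so a null
candidate parent whose likelihood-ratio statistic is χ² reaches relative
posterior odds `exp(χ² − log n − 2γ·log p − logit(π))`.  For that parent to
cross the 0.30 consensus threshold requires χ² ≳ 10.5 at n ≈ 300 and p ≈ 10,
a central-χ²₁ tail event of probability ~10⁻³ per candidate — so even with
~30–40 candidate (parent, child) pairs per cohort, a false consensus edge is
a ≲5% event per learned model.  Planted standardized effects of 0.5 have
χ² ≥ 50 at n = 300 and are unaffected.  A weaker prior (π = 0.1) measurably
inflates the false-consensus rate at this sample size; the replicated
recovery study in the test suite verifies the operating point.

### Ensemble construction

Sampling is per-child fragment-swap Metropolis: propose a uniformly random
fragment for a uniformly random child, accept with probability
`min(1, exp(Δscore/T))`, rejecting cycle-creating moves.  A geometric
temperature ladder (8 levels, T = 8 → 1, 200 burn-in sweeps total) precedes
collection of `n_networks` networks (default 1024; studies in the tests use
64–128 for speed) every `thin = 3` sweeps at T = 1.  The total-score trace is
kept; `convergence_diagnostics` flags a split-half mean difference above
0.5 trace-SD or lag-1 autocorrelation above 0.9.

Because fragment choices are independent across children whenever cycles are
impossible, the exact structural posterior factorizes and can also be
computed by exhaustive enumeration over acyclic assignments
(`exact_edge_posterior`); the test suite and the acceptance script verify
sampled edge frequencies against it to 0.05 absolute.

### Simulation semantics

Clamping is a do-intervention: the clamped column is fixed and its own local
model severed, so influence flows only to descendants.  Exogenous unclamped
variables are resampled *jointly* as whole training rows, preserving their
empirical dependence (coherent SNP codings, correlated baselines).  SNP
predictors are clamped coherently across all three codings from the
additive-dosage quantile (dominant = min(d,1), recessive = max(d−1,0)).
Quantiles use the linear-interpolation convention of `numpy.quantile`.

Both perturbation tests subsample each posterior without replacement to the
training-cohort size, then compare means by an add-one permutation test
(`(b+1)/(n_perm+1)`, default 10 000 permutations; a single subsample per
test).  The progression test simulates the whole outcome trajectory within
one network per draw — preserving within-draw dependence — fits a per-draw
OLS line of value on year (default years 4–7), and keeps only the slopes.

`recall_validation` clamps every baseline/genetic/treatment column at each
participant's observed values and computes the ensemble-averaged endpoint
expectation by exact mean propagation through each network — the analytic
expectation of the forward simulation, hence deterministic.  It reports
per-endpoint R² next to the in-sample R² of a direct OLS on the same
clamped columns; multi-step propagation loses information, so the pipeline
R² sits at or slightly below the direct value.

## Preprocessing defaults

* **SNP QC** (all inequalities strict, first failure recorded): MAF > 0.05,
  missing fraction < 0.05, HWE p > 10⁻⁶.  The HWE test is the 1-df
  chi-square goodness-of-fit against expectations at the sample allele
  frequency; monomorphic SNPs fit HWE exactly (p = 1) and fail on MAF
  instead.  MAF is folded (always the minor side) and computed over
  non-missing calls after participant matching.
* **Genotype imputation**: distance-weighted k-NN over participants
  (nan-Euclidean over co-observed SNPs, k = 5), rounded to {0,1,2}, with a
  modal fallback.  This replaces haplotype-phasing imputation, which adds
  nothing for unlinked simulated SNPs and would pull in reference panels.
* **Clinical pruning**, in this order: variables (per (variable, visit)
  column) with **more than** 5% missing are removed, then participants with
  more than 20% missing over surviving columns.  Order matters and is fixed;
  exactly-5% columns survive.
* **Clinical k-NN imputation**: columns standardized by observed mean/SD;
  k chosen from {1, 3, 5, 10} by 5-fold mask-and-predict cross-validated
  MSE (ties to smaller k); distance-weighted mean over the k nearest rows.
* **Genetic PCA**: background (non-key) SNPs centered/scaled, full-SVD PCA,
  3 components by default, each component's sign fixed so its
  largest-magnitude loading is positive (bit-reproducible scores).
* **Imaging interpolation**: per variable, REML linear mixed model in years
  with fixed intercept/slope and participant-level random intercept and
  slope with *diagonal* covariance; per-participant lines (fixed effects +
  BLUPs) are re-sampled at the visit years.  When the data are saturated and
  (near-)noiseless, or the REML fit fails, the interpolator uses exact
  per-participant OLS lines — the σ²→0 limit of the BLUP.

## The synthetic cohorts

`default_cohort_config` plants the study conditions used throughout the
validation: n = 300 participants; baselines age ~ N(59.6, 8.5²), S/E ADL
~ N(93.1, 5.2²), UPDRS II ~ N(5.8, 3.1²) (marginals matching a de-novo PD
cohort); one key SNP at MAF 0.35; MoCA observed years 4–7 and UPDRS III
years 5–7.  Planted effects: age and S/E ADL on MoCA level and UPDRS II on
UPDRS III level, each at standardized ~0.58; and a progression effect of
−0.4 MoCA points/year per minor allele, anchored at year 4.  Values are
continuous (clipping/rounding of bounded integer scales is available per
variable but off by default, so the planted linear-Gaussian truth is exact
and recovery tests are interpretable).  `full_demo_config` adds MMSE,
UPDRS I, a levodopa intervention series, SBR imaging at months 0/22 and 40
background SNPs; `null_cohort_config` (n = 200, endpoint driven by an
independent covariate) is the calibration instrument.

What the generator does **not** emulate: informative missingness (MCAR
only), dropout over time, LD between background SNPs, integer/bounded scale
artifacts, site effects, and any nonlinearity.  Passing tests therefore
demonstrate correctness of the machinery under the model's own assumptions,
not robustness to real-data violations of them.

## Study designs (tests and acceptance script)

* *Structure-posterior exactness*: 6-column frames, cap 2, 1024 networks vs
  exhaustive enumeration; tolerance 0.05 absolute per edge.
* *Closed-form propagation*: a hand-specified a→b→c chain with known
  coefficients; clamped endpoint mean within 3 Monte-Carlo SE at 10 000
  draws.
* *Type-I calibration*: 200 null cohorts, end-to-end (learning included),
  both tests at 999 permutations; rejection at α = 0.05 must fall in the
  95% binomial band around 0.05.
* *Recovery*: 20 replicates of the default cohort with 128-network
  ensembles; success = all planted level edges at consensus ≥ 0.5, planted
  slope modifier detected at p < 0.05, no false edge above 0.3; ≥ 90% of
  replicates must succeed.
* *QC exactness*: 100 random toy genotype matrices against an independent
  erfc-based single-SNP oracle; clinical pruning against direct
  recomputation.
* *Recall contract*: R² ≥ 0.99 on (near-)zero-noise outcomes; noisy-cohort
  R² never above the direct OLS R² by more than 0.02.

Problem sizes (n = 150–300, 64–128 networks, 999 permutations in replicated
studies) are the package's chosen desk-scale designs; single headline tests
use the full 10 000 permutations.

## Numerical choices

* RSS/n is floored at 10⁻³⁰ inside the score so noiseless planted data keep
  finite scores; fragment fits with singular designs are skipped during
  enumeration and are an explicit error in `score_fragment`.
* Enumeration tie-breaks: higher score, then fewer parents, then
  lexicographic parent ids — fully reproducible orderings.
* All randomness flows from `numpy.random.SeedSequence` spawns of a single
  seed; identical (inputs, seed) give bit-identical cohorts, ensembles and
  p-values.
* Consensus threshold is inclusive (an edge at exactly 0.30 is included).
* The heatmap caps displayed log₁₀ p at −16; TSV output keeps full
  precision.

## Known limitations

* **Slope-test specificity under strong level effects.**  A predictor with a
  pure level effect (equal shift at every year) has no true rate effect, but
  the per-year local models estimate its coefficients with independent
  sampling noise, and the year-weighted combination of those errors gives
  the slope contrast a standard deviation of about (q₉₅−q₀₅)/√2 test-SE
  units regardless of n.  The progression test therefore rejects such
  predictors well above α (~40% at standardized level effect ~0.5), while
  their slope effects stay sign-balanced around zero and an order of
  magnitude below genuine rate effects of equal strength (asserted in the
  tests).  Rate findings for predictors with strong level effects should be
  read jointly with the disease-state results.
* **Sampler multimodality.**  The per-child swap sampler cannot cross
  between modes of an exactly symmetric cyclic pair under permissive
  constraints; under the default temporal constraints cycles are impossible
  and the posterior factorizes, so this does not arise.
* Permutation p-values are reported unadjusted, with the significant (<0.05)
  / exploratory (<0.1) convention; no multiple-testing correction is
  applied.
* No informative missingness, latent confounding, nonlinear local models, or
  continuous-time dynamics; genetic and intervention columns are strictly
  exogenous.
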
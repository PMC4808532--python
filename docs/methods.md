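# Methods

## Model

For site *g* with M-values *y_g* across *n* subjects, the working model is

    y_g = β₀ + Σ_j β_j x_j + Σ_l γ_l SV_l + ε_g,

where the *x_j* are the user's model terms (main effects and pairwise
interactions; categorical covariates reference-coded against their first
sorted level, fixed from the complete covariate table so train/test subsets
share one coding) and the SV_l are surrogate variables estimated from the
data. The intercept is always included. Fitting is vectorised: one QR
factorisation of the shared design serves every site, which keeps a
2,000-site × 600-subject screen with 100 train/test iterations in the
seconds range and makes an array-scale screen (~4 × 10⁵ sites) tractable on
a laptop.

Per-term p-values: a single-column term uses the two-sided t statistic on
the residual degrees of freedom; a multi-column term (a categorical main
effect or an interaction involving one) uses a partial F-test against the
model with that term's columns deleted. The two agree exactly when q = 1.
The joint test is a deliberate design choice: the screen gates on *one*
p-value per term, and for a 4-level factor interaction a joint test is the
only coherent way to produce it. The robust engine is Huber M-estimation
(c = 1.345, MAD scale, IRLS, ≤ 50 iterations, coefficient tolerance 1e-8)
with Wald normal/χ² p-values from the Huber sandwich covariance; a site
that does not converge is flagged and given p = 1 so it can never pass a
gate.

A rank-deficient design is a hard error naming the collinear columns —
silent dropping of columns would silently change what "the term of
interest" means.

## Surrogate variables

The number of SVs is estimated by a permutation test in the
parallel-analysis style: residualise every site on the design, record the
variance explained by each right singular vector, and compare against the
same quantity after independently shuffling each site's residuals across
subjects (20 permutations, per-component significance 0.10, sequential stop
at the first non-significant component). All three knobs are exposed;
defaults follow the published parallel-analysis convention.

Construction is the two-step method: take the leading right singular
vectors of the residual matrix, find the sites whose residuals regress on
each vector with p < 0.05 (exposed as config), and re-extract the SV as the
singular vector of the *original* data over that site subset that is most
correlated with the step-1 vector. If no site associates, the step-1 vector
is kept with a warning. Columns are orthonormalised and signed so the
largest-magnitude loading is positive (SVD sign ambiguity would otherwise
break bit-reproducibility). SVs are estimated once on the complete data and
reused in every train/test iteration — re-estimating per split would let
the adjustment drift between the two gates. A `components="trailing"`
option seeds the construction from the low-variance tail of the residual
spectrum instead; it exists only to study what deliberately uninformative
SVs do to a screen, and we read "less informative" this way as an
interpretation, not a definition.

In the Monte-Carlo harness the number of SVs is re-estimated inside every
replicate, since each replicate is a fresh dataset.

## Screens

* **TT.** Train fraction 2/3 (round(2n/3) subjects), i = 100 iterations,
  both gates strict `p < 0.05`, cutoff m = ⌈50% × i⌉. Candidates are
  *refitted from scratch* on the testing subjects — no coefficient
  transfer — so the confirmation is an out-of-sample test. With several
  terms of interest a site must pass on all of them (config `interest_rule
  = all|any`). One master seed spawns independent per-iteration substreams,
  so results do not depend on execution order and a fixed seed gives
  bit-identical output. A split that leaves a rank-deficient design on
  either half (e.g. an empty factor level in a tiny study) is redrawn once,
  then errors.
* **FDR.** Benjamini–Hochberg step-up on the full-data p-values of the
  interest term: reject the k largest-k-satisfying p(k) ≤ (k/m)α, boundary
  inclusive. Backed by `statsmodels.stats.multitest`; the tests check it
  against a literal step-up oracle.
* **Bonferroni.** p ≤ α/m, boundary inclusive. (One published description
  of this rule reads backwards — "adjusted p-values above the significance
  level are rejected" — we implement the standard rule.) Bonferroni
  selection is a subset of FDR selection on any input.

The output table always populates all three selection flags, plus the
full-data coefficient, SE and p-value columns, with p-values printed to 6
significant digits. Every run writes a JSON manifest (options, seed, n_sv,
versions) sufficient to reproduce it exactly.

## The synthetic study

The generator emulates the simulation design used to benchmark this class
of screens: 2,000 sites, n ∈ {200, 400, 600, 800}, k ∈ {10, 100, 200, 400}
important sites; x1 ~ N(1, 1); x2 four-level multinomial with
π = (0.15, 0.25, 0.25, 0.35); five iid N(0,1) latent variables with
per-site loadings; errors either N(0, 1.5) or χ²(1) (used as drawn — mean 1,
variance 2, strongly skewed — with a `center_errors` flag). 90% of the
important sites carry x1, the x2 main effect, and the x1:x2 interaction;
the remaining 10% drop the x2 main effect. Unimportant sites carry only
latent structure plus error. An optional confounded variant draws
(x1, L1..L5) jointly normal with correlation 0.7^|i−j| (positions 0..5),
x1 shifted to mean 1. x2 enters the generating model through its
reference-coded indicators, consistent with its definition as a categorical
variable.

**Effect sizes and loading scale.** Neither the per-term coefficients nor
the latent-loading scale is part of the study definition, so they are free
parameters of the generator. The defaults — coefficient 0.95 on x1, on each
non-reference x2 indicator and on each x1:x2 interaction column, latent
loadings N(0, 2²) — were fixed once by matching two anchor requirements and
then frozen: (i) with SVs included, the Bonferroni screen must sit in the
non-saturated power regime where the three methods differentiate
(sensitivity ≈ 0.95–0.98 under sparse normal-error signal, dropping under
χ² errors and dense signal); (ii) with SVs excluded, the latent structure
must dominate the signal strongly enough that no method's per-replicate
sensitivity exceeds ~30%. Unit loadings (N(0,1)) fail requirement (ii)
outright — the hidden structure is then too weak to matter — which is why
the loading scale is 2. All six quantities are `SimConfig` fields.

Metrics per replicate: sensitivity = TP/k, specificity = TN/(2000−k),
n_incorrect = FP + FN (the identity n_incorrect = k(1−sens) +
(2000−k)(1−spec) holds exactly). Monte-Carlo means of n_incorrect are
rounded half-away-from-zero to the nearest integer in summary tables.

The cutoff sweep exploits the fact that the significance gates do not
depend on the cutoff: each replicate is screened once and every cutoff is
applied to the same selection counts — numerically identical to rerunning
the study per cutoff.

**What the generator does not emulate:** probe-level artefacts, the
beta-value ↔ M-value transform, spatial correlation along the genome,
realistic (non-Gaussian, sparse, blocky) latent structure such as cell-type
composition, and missingness. Passing tests therefore demonstrate the
statistical behaviour of the screens under the stated generative model, not
performance on array data.

## Numerical choices and edge cases

* Rank tolerance: pivoted-QR diagonal against `max(dim) × 1e-10 × |R₁₁|`.
* Nested-model guard: reduced RSS below full RSS beyond `1e-8 ×
  max(RSS, 1)` raises; small negative differences are clipped to zero.
* Boundary behaviour: both comparator screens are inclusive (≤); both TT
  gates are strict (<). `alpha = 1.0` gates are vacuous and select every
  site every iteration.
* Empty p-vector inputs to the comparator screens return the empty set.
* Degenerate splits (either half below design-columns + 2) are errors.
* Monte-Carlo seeds: `SeedSequence.spawn` everywhere; no global RNG state.

## Known limitations

* The TT screen's false-selection rate on null data is bounded below by
  the tail of the full-data null p-value distribution, not by the naive
  Binomial(i, q) argument: iterations resample the *same* data, so a null
  site that is chance-extreme in the realised sample (full-data p ~ 10⁻⁵)
  is confirmed in most iterations. Empirically this floor is a few × 10⁻⁴
  per site at default gates — indistinguishable from specificity 1.000 in
  2,000-site tables, but visible at 10⁴⁺ sites.
* Sensitivities quoted for the synthetic study depend on the calibrated
  effect sizes above; only the qualitative ordering of the three methods
  (and the SVA-included vs -excluded contrast) is robust to that choice.
* The asymptotic ("leek") num-SV estimator and the "irw"/"supervised" SV
  constructions are accepted as option values but report not-implemented.
* No mixed models, GLMs, beta-value modelling, or missing-data handling
  beyond reject-or-row-mean-impute at load time.
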
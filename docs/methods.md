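# Methods

## Model

`affectmc` models a user's discretized emotional valence
X_t ∈ {negative, neutral, positive} across dialogue turns as a Markov
chain whose transition probabilities depend on a time-varying covariate,
the quality Z_t ∈ {low, medium, high} of the AI response emitted between
turns t and t+1:

    P(X_{t+1} = j | X_t = i, Z_t = z) = softmax_j( α_ij + β_ij[z] )

The chain assumption is that, given the current context and the current
stimulus, earlier states and stimuli carry no additional information
(the current state acts as a summary of the interaction history).  The
model is a multinomial logit per context: the reference next state
(neutral) has its linear predictor pinned at 0, and quality enters as a
categorical covariate with high as the reference level.  Treating
quality as categorical rather than numeric-ordinal is deliberate: it is
the only encoding consistent with a saturated first-order parameter
count of 3 contexts × 2 free outcomes × 3 quality levels = 18, and it
lets low and medium responses have asymmetric effects.

Two parameterizations are implemented.

- **Saturated.** One free logit per (context, quality, non-reference
  next state) cell.  The MLE is closed-form — the fitted
  P(j | i, z) equal the empirical cell proportions, and the
  coefficients are per-cell log-odds against the reference outcome.
  `fit_cdmc(..., method="newton")` runs the Newton optimizer on the
  same structure and is required (and tested) to agree with the closed
  form to 1e-6.
- **Additive.** Context dummies + quality dummies + a constant per
  non-reference outcome, no context×quality interaction — the layout of
  a conventional multinomial regression table.  Fitted by Newton ascent
  on the exact log-likelihood with analytic gradient and Hessian,
  deterministic zero initialization, convergence when the gradient
  ∞-norm falls below `tol` (default 1e-8) or the relative
  log-likelihood change falls below 1e-10.  The additive model is
  nested in the saturated one, so its log-likelihood can never exceed
  the saturated fit's (asserted as a property test).

Both fits are computed on cell-aggregated counts (at most
3^order × 3 cells), so fitting cost is independent of the number of
records.  The Wald covariance is the inverse observed information at
the optimum (Moore–Penrose inverse, so rank deficiency under
separation degrades gracefully rather than failing).

**Quasi-separation.**  A zero cell count drives the corresponding
log-odds to ±∞.  Affected coefficients are capped at |coef| ≤ 30 and
flagged (`separation:` entries in `FitResult.separation`); cells with no
support at all keep zero coefficients and an `unsupported:` flag.  Wald
rows for capped coefficients are flagged instead of reporting a
meaningless SE.  In that regime the empirical transition matrices (with
optional Laplace smoothing) are the recommended report.

## Order selection

`select_order` extracts transitions afresh at each candidate order
(1 or 2), fits the saturated model, and compares AIC = 2k − 2logL and
BIC = k·ln(n) − 2logL.  Note that n is the number of records actually
fitted at that order: a sequence of S states yields S−1 pairs but only
S−2 triples, so the order-2 fit legitimately uses fewer records.  This
order-specific-n convention reproduces both published information
criteria exactly from their printed (logL, k, N) summaries; a shared-n
alternative was considered and rejected for that reason.  The preferred
order minimises BIC, ties broken toward the lower order (parsimony).

One behaviour worth knowing: on a corpus that pools two groups with
different first-order kernels, the *mixture* is not itself first-order
(the penultimate state carries information about group membership), and
with enough pooled data BIC correctly flips to order 2.  At the study
scale used here (~900 transitions) the penalty dominates and order 1 is
selected with a decisive gap.

## Grouping

Participants are grouped by trait emotional stability, measured by a
five-dimension scale (pessimism/optimism, anxiety/calmness,
aggression/tolerance, dependence/autonomy, indifference/empathy; the
total score is their plain sum).  The pipeline standardizes the
dimension columns (z-scores with sample SD, ddof=1), projects onto the
top right-singular vectors, and runs K-means (K=2, k-means++ seeding,
10 restarts, seeded) on the top-3 component scores.  Design choices
where the procedure was genuinely open:

- **Standardize by default.**  The five dimensions share a scale family
  but not exact variances; standardization stops any single dimension
  from dominating the projection.  A flag disables it.
- **Cluster in 3-component space.**  The dominant between-cluster
  direction lives in PC1 (typically >60% of variance on two-cluster
  data); three components retain essentially all structured variance
  while denoising.  Configurable.
- **Sign convention.**  Each component is oriented so the sum of its
  dimension loadings (its loading on the total score) is non-negative,
  making score signs reproducible across linear-algebra backends.
- **Label mapping.**  The cluster with the lower mean total score is the
  low-stability group — invariant to raw K-means label permutation.
  Exactly equal means (a measure-zero event) fall back to cluster size
  with a logged warning.
- **K is fixed at 2.**  An elbow-curve report (`elbow_curve`, inertia
  for k = 1..6) is available for transparency but never auto-selects K.

Totals are additionally flagged against a published normative minimum of
181 for "normal" emotional stability; the threshold itself counts as
normal (strict less-than means below-normal).

## Inference statistics

- Chi-square screen: Pearson test of independence on any r×c count
  table (default construction: quality × next state, df = 4), expected
  counts from the marginals, no continuity correction.
- Cohen's d from summary statistics uses the equal-weight pooled SD
  √((s₁² + s₂²)/2), the pooling that reproduces the published cluster
  effect sizes (2.42 for the total score, 2.27 for pessimism/optimism)
  from the group means and SDs alone; unequal-n pooling is available
  only implicitly through the raw-data path.
- Group-dimension tests default to Welch's t (cluster sizes are
  data-driven and generally unequal); pooled-variance t is available via
  a flag.  Groups of size one leave the statistic undefined and flag the
  row.  The degenerate all-identical case reports t=0, p=1.
- Mann–Whitney U is reported as the conventional smaller of U_x and
  U_y (always integer or half-integer), with the two-sided p from the
  normal approximation with tie and continuity correction.
- `relative_improvement` is the plain percent-change identity
  (final − baseline)/baseline × 100.

## Synthetic-data generator

The generator emulates the study design so the entire pipeline is
testable without raw interaction logs, which are not publicly
available for this kind of study.  Defaults are the study's
stated conditions wherever they are stated, and a documented fixed
choice elsewhere:

- 23 participants per stability group (46 total), one sequence each,
  lengths uniform on 15–23 transitions (mean 19 ≈ 880/46; the real
  per-participant length distribution is unreported).
- Quality is drawn i.i.d. uniform over {low, medium, high},
  independent of the user's state — the exogenous-stimulus stance of
  the analysis.  This deliberately omits the real-world feedback loop
  (frustrated users write worse prompts), which the study itself lists
  as a limitation; passing recovery tests therefore validate estimation
  under exogeneity, not robustness to that loop.
- Transition kernels per (group, quality) embed the published headline
  percentages as dominant entries (e.g. neutral→negative 0.8846 for
  low-stability users under low quality; neutral self-transition 0.7805
  for high-stability users; neutral→positive 0.88/0.9048 under high
  quality).  The remaining mass is the package's own documented choice
  with a 0.01 probability floor so no transition is impossible — the
  non-dominant entries are *not* study ground truth.
- Initial state distribution (0.15, 0.70, 0.15): dialogues start near
  the neutral task-focused baseline; unreported in the source, fixed
  here once.
- Scale scores are drawn independently per dimension from the published
  per-cluster normal summaries (no correlation structure is printed; an
  override exists for robustness experiments).
- All randomness flows from an explicit seed through
  `numpy.random.default_rng`; sequence and scale streams are decoupled
  (`[seed, 101]` / `[seed, 202]`) so adding participants to one does not
  perturb the other.

What the generator does **not** emulate: within-participant trait
heterogeneity beyond the two-group split, non-stationarity over a long
session (fatigue, adaptation), state-dependent quality, measurement
error in the valence labels, and multiple sequences per participant.
Results on synthetic data therefore demonstrate correctness of the
estimators and selection machinery, not external validity.

`recovery_experiment` closes the loop: simulate → extract → fit
saturated per group → report the maximum absolute error between fitted
and generating cell probabilities (unsupported cells flagged and
excluded), plus an order-selection table.  A practical note on its
error scale: cell supports are proportional to the chain's occupancy of
each (state, quality) cell, not uniform.  With 400 participants/group
of length-20 sequences the rarely-visited negative-context cells of the
high-stability group hold only ~300 records, so the maximum over all 54
recovered probabilities concentrates around 0.03–0.07 (2–3 standard
errors of the worst cell) even though typical cells are recovered to
~0.01.  The error decreases monotonically in the number of
participants (tested over 50/200/800, averaged over 5 seeds).

## Numerical choices

- Natural logarithms everywhere; AIC/BIC identities are asserted at
  `FitResult` construction to 1e-8.
- Softmax is computed shift-invariantly (max subtraction) to avoid
  overflow at the ±30 coefficient cap.
- Probability rows from both model and empirical estimators sum to 1
  within 1e-12; zero-support empirical rows are NaN and flagged
  undefined, never silently uniform.
- A record with model probability exactly zero makes the log-likelihood
  −∞ with a warning, not an exception.
- Problem sizes in the test suite are chosen to keep the full run in
  seconds: study-scale corpora (46 participants) for behavioural
  checks, 300–800 participants/group where convergence rates are
  measured, and cell-count fixtures (aggregation makes fitting cost
  independent of record count) elsewhere.

## Known limitations

- Markov orders above 2 are not implemented (the extraction and context
  indexing generalise, but the study question does not need them).
- One categorical covariate only; no continuous covariates, no
  participant-level random effects, no hidden-state (HMM) or
  continuous-time variants, no Bayesian estimation.
- The grouping stage assumes exactly two trait clusters; it will
  happily split unimodal data into two halves (K is never inferred).
- The chi-square screen is a generic r×c independence test; the default
  table construction is quality × next state (3×3, df = 4), and no
  finer-grained transition-cell construction is built in.
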
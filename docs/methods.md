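# Methods

## The trait model

The package induces latent trait dimensions from word usage via the
common-factor model M = FL′ + E on a standardized user-term matrix. The
modelling assumptions, in order of importance:

- **User-level aggregation.** All messages of a user are pooled; the unit
  of analysis is the user's relative word-frequency vector. Message-level
  structure (topicality, threading, time of day) is ignored — every
  statistic the pipeline computes is a function of per-user term counts.
- **Linearity on the standardized frequency scale.** Each term column is
  divided by the user's total in-vocabulary count and z-scored across
  users; factors are linear in these columns. Strongly skewed columns can
  be variance-stabilized with an optional square-root transform
  (`transform="relfreq_sqrt"`).
- **Heteroscedastic Gaussian residuals.** Maximum-likelihood estimation
  (scikit-learn's `FactorAnalysis`, deterministic LAPACK SVD updates)
  fits a separate residual variance per term. The truncated-SVD estimator
  is kept as the isotropic special case Ψ = σ²I, and the two are verified
  to span the same subspace under isotropic noise (largest principal
  angle < 2° in the acceptance battery).
- **Correlation-scale fitting.** The model is fit on z-scored columns
  (i.e., the correlation matrix), not raw covariances. Whether to fit on
  correlation or covariance is a genuine free choice for this kind of
  data; correlation is the default because term variances span orders of
  magnitude under a Zipf vocabulary and would otherwise dominate the fit.
  The choice is visible in the API (standardization is a stored,
  reusable transform), not buried.

### Rotation

Orthogonal rotations use the orthomax family (varimax γ=1, equamax
γ=k/2) computed by Kaiser-style pairwise planar rotations with the
closed-form criterion-maximizing angle per column pair. The pairwise
update is exact, so the sweep cannot stall on symmetric loading patterns
(a known failure mode of the simultaneous SVD-based iteration, observed
during development and covered by a regression test). The oblique
`promax` rotation applies a configurable orthogonal pre-rotation
(equamax by default; the phrase "promax with equamax" is read as promax
*after* an equamax start, with varimax reachable by flag), then regresses
the loadings onto their element-wise power-4 simple-structure target and
renormalizes so the implied factor correlation matrix Φ has unit
diagonal. All rotations preserve the fitted covariance LΦL′ + Ψ to
machine precision, asserted for every method.

### Scoring and identifiability

Held-out users are scored with Thurstone regression weights
W = Σ⁻¹LΦ (Σ the model-implied covariance; pseudo-inverse for the
singular SVD case, which reduces to least-squares projection). Scoring
the training matrix reproduces the fitted scores. Factor order and sign
are not identified — a permutation and sign flip of columns leaves the
fit unchanged — so every recovery and stability statistic is computed
after Hungarian alignment on the cost 1 − |r| and reported as absolute
correlations.

### Number of factors

`suggest_n_factors` implements the scree acceleration rule: on the
descending eigenvalues of the term correlation matrix, the discrete
acceleration aᵢ = (λᵢ₊₁ − λᵢ) − (λᵢ − λᵢ₋₁) is maximized and the count
just before the sharpest elbow returned, ties toward the smaller index.
A flat spectrum returns 1 with a low-confidence warning. The default
model order is k = 5 for parity with five-factor questionnaire models
(3, 10 and 30 are the documented comparison presets); the acceleration
rule on clean synthetic three-factor data returns 3.

## Corpus processing

Tokenization lowercases, splits on non-word characters, keeps
word-internal apostrophes ("didn't" is one token) and preserves emoticon
sequences. The packaged English stopword list (74 high-frequency
function words) is overridable. User filters mirror a realistic study
population: at least 1000 words posted in total ("less than 1000 words"
drops a 999-word user and keeps a 1000-word one), age at most 65, and a
country restriction — age/country apply only when metadata is present.
Time windows are half-open 6-month calendar intervals anchored at the
earliest timestamp (a message exactly on a boundary belongs to the later
window); within each window, users below 1000 words are dropped for that
window only.

## Differential language analysis

Each term's relative frequency is Pearson-correlated with each factor's
scores; p-values come from the t distribution with n − 2 df.
Correlations are computed on relative frequencies rather than z-scores —
identical by affine invariance of Pearson r, so this is documented, not
configurable. FDR control is Benjamini–Hochberg (statsmodels), applied
**per factor** across the V terms by default with a global-family option;
constant term columns are emitted with r = 0, flagged degenerate, and
excluded from the FDR family. Frequency tiers (low / moderate /
frequent) are corpus-frequency terciles — the conventional three-colour
coding of word-cloud figures, exported here as ranked tables.

## Evaluation battery

- **Likes targets.** The binary user-item matrix is restricted to the
  most popular items (10,000 at full scale) and factorized with NMF
  (nndsvda initialization, fixed seed) into 20 clusters at full scale.
  How per-user binary targets are derived from NMF is not canonical; the
  package thresholds each user's cluster weight at that cluster's median,
  which guarantees balanced targets — a property AUC handles gracefully.
- **Prediction.** Ridge regression / L2 logistic regression with the
  penalty grid 10⁻³..10³ (7 log-spaced points) chosen by 3-fold inner CV
  on each training part; performance is the mean over 10 random 75/25
  train/test splits (the 75/25 fraction matches the corpus split used for
  stability; the split fraction and fold count are config). Income-like
  skewed outcomes are modelled on the log scale, and the synthetic
  generator emits `log_income` directly so generator and evaluator agree
  on the transform.
- **Covariates.** Age (z-scored) and gender (0/1) can be concatenated to
  any feature set; `residualize` replaces each factor by its OLS residual
  on [1, age_z, gender], leaving residuals exactly uncorrelated with the
  covariates.

## Stability

Test-retest splits each user's messages 75/25 at random (per user, so
everyone appears in both portions), learns the model on the training
portion only, scores each 6-month window of the held-out portion with
the fixed model, and correlates each window's scores with the earliest
window over per-lag common users. Dropout reliability refits the model
on the training matrix with a random 20% of users removed (the fixed
matrix is row-subset and re-standardized rather than re-tokenized —
statistically equivalent and much cheaper), scores a fixed disjoint test
set, and averages the aligned |r| over all C(n_runs, 2) run pairs (4,950
at the full 100 runs).

## The synthetic generator

The generator emulates the population structure such a study sees:

- **Traits.** k-dimensional MVN with equicorrelation 0.2 (mildly oblique,
  motivating promax), unit variances; across 6-month windows a stationary
  AR(1) with coefficient ρ (default 0.85), so corr(window t, window 0) =
  ρᵗ exactly.
- **Language.** V = 500 terms with Zipf(1.0) baseline frequencies; each
  factor gets 60 disjoint marker words with loadings ±0.5 (signs split
  evenly); per user and window, word counts are log-normal (median ~1340)
  truncated below at 1000, drawn i.i.d. from
  softmax(baseline + L·trait) and partitioned into messages with
  timestamps inside the window. Common stopwords are interleaved at rate
  0.15 to exercise stopword removal without touching in-vocabulary
  relative frequencies.
- **Why ±0.5 over 60 markers.** The exponential link makes a term's
  relative frequency nonlinear in the trait: the population correlation
  between q·exp(a·t) and t is a/√(e^{a²} − 1), ≈ 0.97 at a = 0.5 but
  ≈ 0.76 at a = 1, and the shared nonlinear distortion across markers of
  one factor creates spurious variance directions at large a. Diffuse
  small effects over many words both recover better and are the more
  realistic regime — in real open-vocabulary studies, individual word
  correlates of a trait are weak and numerous. The default was fixed on
  this reasoning and recorded in `SyntheticConfig`, not in downstream
  code.
- **Demographics.** 62.8% female; ages from a shifted log-normal matched
  to median 22 / mean 25.49, clipped to [13, 65].
- **Outcomes.** Linear in window-0 traits, z-scored age and gender, plus
  Gaussian noise; each outcome's theoretical R² under the generating
  covariance is stored for oracle comparisons. Binary outcomes threshold
  the latent value at its median.
- **Likes.** Items in equal blocks; each user's cluster propensities are
  logistic in the traits and the argmax cluster receives likes at
  `within_p` (0.3 by default) versus `background_p` (0.02) elsewhere.

What the generator does **not** emulate: non-English text, spam and
reposted chain-letter dynamics, message-level topical structure, or any
network structure among users. Passing recovery tests therefore shows
the pipeline is correct and well-calibrated under the generative
assumptions — not that real social-media language satisfies them; on
real data, duplicated viral text in particular is known to produce
state-like rather than trait-like factors.

## Problem sizes and numerical choices

The validation battery runs at desk scale, chosen so each stage's
sampling error is small relative to its assertion tolerance: trait
recovery on 2,000 training + 1,000 held-out users at V = 500; the
isotropic check at 500 x 50; retest on 400 users x 3 windows at V = 300
(with ~6,000 words per user-window so the 25% held-out portion still
clears the 1000-word window threshold); dropout with 20 refits on 1,200
training users. ML fitting converges when the per-sample log-likelihood
change drops below 1e-6 (config-exposed; non-convergence raises, naming
the iteration cap). Orthomax sweeps stop when no pairwise angle exceeds
1e-10. Ties in vocabulary ranking and ranked word/target lists break
lexicographically; all generators and evaluators are pure functions of
(data, seed).

## Known limitations

- Regression factor scores are shrunken estimates; retest correlations
  measure score reliability times trait autocorrelation, and the
  reliability factor must be estimated (here, via alignment against
  planted traits) to deconvolve the two.
- The scree acceleration rule is reliable only for clean spectra; with
  correlated factors or weak signal the dominant eigenvalue gap can pull
  the elbow to position 1 (it is a heuristic, reported with a confidence
  flag, not a substitute for judgment).
- `evaluate_classification` refuses targets that are single-class
  overall and redraws splits that leave a training side single-class;
  with very rare targets this can bias split selection.
- The LDA-style mixture representation of users is deliberately out of
  scope: sum-to-one factor scores are negatively coupled by
  construction, which conflicts with the unconstrained-trait model this
  package implements.
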
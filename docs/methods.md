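# Methods

## Problem setting

Routinely collected blood tests (hemoglobin, electrolytes, cell counts …)
are measured repeatedly and irregularly during a hospital stay. Their
*trajectories* — not single values — carry prognostic information after
spine trauma and spinal cord injury (SCI). `dyntraj` implements the full
chain needed to use them as *dynamic biomarkers*:

1. curate long-format lab events;
2. model each marker's heterogeneity with latent-class trajectory models;
3. recompute each subject's posterior class membership using only the data
   available up to a landmark day (1, 3, 7, 14, 21);
4. feed those memberships (plus summary statistics and baseline covariates)
   to a repeated elastic-net classifier for in-hospital mortality, SCI
   presence, and SCI severity;
5. test class–covariate associations with FDR control.

Because the real cohorts (credentialed ICU EHR databases and an external
SCI registry) cannot ship with code, a first-class synthetic generator
reproduces the *structure* of those data with known ground truth, so every
stage is testable end to end.

## Trajectory model

For subject *i* with observation times *t_ij* and marker values *y_ij*,
class *g* ∈ {1..G}:

    H(y_ij; η) = B(t_ij)ᵀ β_g + Z(t_ij)ᵀ b_i + ε_ij
    b_i ~ N(0, D),  ε_ij ~ N(0, σ²),  P(class = g) = π_g

* **Time basis** `B(t)`: polynomials of degree 1–3 for the exploratory
  stage; natural cubic splines (intercept + df columns, interior knots at
  quantiles of the pooled observation times) for refinement. The natural
  spline uses the standard truncated-power construction with linear tails.
* **Link** `H`: a monotone map from the observed scale to the latent
  Gaussian scale. Families: *linear* (standardization), *quadratic
  I-spline* (intercept + 5 nonnegative coefficients on integrals of
  degree-1 M-splines over 3 interior knots at the 25/50/75% value
  quantiles), and *beta CDF* (after rescaling the value range into (0,1)
  with a buffer δ = 10⁻³ × range). The log-Jacobian Σ log H′(y_ij) enters
  the likelihood so models with different links are comparable.
* **Random effects** `Z(t)`: none (LCGA), intercept, or intercept + slope
  (GMM). `D` is shared across classes — class-specific covariances would
  roughly double the variance-parameter count at desk-scale n.

The observed-data log-likelihood is the mixture of multivariate-normal
densities with covariance `Z_i D Z_iᵀ + σ² I`, evaluated with the Woodbury
identity (`S = (σ²I + D Z′Z)⁻¹ D`), which stays valid for singular `D` and
is O(n_i q²) per subject. A brute-force dense-covariance implementation
serves as the oracle in the test suite (agreement to 1e-8), and a 1-D
adaptive quadrature oracle checks the random-intercept integral (1e-6).

**Identifiability of the linear link.** `(loc, scale)` of the linear link
are not identified jointly with `(β, σ²)`: rescaling the latent axis is
absorbed exactly. They are therefore *fixed* at the pooled sample
mean/sd — the canonical point on that ridge — and still counted as 2
parameters in the model-size convention. A consequence worth knowing:
latent-scale quantities (`β`, `σ²`, `D`) are per-marker standardized; map
them through the link before comparing with observed-scale truth.

**Estimation.** EM over class responsibilities:

* E-step: posterior responsibilities from current parameters;
* M-step: `π` and `β_g` in closed form (weighted GLS through the Woodbury
  factors); `(σ², D, η)` by an L-BFGS sub-step (log-variance and
  log-diagonal-Cholesky parametrizations, ~10 inner iterations per sweep),
  except for linear-link LCGA where σ² is closed form too;
* multi-start: one k-means start on per-subject OLS (intercept, slope)
  summaries plus random-assignment starts (`n_starts` default 5; the
  pipeline and acceptance runs use 2–3, which recovery experiments show is
  enough at these class separations);
* convergence: relative log-likelihood change < `tol` (default 1e-6,
  max 500 iterations). A class prior collapsing below `1/(10 n)` flags the
  fit as non-converged, never silently.
* label switching: classes are re-ordered by descending MAP-assigned count
  (ties by fitted level at t = 0), so PPA feature columns are stable
  across refits.

**Parameter counting** (used by BIC/ICL): `(G−1) + G(d+1) + q(q+1)/2 + 1 +`
link parameters (linear 2, I-spline 6, beta 4). This is one self-consistent
convention; published per-model parameter totals for specific markers are
not reproducible from text alone and are not targeted.

## Model selection

The exploratory grid is LCGA over G ∈ 1..5 × {linear, I-spline, beta} ×
polynomial degree 1..3 (900 specifications at the study's 20 markers).
Scoring: `BIC = −2logL + k log n`; `ICL = BIC + 2·entropy` of the
responsibilities (the standard entropy-penalized form — the ICL variant is
a documented choice); per-class APPA (mean posterior among MAP-assignees;
a class with zero assignees has APPA recorded as missing, which also
happens under exact posterior ties).

Constraints: minimum per-class APPA ≥ 0.7 and smallest MAP class ≥ 20
subjects (scaled via config for small cohorts). Ranking: ICL first, BIC
tiebreak; the shortlist keeps the best model plus near-ties within Δ = 6
ICL, fewest parameters first — a window rather than an argmin because the
protocol keeps several candidate class counts before a parsimony call; 6
is "strong evidence" on the BIC scale. If everything violates the
constraints, the best-BIC model is kept with a loud warning.

Survivors are refit as GMMs (default intercept + slope random effects)
with natural-spline bases of matching df; the final model per marker is
the best-ICL converged refit, with the LCGA fit as a flagged fallback.

## Dynamic features and prediction

For cutoff day *t* ∈ {1, 3, 7, 14, 21}, features use only observations at
or before *t*:

* **PPA block**: all G posterior class probabilities per marker (the
  sum-to-one collinearity is tolerated by the elastic net); an empty
  window yields the model priors;
* **summary block**: mean, sd (n−1), min, max of raw values in-window;
* **baseline block**: age, gender, one-hot ethnicity/insurance
  (experiment III: age and gender only).

Experiments: I — in-hospital mortality (modeling cohort); II — SCI
presence vs spine trauma; III — motor-complete severity on the external
cohort with frozen trajectory models (no link or parameter refitting).

The classifier is glmnet-parametrized penalized logistic regression
(`λ[α‖w‖₁ + (1−α)/2 ‖w‖₂²]`, intercept unpenalized, features standardized
with training mean/sd, constant columns passed through), solved by FISTA
proximal gradient. The solver exists for throughput — the protocol needs
tens of thousands of fits — and is checked against off-the-shelf solvers
to ~1e-5 in the test suite. Protocol per experiment/cutoff/feature set:

* 25 repeats; repeat *r* uses seed `base_seed + r` and one stratified
  80/20 split reused across all cutoffs and feature sets (split
  stratification is this package's documented choice — at ~10% mortality
  prevalence an unstratified desk-scale split too often yields degenerate
  folds);
* stratified 5-fold CV over α ∈ {0.00, 0.11, …, 1.00} × λ ∈ {0.0001,
  0.11, …, 1.00}, maximizing Cohen's kappa at probability threshold 0.5
  (the reference tooling's default); kappa ties resolve toward larger λ,
  then larger α — deterministic and overfitting-averse;
* imputation (numeric median / categorical mode) learned on the training
  split only, inside each repeat;
* metrics: ROC-AUC (Mann–Whitney with tie half-credit) primary, PR-AUC
  (step-wise average precision) secondary, both in-train and out-of-train;
  95% CIs are t-based over the 25 repeats (single repeat ⇒ point CI);
* variable importance: |standardized coefficient| rescaled so the top
  feature scores 100, averaged over repeats, flagged above 40.

A kappa quirk worth documenting: with a rare outcome and genuinely weak
early-window signal, no grid cell beats kappa 0, the tie-break selects the
fully shrunk model, and the cell's AUC is exactly 0.5. That is the
intended behavior of threshold-based kappa selection, and it is why
desk-scale day-1 mortality AUC sits at the non-information rate while
later cutoffs rise well above it.

## Class associations

MAP classes per marker are tested against demographics and stay
characteristics: one-way ANOVA for continuous covariates (identical to the
pooled-t at 2 classes; Kruskal–Wallis available by flag, since the source
protocol's narrative and its cohort tables disagree on this point), Fisher
exact for categorical — exact at 2×2, seeded Monte-Carlo otherwise (2000
fixed-margin tables sampled by margin permutation; the p-value counts
tables at most as probable as the observed one). Benjamini–Hochberg is
applied within each marker's family (configurable to a global family);
significance at q < 0.05. Degenerate covariates are reported untestable
rather than dropped silently.

## Synthetic cohorts: what they emulate, and what they don't

Defaults (the package's study conditions, chosen once):

* 6 markers, groups of 120/60/420 subjects (SCI-fracture / SCI-no-fracture
  / spine trauma) — the real cohorts' imbalance at roughly quarter scale;
* per-day lab counts Poisson(2.5 · e^(−0.12·day)) with uniform within-day
  jitter, capped at min(length of stay, 22 days): front-loaded sampling,
  ~13 observations per subject-marker;
* length of stay log-normal (medians 10/8/7 days); age truncated-normal
  above 15 years; 1% zeros and 1% symmetric ≥5-sd outliers injected;
* 2–3 latent classes per marker; hematology-style geometry (classes with
  similar admission levels that diverge over the stay — a slow decline, a
  fast early drop, a low-flat class) on linear links for
  hemoglobin/hematocrit/sodium/glucose and beta-CDF links for wbc and
  potassium (skewed marginals); random intercepts (sd 0.2–0.3 latent) and
  small slopes;
* class frequencies differ by cohort group for the hematology markers —
  that group linkage is what makes SCI detection (experiment II)
  learnable;
* outcomes are Bernoulli with logit linear in true-class indicators and
  standardized age. Mortality (~10–12% prevalence, matching the cohort
  range) loads mostly on the late-diverging classes so the predictive
  value of trajectory membership grows with the cutoff; severity (~50%
  motor complete) loads on the low/high-flat classes. The external cohort
  (default n = 137, SCI groups only, severity labeled for everyone)
  supports additive latent-scale mean shift and rescaled sampling
  intensity.

Not emulated: cross-marker correlation beyond shared group membership
(real hematology panels are strongly correlated), unit heterogeneity and
LOINC mapping, informative observation times (sicker patients sampled
more), censoring by death/discharge interacting with trajectories, and
admission-coding structure. Passing tests therefore demonstrate that the
*machinery* recovers planted structure under realistic sampling geometry —
not that the clinical effect sizes transfer.

## Problem sizes and numerical choices in the shipped runs

* Acceptance-grade experiments use the full protocol grids and 25 repeats;
  trajectory fits in pipeline/acceptance runs use 2–3 starts and 120–300
  EM iterations (recovery and selection-consistency experiments validate
  these sizes).
* The selection-consistency experiment uses 10 replicate n=300 cohorts
  with true G = 3 and no random effects (the LCGA-faithful case the
  exploratory stage assumes); the recovery experiment uses the same
  generator with 5–15 observations per subject.
* The end-to-end determinism check runs the full chain twice at reduced
  scale (linear links, G ≤ 3, 2 repeats, cutoffs {1, 21}) and requires
  byte-identical serialized outputs.
* Covariance jitter: a single 10⁻⁸·trace/dim ridge on near-singular
  covariances; a second failure flags non-convergence. FISTA uses the
  spectral-norm Lipschitz bound, tolerance 1e-6 during CV scoring and
  1e-9 for final refits.
* Values outside a frozen beta link's domain (external cohorts) are
  clipped to the domain edge before posterior evaluation; the raw
  transform still raises, so silent clipping cannot leak into fitting.

## Known limitations

* The EM's variance/link sub-step uses numerical gradients; fits with
  I-spline or beta links are ~10–50× slower than linear-link fits, so the
  shipped end-to-end runs restrict grids accordingly (the full 900-spec
  grid is enumerated and unit-tested, and per-family fits are tested, but
  fitting all 900 at study scale is a batch job, not a test).
* ML (not REML) variance estimates: random-effect variances are biased
  low at moderate n; the GMM tests compare against observed-scale truth
  with that in mind.
* No joint multivariate trajectory model across markers (per-marker
  univariate models by design); no membership covariates in the mixture.
* Kappa-at-0.5 hyperparameter selection is coarse for rare outcomes at
  desk scale (see above); AUC-based selection would behave differently
  but is out of protocol.
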
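# Methods

This note documents the models behind `misspipe`, the defaults and why they
were chosen, what the synthetic cohorts do and do not emulate, and the
numerical choices that matter for reproducing its outputs.

## Synthetic cohorts

The generator stands in for a private clinical registry of pelvic-floor
prognostic factors; no real data ship with the package. A cohort is drawn
from a documented recipe:

1. Latent AR(1) Gaussian field `Z` with parameter ρ (default 0.2):
   `Z_0 = E_0`, `Z_j = ρ Z_{j−1} + √(1−ρ²) E_j`, standard-normal marginals,
   `corr(Z_j, Z_k) = ρ^{|j−k|}`.
2. Continuous features keep the latent value; binary features threshold it at
   zero. The default schema has d = 67 features, 40% binary, spread evenly —
   the registry's mix of instrument measurements and yes/no history items is
   not public, so the binary fraction is an explicit free choice, not an
   inference.
3. A sparse logistic outcome: 9 of the 67 features carry nonzero coefficients
   (mixed signs, magnitudes 0.7–1.2), the rest are noise. The intercept
   offsets the mean linear predictor so prevalence sits near 1/2.

The generator is bit-reproducible given `(spec, seed)`; a test re-executes
the recipe independently and compares draws exactly.

### Missingness

Three mechanisms are supported.

* **MCAR** — each cell masked independently with its per-feature rate.
* **MAR** — cell `(i, j)` masked with probability
  `sigmoid(a_j + b·x[i, driver])`, with the intercept `a_j` solved by root
  finding so the marginal rate is exact; the driver feature is always
  observed.
* **Clustered (row-susceptibility MCAR)** — a calibrated fraction of rows is
  "missing-prone"; cells are masked only inside prone rows, at conditional
  rates `p_j/π`, preserving the marginal per-feature rates.

The clustered mechanism exists because the registry's two row-level facts —
7.71% of cells missing overall and 77.5% of cases incomplete — are jointly
impossible under independent cell-wise masking with the published per-feature
profile (independence would make ~99.6% of rows incomplete). Real registries
concentrate missingness in a subset of patients (those who skipped the
instrumented examination), and the clustered mechanism reproduces exactly
that: the default profile puts rates (0.307, 0.306, 0.232, 0.231, 0.228) on
five features, calibrates the remaining 62 to hit the 7.71% overall rate, and
solves the prone-row fraction so ~77.5% of cases carry at least one missing
value.

What the generator does **not** emulate: informative (MNAR) missingness,
longitudinal/recurrence structure, multi-level categorical features, feature
distributions with skew or heavy tails. Tests passing on these cohorts
demonstrate correctness of the machinery and the expected qualitative
orderings under a known truth — not clinical performance on any real
registry.

## Imputers

All five share one contract: fitted on training rows only, observed cells
copied through bit-exactly, output free of missing values. Binary columns are
rounded at 0.5 on output (mean imputation uses the observed mode directly).

* **Mean/mode** — the baseline every learning method must beat.
* **EM** under a multivariate normal working model. E-step: per missingness
  pattern, conditional mean and covariance of the missing block; M-step:
  moment update including the conditional-covariance correction, plus a
  ridge jitter (default 1e-6) on the diagonal. Convergence on relative change
  of the observed-data log-likelihood (tol 1e-6, cap 100 iterations); the
  likelihood trace is retained and is nondecreasing, which a test asserts at
  1e-8 per step. Binary columns are treated as continuous during iteration —
  a deliberate model misspecification that keeps the E-step closed-form.
* **KNN** with the Minkowski metric (q = 2 by default). Distances use
  mutually observed coordinates rescaled by `√(d/#shared)`; candidates must
  observe the target column; ties break toward the lower row index; K = 5 by
  default (there is no theoretically optimal K). A column with no eligible
  candidates falls back to the column mean/mode with a warning.
* **DAE** — encoder widths (d+θ, d+2θ, d+3θ), mirrored decoder, θ = 7,
  tanh hidden units, linear output, squared-error loss on observed cells,
  Adam at 1e-3, 200 epochs, batch 64, min-max scaling to [0, 1] fitted on
  training observations. Missing inputs hold their column-mean placeholder.
  Training additionally *corrupts* 20% of observed inputs per batch (hides
  them behind their placeholders while the loss still scores them): this is
  the denoising step, and it is what forces the network to learn
  cross-feature prediction instead of the identity shortcut — without it the
  net reconstructs observed cells perfectly and never beats mean imputation
  at missing ones. The output-layer bias is initialized at the (scaled)
  column means, so the untrained network already matches the mean-imputation
  baseline and training starts from there instead of from zero outputs.
* **GAIN** — generator and discriminator are two-hidden-layer networks
  (width d, relu, sigmoid outputs) on features min-max scaled to [0, 1].
  The generator sees `(M⊙X + (1−M)⊙Z, M)` with `Z ~ U[0, 0.01)`; the
  composed vector `X̂ = M⊙X + (1−M)⊙X̄` and a hint vector go to the
  discriminator, which predicts per-coordinate observation probabilities.
  The default hint hides a single random coordinate per case at 0.5; a
  Bernoulli-hint variant (reveal probability configurable) is available and
  is what the package's own benchmarks use at rate 0.5, because hiding more
  coordinates densifies the only training signal the generator's missing
  slots receive. The discriminator's cross-entropy is trained over all
  coordinates (revealed coordinates contribute near-zero loss but stabilize
  the fit); the generator's adversarial term is restricted to hidden
  coordinates, where fooling is possible — extending it to revealed
  coordinates only injects unbounded clipped-log gradients. Reconstruction
  weight α = 100, batches 128, 10 000 iterations by default, Adam at 1e-3.
  The generator's output bias is likewise warm-started at the logit of the
  column means.

## Penalized logistic regression

The estimator minimizes `−l(β) + P_λ(β)` with the intercept unpenalized and
columns standardized internally (coefficients are reported on the original
scale). Families:

* LASSO `λΣ|β_j|` and Elastic Net (`mix` = 0.5 by default), solved by cyclic
  coordinate descent with soft-thresholding on the IRLS quadratic surrogate.
  IRLS weights are floored at 1e-5; a step-halving safeguard backtracks any
  surrogate overshoot, so the recorded objective trace is nonincreasing
  (asserted at 1e-10 per step).
* SCAD with shape a = 3.7 (the conventional value), solved by local linear
  approximation: reweighted-L1 problems with weights from the SCAD
  derivative `λ{I(t≤λ) + (aλ−t)₊/((a−1)λ) I(t>λ)}`, wrapped around the same
  engine; majorize-minimize makes the SCAD objective trace nonincreasing.
* BAR: ridge initialization (ξ = 1.0), then adaptively weighted ridge fits
  with weights `λ/β_j²`; coordinates falling below `zero_eps` = 1e-6 freeze
  at exactly zero for all later iterates (which also forecloses division by
  zero). Estimates are therefore exactly sparse. BAR is a fixed-point
  iteration, not descent on a single objective: the recorded trace (the L0
  surrogate `−l + λ/2·#active`) is a diagnostic, and the guaranteed descent
  property — each outer step lowers its own weighted objective — is exposed
  and tested via `step_objectives`.

Tuning: 5-fold stratified cross-validated binomial deviance for
LASSO/Elastic-Net/SCAD (ties prefer the larger, sparser λ); BIC
(`2·nll + log(n)·(support+1)`) for BAR. The post-selection refit is an
unpenalized maximum-likelihood fit on the support with standard errors from
the inverse observed information; the table reports β, Wald = (β/SE)²,
OR = e^β, 95% CI = e^{β±1.96·SE} and the χ²₁ upper-tail p-value, with
separation flagged rather than hidden.

## Benchmarking

Each repeat: stratified 80/20 split; imputer fitted on the training partition
only (a leakage test asserts that deleting test rows changes no fitted
parameter); optional selection on imputed training data; classifier trained;
held-out accuracy/F1 (threshold 0.5) and Mann–Whitney AUC (ties at 1/2).
Cells report means and sample SDs (n−1) over R repeats (default 100;
reduced sizes below for the shipped experiments). Per-repeat seeds spawn
deterministically from the master seed, so reports are bit-reproducible. The
complete-case baseline drops incomplete rows from both partitions and scores
the complete test subset — how incomplete test cases should be scored without
imputation is undefined, and this choice keeps the baseline's test
distribution honest (under MCAR-type mechanisms it is an unbiased subset).

## Problem sizes in the shipped tests and acceptance script

Chosen as the smallest designs where each property is identifiable:

* imputer quality: 500 × 10 Gaussian cohorts, AR(1) ρ = 0.7, 20% MCAR,
  5 seeds; GAIN at 3000 iterations (Bernoulli hint 0.5), DAE at 200 epochs.
  ρ = 0.7 makes conditional imputation clearly identifiable at n = 500; the
  cohort default (ρ = 0.2) is a separate choice modelling weakly correlated
  prognostic factors.
* BAR support recovery: n = 2000, d = 20, three coefficients ≥ 1 in
  magnitude, BIC over 8 grid points, 10 seeds; best-subset comparison at
  d = 8, n = 400 against exhaustive enumeration of all 2⁸ submodels.
* benchmark findings: n = 1000 cohorts with the registry profile, R = 10
  repeats, 10 master seeds, with reduced imputer configurations (EM capped at
  12 iterations, DAE 40 epochs, GAIN 500 iterations); and 20 seeds of
  n = 2000 for the BAR-vs-LASSO support-size comparison.

## Known limitations

* The EM working model is jointly Gaussian; binary columns violate it by
  construction (they are rounded post hoc).
* GAIN's adversarial signal is sparse whenever few coordinates are hidden;
  the defaults follow the single-slot hint formulation, and users comparing
  imputation quality should prefer the Bernoulli-hint benchmark
  configuration.
* The numpy networks run on a single CPU thread; they are sized for cohorts
  of thousands, not millions.
* Cross-validated λ for the penalized classifiers inside the benchmark uses
  a short fixed grid; per-cell bespoke grids would be slower and slightly
  sharper.
* No MNAR mechanism is provided, so the benchmark cannot exhibit the regime
  where complete-case analysis is asymptotically biased rather than merely
  inefficient.
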
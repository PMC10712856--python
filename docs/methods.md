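# Methods

## Model and estimator

We observe pairs (xᵢ, yᵢ), i = 1…n, with xᵢ ∈ ℝᵈ and yᵢ ∈ {0, 1}, where the
recorded label may differ from the true one: within each class a fraction ρ
of labels has been flipped (the classification-noise-process model with
class-conditional flip rates). The working model is a binary GLM,
π(x; β) = h(xᵀβ), with h either the logistic sigmoid or the standard-normal
CDF (probit). There is no intercept by default — the linear predictor is
xᵀβ exactly — and `add_intercept` prepends a constant column when one is
wanted.

Rather than maximizing the likelihood, which a single confidently
mislabeled point can dominate, the estimator maximizes the empirical
γ-divergence objective

    Q(β) = Σᵢ φᵢ(β) − n Σⱼ P_λ(|βⱼ|),
    φᵢ = ℓᵢ^γ / Sᵢ^{γ/(γ+1)},   ℓᵢ = πᵢ^{yᵢ}(1−πᵢ)^{1−yᵢ},
    Sᵢ = πᵢ^{γ+1} + (1−πᵢ)^{γ+1}.

φᵢ ∈ (0, 1] is bounded, so no single observation can contribute unbounded
pull; as γ → 0⁺, φᵢ → 1 + γ·(log ℓᵢ − log Sᵢ/(γ+1)) and the maximizer
converges to the (penalized) maximum-likelihood estimate — verified in the
tests against the `statsmodels` logistic fit. For the logit link the general
form collapses algebraically to
[exp{y(γ+1)xᵀβ} / (1 + exp{(γ+1)xᵀβ})]^{γ/(γ+1)}; both routes are
implemented independently and their agreement to 1e−12 is a standing test.

## Penalties

Three members of the usual class of folded penalties (nondecreasing,
P(0) = 0, continuous derivative) are provided, all scaled by a single
tuning parameter λ so that it acts uniformly across kinds:

- **SCAD** (shape α = 3.7, the Fan–Li convention): linear λt up to λ,
  quadratic transition on (λ, αλ], constant (α+1)λ²/2 beyond. Large
  coefficients are left unpenalized — the source of the oracle property.
- **MCP** (shape v = 3): λt − t²/(2v) up to λv, constant λ²v/2 beyond.
- **Lasso**: λt.

Derivatives are continuous on (0, ∞) for SCAD/MCP; the Lasso derivative is
the constant λ with subgradient value 0 returned at the origin so that
unpenalized stationary points remain stationary under plain gradient steps.

## Optimization: Meta Gradient Correction

The optimizer descends on loss = −Q with full-batch gradient steps by
default (minibatches, shuffled by the run seed, are available). At each
step the per-sample weights ωᵢ = φᵢ are recomputed at the current β — they
are never frozen — and each sample's loss gradient gᵢ = −∇φᵢ enters the
update with sign +1 if ωᵢ ≥ Tv (treated as clean) and −1 if ωᵢ < Tv
(suspected mislabeled, contribution reversed). The penalty gradient is
added once per step, scaled by the batch size. With Tv = 0 no weight can
fall below the threshold and the trajectory is bit-identical to plain
gradient descent (`fit_baseline` runs the same loop with the correction
disabled, as the ablation control).

When clean samples outnumber noisy ones per batch and the step size is
small relative to the gradient's Lipschitz constant, the loss sequence is
non-increasing. Empirically this monotonicity holds exactly (to 1e−8 per
epoch) in the study's high-dimensional regime (n < d, e.g. 200×500 at
ρ = 0.2, η = 0.01), which is where the method is intended to operate; at
low dimension with many epochs the correction can produce small transient
increases in Q, because the corrected dynamics ascend a *sign-modified*
objective rather than Q itself. The convergence test therefore runs in the
n < d regime.

Stopping: |Q_t − Q_{t−1}| ≤ tol·(1 + |Q_{t−1}|) with tol = 1e−6 by default,
max 500 epochs. Divergence (non-finite coefficients or objective) raises an
error naming the epoch and learning rate.

**Learning-rate convention.** The update uses the *sum* gradient over the
batch (matching the objective's sum form), so the appropriate η scales like
1/n: the default η = 0.01 suits the n < d study conditions, while the
larger-n experiments in the tests use η ≈ 2/n. For near-zero γ the gradient
carries an overall factor γ, so the γ → 0 comparisons use η ≈ 2/(γn).

**Sparsity reporting.** Plain gradient iterates never land on exact zeros;
`FitResult.beta_sparse` zeroes entries with |βⱼ| < 1e−3 (configurable)
while the raw iterate is preserved. For folded-concave fits the recommended
schedule — used in the tests and acceptance runs — is a two-stage one:
an unpenalized warm start, then penalized refinement with a small step
(η·n·λ below the reporting tolerance, since the oscillation amplitude of a
null coordinate under a constant step is of that order). Proximal or
coordinate-descent solvers are deliberately out of scope.

**Choice of λ.** The operating default is λ = 1, used throughout the
ablation grid. The support-recovery experiments instead use
λ = 2√(log d / n), the classical vanishing-λ regime in which the
folded-concave theory (consistency, sparsity, asymptotic normality) holds;
the factor 2 places the SCAD flat region αλ above the sampling noise of
null coordinates, which is necessary because SCAD exerts no shrinkage at
all beyond αλ.

## Noise detection and evaluation

Two flagging rules are exposed: thresholding the weights (ωᵢ < Tv, the
default, Tv = 0.5) and prediction/label disagreement. Detection quality is
scored with "noisy" as the positive class: recall = tp/(tp+fn),
precision = tp/(tp+fp), F1 their harmonic mean. Any metric with a zero
denominator is reported as an explicit `None`, never as 0; grid averages
skip undefined values and report the count of contributing repetitions.
Prediction accuracy is reported both against the observed labels
(ACC_noisy) and, when ground truth is carried, the true labels (ACC_true).

## Synthetic data

The generator emulates the simulation design: xᵢ i.i.d. N(0, I_d); β_true
with s nonzero entries of ±magnitude at seeded random positions (defaults
s = 10, magnitude 1 — the covariate law, class balance and coefficient
scale are this package's choices, since only the dimensions and flip ratios
of the design are fixed); labels Bernoulli(π(x; β_true)); then
class-conditional flipping: within each observed class, ⌊ρ·n_c⌋ samples
chosen uniformly without replacement are flipped, with the flip recorded in
a mask and the true label preserved. Test sets are flipped at the same ρ
with an independent seeded stream. The floor rule reproduces the 456/115
arithmetic of an 0.8/0.2 split of 571 samples. Everything is a pure
function of (spec, seed).

What this generator does **not** emulate: correlated or heavy-tailed
covariates, covariate-dependent (instance-dependent) flip probabilities,
class imbalance, and intercepts. Passing tests on this data therefore
demonstrate correctness of the machinery and the qualitative robustness
ordering, not performance claims for arbitrary real data.

## Numerical choices

- All probability work is in the log domain (`log_expit`, `log_ndtr`,
  log-sum-exp); probabilities are clipped to [1e−12, 1−1e−12], so extreme
  linear predictors cannot overflow and every weight stays strictly inside
  (0, 1]. The logit-form route clips the linear predictor to the equivalent
  range so the two algebraic forms agree to machine precision.
- The probit score (y−π)·pdf/(π(1−π)) is evaluated as
  exp(log pdf − log π − log(1−π)), which stays bounded under clipping.
- Penalty gradients use subgradient 0 at βⱼ = 0.
- Initial β is the zero vector unless a warm start is supplied.
- Problem sizes in the tests and acceptance script (e.g. 10–50 seeded
  repetitions, grids at 100×20, recovery at n = 2000–4000 with d = 10) are
  desk-scale reductions of the full 50-repetition design, chosen to keep a
  complete run in minutes on one core while preserving each qualitative
  conclusion.

## Known limitations

- MGC's benefit is marginal at the default operating point — consistent
  with the small gaps between the corrected and uncorrected rows of the
  method's own ablations — and the sign correction can mildly hurt when the
  flagged set has many false positives (visible in the low-dimensional
  worked example).
- In the strongly overparameterized regime the unregularized fit can
  interpolate the observed (noisy) labels, driving all weights above Tv and
  emptying the flagged set; the disagreement rule inherits the same
  failure. Penalization mitigates but does not remove this.
- Weight-based detection at Tv = 0.5 is a hard threshold with no
  calibration; ROC-style analysis is out of scope.
- Only logit and probit links, binary responses, and the three penalties
  above are supported.
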
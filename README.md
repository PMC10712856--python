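# gammaglm

Robust binary classification when some of your labels are wrong.

`gammaglm` fits logistic and probit regression models to data whose binary
responses are contaminated by class-conditional label flipping — the setting
where a fraction of 0s were recorded as 1s and vice versa, as happens with
imperfect diagnostic calls, crowd-sourced annotation, or automated labeling
pipelines. Instead of the log-likelihood, it maximizes an empirical
**γ-divergence** objective, optionally penalized for sparsity in high
dimensions (n < d), and optimizes it with a **Meta Gradient Correction
(MGC)** scheme that detects suspect samples on the fly and reverses their
pull on the coefficients.

## The model

For a binary GLM with success probability π(x; β) = h(xᵀβ) (h the logistic
sigmoid or the standard-normal CDF), each observation contributes the term

    φᵢ = [πᵢ^{yᵢ} (1−πᵢ)^{1−yᵢ}]^γ / [πᵢ^{γ+1} + (1−πᵢ)^{γ+1}]^{γ/(γ+1)} ∈ (0, 1],

and the estimator maximizes

    Q(β) = Σᵢ φᵢ − n Σⱼ P_λ(|βⱼ|),

where P_λ is one of the SCAD, MCP or Lasso penalties. The tuning parameter
γ > 0 controls robustness: as γ → 0 the estimator reduces to penalized
maximum likelihood, while larger γ discounts observations that fit the
current model poorly — exactly the behavior a mislabeled sample provokes.

The same quantity φᵢ doubles as a per-sample **credibility weight**
ωᵢ: a small value marks a likely mislabeled sample. MGC exploits this
during optimization: at every gradient step, samples with ωᵢ ≥ Tv
contribute their ordinary (descent) gradient on the loss −Q, while samples
with ωᵢ < Tv contribute the sign-flipped gradient, neutralizing their
influence. With Tv = 0 the iteration is exactly plain gradient descent.
After fitting, the weights (or prediction/label disagreement) yield
noisy-label flags that are scored by recall, precision and F1 against the
known flip mask in simulations.

Default hyperparameters: γ = 0.5, λ = 1, Tv = 0.5, learning rate η = 0.01.

## Worked example

```python
from gammaglm import (SimulationSpec, generate_clean, flip_labels, fit,
                      ModelConfig, predict, accuracy_metrics, detection_metrics)

spec = SimulationSpec(n_train=500, n_test=200, d=50, s=10,
                      beta_magnitude=1.0, noise_ratio=0.2, seed=42)
train, test, beta_true = generate_clean(spec)
train = flip_labels(train, 0.2, seed=43)   # 20% of each class flipped
test = flip_labels(test, 0.2, seed=44)

config = ModelConfig(gamma=0.5, threshold=0.5, learning_rate=0.004,
                     max_epochs=2000, tol=1e-8)
result = fit(train, config)

preds = predict(test.X, result.beta, config.link)
acc_noisy, acc_true = accuracy_metrics(preds, test.y_observed, test.y_true)
recall, precision, f1, _ = detection_metrics(result.noisy_flags, train.flip_mask)
```

This prints (via the obvious `print` statements):

```
epochs run: 517
flagged 76 of 500 training samples (99 were actually flipped)
test accuracy vs observed labels: 0.560
test accuracy vs true labels:     0.645
detection recall=0.404 precision=0.526 f1=0.457
```

Accuracy against the *observed* labels is capped near 1 − ρ by the flips
themselves; accuracy against the *true* labels shows the model has partly
seen through the 20% contamination, and the flagged set recovers a sizable
share of the genuinely flipped samples.

## Command line

```sh
gammaglm simulate --n-train 200 --d 500 --rho 0.2 --seed 1 --out data.csv
gammaglm fit data.csv --gamma 0.5 --penalty scad --out fit.json
gammaglm evaluate fit.json data_test.csv --out report.json
gammaglm grid grid.yaml --out results.csv
```

`grid` runs the full ablation: two backbones (logit/probit) × MGC on/off ×
four penalties × the configured dimensions and flip ratios, averaging the
five metrics (ACC_noisy, ACC_true, Recall, Precision, F1) over seeded
repetitions. Undefined metrics are excluded from averages and the number of
contributing repetitions is reported per cell.

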
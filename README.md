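# bandedreg

Empirical-Bayes **banded regression**: linear models whose predictors are
partitioned into named feature groups ("bands"), each with its own shrinkage
strength learned from the data by an expectation-maximization (EM)
algorithm.

## Who this is for

Encoding and decoding analyses in computational neuroscience routinely fit
linear models whose predictors fall into natural groups — distinct stimulus
feature spaces (spectrogram bands, phoneme indicators, semantic embeddings)
in an encoding model, or all time-lag copies of each electrode in a
decoding model.  A single ridge penalty shrinks all groups equally, which
dilutes weights across correlated groups and cannot suppress an entirely
irrelevant feature space.  `bandedreg` gives every group its own shrinkage
scale, tuned automatically without cross-validation, and can additionally
encourage smooth weight profiles within a group (e.g. FIR filters across
time lags).

## Model

For targets `y ∈ R^M` and grouped design `X = [F_1, …, F_J] ∈ R^{M×D}`:

    y | X, w, ν   ~  N(Xw, ν I_M)
    w             ~  N(0, Λ),   Λ = blockdiag(λ_1 Ω_1, …, λ_J Ω_J)
    λ_j           ~  Inv-Gamma(η, τ),    ν ~ Inv-Gamma(φ, κ)

Each `Ω_j` is fixed a priori: the identity, or a Matérn covariance of order
3/2, `Ω_j[k,i] = (1 + √3|k−i|/h_j)·exp(−√3|k−i|/h_j)`, when the group's
weight profile should be smooth.  The hyperparameters `(λ, ν)` are point
estimates that maximize the marginal posterior `p(λ, ν | y, X)` by EM:

* **E-step** — posterior over the weights at fixed hyperparameters:
  `Σ = (Λ⁻¹ + ν⁻¹XᵀX)⁻¹`, `μ = ν⁻¹ΣXᵀy`
* **M-step** — closed form:
  `λ_j ← (μ_jᵀΩ_j⁻¹μ_j + Tr(Ω_j⁻¹Σ_j) + 2τ)/(D_j + 2η + 2)` and
  `ν ← (‖y − Xμ‖² + Tr(XᵀXΣ) + 2κ)/(M + 2 + 2φ)`

A single broad setting `γ = η = τ = φ = κ = 10⁻⁴` (the default) lets the
model shrink irrelevant groups aggressively while leaving relevant ones
nearly untouched.  With `T` target columns sharing the design, one set of
`(λ, ν)` is estimated jointly at the cost of a single covariance
factorization per iteration.  A cross-validated ridge baseline
(`w = (XᵀX + αI)⁻¹Xᵀy`) is included for comparison.

## Worked example

Three 64-predictor Gaussian groups, 1024 observations at 0 dB SNR; the
middle group truly contributes nothing:

```python
import numpy as np
from bandedreg import EMBanded, Hyperpriors, recipe, simulate

data = simulate(recipe(1, seed=0))      # benchmark design 1
model = EMBanded(data.design, data.y, hyperpriors=Hyperpriors(gamma=1e-4))
res = model.fit()
print(res.summary())
```

```
Banded empirical-Bayes regression (EM)
======================================================
Observations:     1024   Predictors: 192
Groups:              3   Targets:    1
Iterations:        200   Converged:  False (max_iter)
Residual variance nu: 91.5219
------------------------------------------------------
group                 size        lambda       h
F1                      64      0.717043       -
F2                      64   0.000112522       -
F3                      64      0.684675       -
------------------------------------------------------
Final objective: -3937.182106 (increase 37017.022354)
```

The inert group `F2` receives a shrinkage scale nearly four orders of
magnitude below the active groups — its weights are crushed toward zero
(mean squared weight `8.2e-08`) — while the active-group weights correlate
with the generating truth at `0.944`:

```python
active = np.concatenate([res.coef_group("F1"), res.coef_group("F3")])
truth  = np.concatenate([data.true_weights[:64], data.true_weights[128:]])
print(np.corrcoef(active, truth)[0, 1])    # 0.944
```

`res.predict(X_new)` makes point predictions;
`res.predict(X_new, mode="distribution")` also returns the predictive
covariance `ν̃I + X̂Σ̃X̂ᵀ`.  The same workflow is available from the shell:

```
bandedreg simulate --sim 1 --seed 0 --out sim_
bandedreg fit --x sim_X.csv --y sim_y.csv --config groups.yaml --gamma 1e-4 --out fit_
bandedreg sweep --x sim_X.csv --y sim_y.csv --config groups.yaml \
    --gamma-grid 1e-6,1e-5,1e-4,1e-3,1e-2,1e-1 --out sweep_
```

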
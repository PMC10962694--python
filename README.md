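# cdrnn — continuous-time deconvolutional regression with neural impulse responses

Behavioral and neural time series from naturalistic experiments — reading
times, fMRI BOLD, and similar — superpose delayed responses to many
irregularly spaced stimulus events. Standard regression models force such
data into discrete time and typically assume linear, stationary,
homoscedastic effects. `cdrnn` implements continuous-time deconvolutional
regressive neural networks (CDR-NNs): a regression family in which a small
feedforward network *is* the impulse response function (IRF), mapping each
event's delay, onset time and predictor values onto its contribution to
**every** parameter of the response distribution.

For a response sample at time τ and events `(t_n, x_n)` with delays
`d_n = τ − t_n`:

```
G_n = f_IRF([d_n; t_n; x_n])  ∈ ℝ^{S×(J+1)}
s   = s_0 + Σ_n G_n diag(b) [1; x_n],      y ~ F(s)
```

where `b` weights each impulse column (its leading slot is *rate*, the
baseline response evoked by any event) and `s_0` is an intercept. The
additive read-out keeps the network interpretable: single-event
perturbations of the inputs recover the full IRF exactly, with Monte Carlo
dropout credible bands. Random effects add zero-centered per-group
deviations to `b` and `s_0`. Constraints (linearity, stationarity,
homoscedasticity, causality, predictor ablation, a Dirac reduction that
collapses the family to linear regression) define nested nulls that are
tested by paired permutation tests on out-of-sample log likelihood.

The intended users are cognitive scientists and neuroscientists analyzing
observational event streams, and methodologists studying deconvolutional
regression itself. Everything runs on plain numpy/scipy/pandas — the
networks are small enough that the package carries its own forward pass,
analytic backprop and Adam optimizer.

## Worked example

Simulate the packaged quickstart conditions — 2000 events across 4
participants, exponential spacing (mean 0.3 s), two predictors convolved
with known exponential kernels, unit noise, per-participant random
intercepts — and fit a model:

```python
import numpy as np
from cdrnn import (CDRNN, ModelSpec, TrainConfig, ConvergenceConfig,
                   quickstart_fixture)

events, responses, truth, kernels, config = quickstart_fixture()
spec = ModelSpec(predictors=("x1", "x2"), groups=("participant",), d_max=2.5)
res = CDRNN(events, responses, spec).fit(
    TrainConfig(seed=1, max_epochs=800, dropout=0.1, lr_decay=0.999,
                convergence=ConvergenceConfig(window=100,
                                              eval_metric="exploratory_loglik"))
)
print(res.summary())
```

```
Continuous-time deconvolutional regression (neural IRF)
========================================================
Response:            y ~ normal
Predictors (J=2):    x1, x2
Constraints:         causal, nonstationary, heteroscedastic
IRF network:         4 -> 32 -> 32 -> 6 (tanh)
History window:      0..2.5 s
Trainable params:    1439
Epochs run:          800 (converged: not reached)
Final metric:        -1.48342 (mean loglik/sample)
Penalized objective: 1427.689
Seed:                1

Coefficients b (scale of each impulse-response column):
  rate               +0.9327
  x1                 +1.2152
  x2                 +1.0528
Intercept s0:        mu=+1.3394, sigma=1.2593
Random effects (participant, 4 levels): coef sd=0.0627, bias sd=0.1692
```

The coefficients `b` are scale factors on the learned IRF columns (their
product with the network output is what matters); the intercept is the
response's baseline location and scale. Querying the IRF by perturbation
— the estimated change in the response from a one-SD increase in `x1`, by
delay — and comparing against the generating kernel `e^{−5d}`:

```python
r = res.irf_curve("x1", delay_grid=[0.0, 0.2, 0.5], n_mc=64, seed=0)
```

```
delay 0.0s: effect +0.892  [+0.718, +0.987]  (truth +1.000)
delay 0.2s: effect +0.642  [+0.539, +0.720]  (truth +0.368)
delay 0.5s: effect +0.185  [+0.091, +0.315]  (truth +0.082)
```

A single short fit tracks the kernel's decay but smooths its sharp peak;
the ensemble protocol used by the validation studies (4 members, up to 3000
epochs with the time-loss convergence criterion) brings the curve within a
normalized RMSE of about 0.12 of the truth and the held-out log likelihood
within about 4% of the generator's oracle bound.

Hypothesis tests compare a full against a constrained ensemble on held-out
data:

```python
from cdrnn import ConstraintSet, compare
report = compare(events, responses, spec, ConstraintSet(ablate=("x1",)),
                 n_members=4, n_perm=10000)
print(report.summary())   # Δ loglik and permutation p-value
```

A command-line front end mirrors the library (`cdrnn simulate / partition /
fit / predict / plot / test`); each subcommand writes its artifacts plus a
manifest into a run directory.

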
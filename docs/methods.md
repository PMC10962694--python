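# Methods

## The model

`cdrnn` fits continuous-time deconvolutional regression models with neural
impulse response functions (CDR-NNs) to variably spaced event streams. The
data are two time series: stimulus events `(t_n, x_n)` — a timestamp in
seconds and a K-vector of predictors — and response samples `(τ, y)` with
categorical random-grouping labels (e.g. participant). The model maps the
event history onto *all* parameters of the response distribution at time τ:

    d_n = τ − t_n                                  (signed delay)
    G_n = f_IRF([d_n; t_n; x_n])   ∈ ℝ^{S×(J+1)}   (impulse response)
    s   = s_0 + Σ_n G_n diag(b) [1; x_n]           (convolution)
    y ~ F(s)

with `f_IRF` a small feedforward network (default two tanh layers of 32
units, identity output), `b ∈ ℝ^{J+1}` a coefficient vector whose leading
slot weights a constant *rate* regressor (the baseline response evoked by any
event, a "deconvolutional intercept"), and `s_0` an ordinary intercept. The
input transform `f_in` is the identity in all fitted models (impulses equal
predictors, J = K); a feedforward `f_in` is available as a standalone
operation but not as a fitting path, since effect nonlinearities are already
captured by `f_IRF`.

Because the read-out is additive over events, `G_n` is a complete description
of event n's contribution, which is what makes the network interpretable: the
impulse response can be queried exactly by perturbation (below).

Constraints carve out nested null families:

* **causal** (default on): `G_n = 0` whenever `d_n < 0`; delay 0 counts as
  the past.
* **stationary**: `t_n` is withheld from the network, so effects cannot
  drift over absolute time.
* **linear** (per predictor or all): the predictor is withheld from the
  network inputs but kept in the convolution product, making its effect
  exactly linear in its value.
* **homoscedastic**: rows of `G_n` beyond the location row are zeroed and
  random effects may not touch the scale component of `s_0`, so σ is a
  single shared constant.
* **ablate**: the predictor is removed everywhere.
* **dirac**: `f_IRF` is replaced by an indicator on `d = 0`. With identity
  `f_in` the family collapses to linear regression, which the test suite
  exploits as a closed-form oracle (fitted coefficients must match OLS).

## Response distribution

Only the normal family is implemented end to end (`S = 2`). The location
uses an identity link. The scale uses a **log link**: additive per-event
contributions to the raw scale parameter act multiplicatively on σ, which is
the standard convention in distributional regression (GAMLSS) and gives a
bounded gradient `∂NLL/∂s_σ = 1 − z²`. We initially used a softplus link;
with a multiplicative heteroscedastic data-generating process (the
generator's `σ ∝ exp(γ·x)` map) softplus-additive contributions produced
systematically biased single-event σ queries, so the log link is the
package's deliberate choice. The raw scale is clipped at ±20 before
exponentiation. Multivariate responses would be handled as independent
families per dimension; only Y = 1 is exercised.

## Mixed effects

Every parameter conceptually lives in a vector `v = v_0 + Vz`, where `z`
indicates the active random-effects levels and the rows of `V` sum to zero
within each grouping factor. The generic composition and centering
operations support arbitrary parameter blocks. The *trainable* model applies
random effects to the coefficient vector `b` (random slopes, including rate)
and the intercept `s_0` (random intercepts); random deviations of the
network weights themselves are accepted by the parameter-store type but not
fitted — per-level network weights would require per-level forward passes
for little benefit at the problem sizes targeted here. Deviations are
re-projected to exact zero sum after every epoch and shrunk by an L2 penalty
(strength 1.0 by default; network weights get 0.01).

## Estimation

Parameters are fitted by Adam (default learning rate 1e-3, batch 1024,
optional multiplicative per-epoch learning-rate decay) on the penalized
negative log likelihood, with inverted dropout (default rate 0.1) on the
hidden layers of `f_IRF` during training. Dropout doubles as the variational
posterior approximation: resampling dropout masks at query time yields
Monte Carlo draws of the impulse response. The networks are small enough
that the forward pass, analytic backprop, and Adam are implemented directly
in numpy; gradients are verified against finite differences in the test
suite.

Predictors, timestamps and delays are standardized by training-set
statistics before entering the network (predictor statistics over the event
stream; delay/time statistics over the training pairs); all reported
estimates are on the original scales. The intercept is initialized at the
training response's mean and log-SD, the coefficient vector at 1, and the
output layer near 0.

**History window.** The convolution is truncated to events with
`0 ≤ d ≤ d_max` (default 10 s for reading-like data; the recovery studies
use 2.5 s because their generating kernels decay within ~1 s). The
`history_window_diagnostic` reports the share of fitted IRF mass beyond
`d_max` so users can verify the truncation is harmless.

**Convergence.** Training stops early under the time-loss criterion: at each
evaluation epoch, the Pearson correlation between the metric (training or
exploratory-set log likelihood) and training time is tested at α = 0.5 over
the most recent `window` = 100 evaluations; the run has converged when at
least half of the last 100 epochs fail to reject the null of no correlation.
Testing each endpoint over a sliding window (rather than the full history)
is required for the criterion to detect a plateau that follows a long
improvement phase. Under a pure i.i.d. plateau the fail-to-reject count
fluctuates around the decision threshold, so detection is sequential rather
than guaranteed at any fixed epoch; the validation suite asserts the
sequential behavior. `fit` also keeps the parameter snapshot from the best
evaluation epoch (`restore_best`), which curbs late-training overfitting
when the exploratory metric is used.

## Interpretation by perturbation

All effect queries are built from single hypothetical events evaluated at
population level (z = 0), so they are invariant to unrelated context by
construction:

* `irf_curve` — change in a distribution parameter from one event whose
  queried predictor sits one training SD above the reference (the
  training-set mean), as a function of delay; `rate` compares an event at
  the reference against no event.
* `effect_surface` — the same over predictor value × delay (computed
  column-wise so a slice of the surface reproduces `irf_curve` exactly).
* `functional_form_slice` — effect versus predictor value at a fixed delay.
* `interaction_surface` — joint effect over two predictors at a fixed delay.
* `sigma_irf` — `irf_curve` targeting σ.
* `nonstationarity_curve` — effect at a fixed delay versus event onset time.

Point estimates are means over Monte Carlo dropout draws (pooled over
ensemble members when present); bands are pointwise empirical quantiles
(default 95%). A posterior draw is one sampled network — a single unit mask
per hidden layer shared across the whole grid — so constraint-induced
degeneracies (flat in onset under stationarity, linear under linearity, zero
σ-response under homoscedasticity) hold exactly draw by draw, giving each
null hypothesis an executable definition. The bands reflect dropout and
ensemble variation only, not full posterior uncertainty; they are
anti-conservative for sharp kernel features, which is visible in the
recovery studies. Default grids: delay 0–1 s (201 points) for reading-like
fits, 0–30 s for fMRI-like; predictor grids span ±2.5 training SDs.
Fixed-delay slices default to 5 s (near the hemodynamic peak); the recovery
studies slice at the generating kernel's peak (0 s for exponential kernels).

## Hypothesis testing

Nulls are constraint sets applied to the model spec (`build_null`). Full and
constrained ensembles (default 10 members differing only in seed) are fitted
on the training partition; ensemble prediction is the mixture of member
predictive densities (log-mean-exp of per-sample log likelihoods). The
per-sample conditional log likelihoods on a held-out partition are compared
with a paired permutation test: statistic `|Σ(llₐ − ll_b)|`, null built by
independently swapping each pair's labels with probability ½ (optionally per
participant cluster), add-one smoothed p-value `(1 + #{null ≥ obs}) /
(1 + n_perm)`, default `n_perm` = 10000.

## Data handling

The partitioner cycles units through `(e + u) mod 4` with outputs {0,1} →
train, {2} → exploratory, {3} → test, where `e` is a sentence index
(reading-like) or a chunk index `⌊i/chunk_len⌋` of consecutive samples
(fMRI-like, default 15 samples ≈ 30 s at a 2 s sampling interval) and `u`
phases participants. Exclusion filters for self-paced reading (durations
outside (100 ms, 3000 ms), sentence-boundary items, participants missing ≥4
comprehension questions or left with <100 responses) and eye-tracking
(unfixated items, saccades longer than 4 words, boundary items, blinks) are
implemented with per-rule exclusion reports; because the ordering of the
sentence-boundary rule relative to the 100-response count is
underdetermined, the report carries participant counts under both orders.
Scan-path predictors can be split into `+reg`/`−reg` variants by the
in-regression indicator, conserving column sums.

## Synthetic ground truth

The generator emulates the targeted study designs: events with fixed or
exponential inter-arrival times carrying standard-normal predictors;
responses either event-aligned (reading-like) or on a fixed 2 s grid
(fMRI-like); known kernels (exponential decay, an HRF-like double-gamma with
peak ≈ 5 s and undershoot ratio 1/6, Dirac); optional per-participant random
intercepts, a linear nonstationary gain ramp `m(t)`, and multiplicative
heteroscedasticity `log σ(τ) = log σ₀ + Σ_n Σ_k γ_k x_{nk} kernel_k(d_n)`.
The truth record stores each sample's exact mean and scale, so the
generator's oracle log likelihood upper-bounds any fitted model's held-out
likelihood up to sampling noise.

The quickstart conditions — 2000 events over 4 participants, exponential
spacing with mean 0.3 s, two predictors with exponential kernels
(a = 1, λ = 5 and a = −0.5, λ = 2), a small rate kernel, unit noise,
random-intercept SD 0.2, chunk-cycled 50/25/25 partition — are sized so that
a full recovery study (a 4-member ensemble, up to 3000 epochs each with the
time-loss criterion on the exploratory metric) runs in a few minutes on one
CPU. What these studies show is kernel identifiability and calibration of
the machinery under the generator's assumptions (additive kernels, Gaussian
noise, log-linear heteroscedasticity, exchangeable samples); they do not
establish anything about real reading or imaging data, which add predictor
collinearity, autocorrelated noise, and model misspecification.

## Numerical choices and edge cases

* Delays use exact arithmetic on the given timestamps; a global time shift
  changes predictions only at floating-point roundoff (~1e-13).
* Simultaneous events are allowed and order-stable; duplicate events
  contribute additively (superposition is exact).
* Responses with empty history windows get the pure intercept prediction.
* Unknown random-effects levels at prediction time fall back to the
  population (z = 0) with a warning.
* Constant metric stretches in the convergence test are treated as "fail to
  reject" (p = 1).
* A non-finite training objective halts with an error rather than
  continuing.
* Checkpoints are single `.npz` archives (arrays plus JSON metadata,
  format-versioned); a reloaded checkpoint reproduces predictions
  bit-for-bit.

## Known limitations

* Only the normal response family is implemented; gamma/Bernoulli are
  interface stubs.
* `f_in` networks and random effects on network weights are not fitting
  paths.
* The recurrent, stateful generalization of the model is out of scope.
* Credible bands come from MC dropout and ensembling, not a full posterior;
  coverage is approximate and can undershoot for sharp kernel features.
* Smooth tanh IRFs systematically smooth very steep kernels in delay
  (visible as undershoot at the peak and overshoot just after it); deeper
  or wider networks sharpen this at extra cost.
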
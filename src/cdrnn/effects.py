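"""Perturbation-based interpretation of a fitted model.

Because the convolution read-out is additive over events, the causal
contribution of a single event can be queried exactly: construct one event
with chosen predictor values at a chosen onset, evaluate the model's
response-distribution parameters at a chosen delay, and subtract the same
evaluation at a reference point. All queries here are built single-event, so
they are invariant to unrelated context by construction.

Uncertainty comes from Monte Carlo dropout: each posterior draw resamples the
dropout masks of the impulse-response network; credible bands are pointwise
empirical quantiles over draws (pooled over ensemble members when present).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import output_mask
from .nn import ffn_forward

RATE = "rate"


@dataclass
class EffectQuery:
    """A gridded what-if question about the fitted response."""

    target_param: object = "mu"  # name or index into the linked parameters
    predictors: tuple = ()
    predictor_values: object = "+1sd"
    delay_grid: np.ndarray = None
    onset_time: object = None
    reference_point: np.ndarray = None
    n_mc: int = 100
    level: float = 0.95

    def __post_init__(self):
        if not 0.0 < self.level < 1.0:
            raise ValueError("credible level must lie in (0, 1)")
        if self.n_mc < 1:
            raise ValueError("n_mc must be positive")


@dataclass
class EffectQueryResult:
    """Gridded change in a response-distribution parameter with credible bands."""

    grid: dict
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    target_param: object = "mu"
    predictors: tuple = ()
    draws: np.ndarray = field(default=None, repr=False)

    def to_frame(self):
        import pandas as pd

        axes = list(self.grid.items())
        mesh = np.meshgrid(*[v for _, v in axes], indexing="ij")
        cols = {name: m.ravel() for (name, _), m in zip(axes, mesh)}
        cols["estimate"] = self.estimate.ravel()
        cols["lower"] = self.lower.ravel()
        cols["upper"] = self.upper.ravel()
        return pd.DataFrame(cols)

    def plot(self, path=None, ax=None):
        """Line plot (1-D grid) or filled surface (2-D grid)."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        axes = list(self.grid.items())
        if ax is None:
            fig, ax = plt.subplots(figsize=(5, 3.5))
        else:
            fig = ax.figure
        if len(axes) == 1:
            name, x = axes[0]
            ax.fill_between(x, self.lower, self.upper, alpha=0.3)
            ax.plot(x, self.estimate)
            ax.axhline(0.0, lw=0.5, color="k")
            ax.set_xlabel(name)
            ax.set_ylabel(f"change in {self.target_param}")
        elif len(axes) == 2:
            (na, a), (nb, bg) = axes
            pc = ax.pcolormesh(bg, a, self.estimate, shading="auto")
            fig.colorbar(pc, ax=ax, label=f"change in {self.target_param}")
            ax.set_xlabel(nb)
            ax.set_ylabel(na)
        else:
            raise ValueError("can only plot 1-D or 2-D grids")
        if self.predictors:
            ax.set_title(" x ".join(map(str, self.predictors)))
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return ax


def credible_band(draws: np.ndarray, level: float = 0.95):
    """Pointwise empirical quantile band over draws (axis 0)."""
    if not 0.0 < level < 1.0:
        raise ValueError("credible level must lie in (0, 1)")
    q = (1.0 - level) / 2.0
    lo = np.quantile(draws, q, axis=0)
    hi = np.quantile(draws, 1.0 - q, axis=0)
    return lo, hi


# ---------------------------------------------------------------------------
# single-event evaluation


def _param_index(res, target_param) -> int:
    if isinstance(target_param, (int, np.integer)):
        return int(target_param)
    names = {"mu": 0, "sigma": 1} if res.spec.family == "normal" else {}
    if target_param not in names:
        raise ValueError(f"unknown target parameter {target_param!r}")
    return names[target_param]


def _check_predictor(res, name):
    if name != RATE and name not in _members(res)[0].spec.predictors:
        raise ValueError(f"unknown predictor {name!r}")


def linked_single_event(res, d, t0, x_raw, draw_seed=None) -> np.ndarray:
    """Linked distribution parameters for a lone event (or none).

    ``d``, ``t0`` are arrays of delays and onset times (seconds); ``x_raw``
    is an ``(n, K)`` array of raw predictor values, or ``None`` for the
    no-event baseline. Population-level (z = 0) prediction.
    """
    spec, stz, theta = res.spec, res.stz, res.theta
    fam = res.family
    d = np.atleast_1d(np.asarray(d, dtype=float))
    n = d.shape[0]
    bias = np.tile(theta["bias"], (n, 1))
    if x_raw is None:
        return fam.link(bias)
    t0 = np.broadcast_to(np.asarray(t0, dtype=float), (n,))
    x_raw = np.broadcast_to(np.atleast_2d(np.asarray(x_raw, dtype=float)), (n, len(spec.predictors)))
    X_std = stz.std_x(x_raw)
    S = fam.n_params
    J1 = len(spec.predictors) + 1
    E = np.hstack([np.ones((n, 1)), X_std])
    if spec.dirac:
        G = (np.abs(d) < 1e-9).astype(float)[:, None, None] * np.ones((1, S, J1))
    else:
        cols = [stz.std_d(d)[:, None]]
        if spec.nonstationary:
            cols.append(stz.std_t(t0)[:, None])
        nl_ix = [i for i, p in enumerate(spec.predictors) if p in spec.nonlinear_set]
        if nl_ix:
            cols.append(X_std[:, nl_ix])
        U = np.hstack(cols)
        params = [(theta[f"W{l}"], theta[f"b{l}"]) for l in range(res.ffspec.n_layers)]
        masks = res.draw_masks(draw_seed, n)
        out, _ = ffn_forward(res.ffspec, params, U, masks)
        G = out.reshape(n, S, J1)
    G = G * output_mask(spec, S, J1)
    if spec.causal:
        G = np.where((d < 0)[:, None, None], 0.0, G)
    w = theta["coef"] * E
    c = np.einsum("psj,pj->ps", G, w)
    return fam.link(bias + c)


def _members(res):
    """Ensemble members, or the single result itself."""
    return getattr(res, "members", [res])


def _effect_draws(res, target_ix, d, t0, x_query, x_ref, n_mc, seed):
    """Draw-wise effects: linked(query) - linked(reference), per grid point."""
    members = _members(res)
    all_draws = []
    for mi, m in enumerate(members):
        stochastic = m.ffspec is not None and m.config.dropout > 0
        if stochastic:
            seeds = m.posterior_sample(n_mc, None if seed is None else seed + 7919 * mi)
        else:
            seeds = [None]
        for s in seeds:
            lq = linked_single_event(m, d, t0, x_query, draw_seed=s)
            lr = linked_single_event(m, d, t0, x_ref, draw_seed=s)
            all_draws.append(lq[:, target_ix] - lr[:, target_ix])
    return np.asarray(all_draws)


def _resolve_reference(res, reference_point):
    if reference_point is None:
        return res.stz.x_mean.copy()
    ref = np.asarray(reference_point, dtype=float)
    if ref.shape != res.stz.x_mean.shape:
        raise ValueError("reference point has wrong length")
    return ref


def _resolve_value(res, predictor, value, ref):
    """Raw predictor value for the query; '+1sd' means reference + 1 train SD."""
    k = res.spec.predictors.index(predictor)
    if isinstance(value, str):
        if value != "+1sd":
            raise ValueError(f"unknown predictor value spec {value!r}")
        return ref[k] + res.stz.x_std[k]
    return float(value)


def _default_onset(res):
    return res.stz.t_mean


def _default_delay_grid(res):
    return np.linspace(0.0, min(res.spec.d_max, 1.0) if res.spec.d_max <= 10.0 else 30.0, 201)


def _default_predictor_grid(res, predictor, n=21):
    k = res.spec.predictors.index(predictor)
    m, s = res.stz.x_mean[k], res.stz.x_std[k]
    return np.linspace(m - 2.5 * s, m + 2.5 * s, n)


def _band_result(grid, draws, level, target_param, predictors, shape=None):
    est = draws.mean(axis=0)
    lo, hi = credible_band(draws, level)
    # the mean of draws is the point estimate; keep it inside the band
    lo = np.minimum(lo, est)
    hi = np.maximum(hi, est)
    if shape is not None:
        est, lo, hi = est.reshape(shape), lo.reshape(shape), hi.reshape(shape)
    return EffectQueryResult(
        grid=grid, estimate=est, lower=lo, upper=hi,
        target_param=target_param, predictors=predictors, draws=draws,
    )


# ---------------------------------------------------------------------------
# query operations


def irf_curve(
    res,
    predictor,
    target_param="mu",
    delay_grid=None,
    value="+1sd",
    reference_point=None,
    onset_time=None,
    n_mc=100,
    level=0.95,
    seed=None,
):
    """Estimated change in a distribution parameter from one event, by delay.

    For each delay ``d`` on the grid, compares a single event whose queried
    predictor is at ``value`` (default: one training-set SD above the
    reference) against the same event at the reference point, all other
    predictors held at reference. ``predictor="rate"`` compares an event at
    the reference against no event at all — the baseline response evoked by
    any event.
    """
    _check_predictor(res, predictor)
    target_ix = _param_index(_members(res)[0], target_param)
    m0 = _members(res)[0]
    d = np.asarray(delay_grid if delay_grid is not None else _default_delay_grid(m0), float)
    t0 = _default_onset(m0) if onset_time is None else float(onset_time)
    ref = _resolve_reference(m0, reference_point)
    if predictor == RATE:
        x_query, x_ref = ref[None, :], None
    else:
        q = ref.copy()
        k = m0.spec.predictors.index(predictor)
        q[k] = _resolve_value(m0, predictor, value, ref)
        x_query, x_ref = q[None, :], ref[None, :]
    draws = _effect_draws(res, target_ix, d, t0, x_query, x_ref, n_mc, seed)
    return _band_result(
        {"delay": d}, draws, level, target_param, (predictor,)
    )


def effect_surface(
    res,
    predictor,
    target_param="mu",
    predictor_grid=None,
    delay_grid=None,
    reference_point=None,
    onset_time=None,
    n_mc=100,
    level=0.95,
    seed=None,
):
    """Change in a distribution parameter over predictor value x delay.

    Computed column-by-column (one delay sweep per predictor value) so that a
    slice of the surface at a value equals :func:`irf_curve` at that value.
    """
    _check_predictor(res, predictor)
    if predictor == RATE:
        raise ValueError("surfaces require a named predictor; use irf_curve for rate")
    m0 = _members(res)[0]
    pg = np.asarray(
        predictor_grid if predictor_grid is not None else _default_predictor_grid(m0, predictor),
        float,
    )
    d = np.asarray(delay_grid if delay_grid is not None else _default_delay_grid(m0), float)
    cols = []
    for v in pg:
        r = irf_curve(
            res, predictor, target_param=target_param, delay_grid=d, value=float(v),
            reference_point=reference_point, onset_time=onset_time,
            n_mc=n_mc, level=level, seed=seed,
        )
        cols.append(r.draws)
    draws = np.stack(cols, axis=1)  # (n_draws, n_pg, n_d)
    draws = draws.reshape(draws.shape[0], -1)
    return _band_result(
        {predictor: pg, "delay": d}, draws, level, target_param, (predictor,),
        shape=(len(pg), len(d)),
    )


def functional_form_slice(
    res,
    predictor,
    fixed_delay=5.0,
    target_param="mu",
    predictor_grid=None,
    reference_point=None,
    onset_time=None,
    n_mc=100,
    level=0.95,
    seed=None,
):
    """Effect as a function of predictor value at a fixed delay."""
    _check_predictor(res, predictor)
    if predictor == RATE:
        raise ValueError("functional form requires a named predictor")
    m0 = _members(res)[0]
    target_ix = _param_index(m0, target_param)
    pg = np.asarray(
        predictor_grid if predictor_grid is not None else _default_predictor_grid(m0, predictor),
        float,
    )
    ref = _resolve_reference(m0, reference_point)
    k = m0.spec.predictors.index(predictor)
    Xq = np.tile(ref, (len(pg), 1))
    Xq[:, k] = pg
    d = np.full(len(pg), float(fixed_delay))
    t0 = _default_onset(m0) if onset_time is None else float(onset_time)
    draws = _effect_draws(res, target_ix, d, t0, Xq, np.tile(ref, (len(pg), 1)), n_mc, seed)
    return _band_result({predictor: pg}, draws, level, target_param, (predictor,))


def interaction_surface(
    res,
    predictor_a,
    predictor_b,
    fixed_delay=5.0,
    target_param="mu",
    grid_a=None,
    grid_b=None,
    reference_point=None,
    onset_time=None,
    n_mc=100,
    level=0.95,
    seed=None,
):
    """Joint effect over a grid of two predictors at a fixed delay.

    All other predictors are held at the reference; the value at
    (reference, reference) is zero by construction. The interaction residual
    is the surface minus the sum of the two marginal slices.
    """
    for p in (predictor_a, predictor_b):
        _check_predictor(res, p)
        if p == RATE:
            raise ValueError("interactions require named predictors")
    m0 = _members(res)[0]
    target_ix = _param_index(m0, target_param)
    ga = np.asarray(grid_a if grid_a is not None else _default_predictor_grid(m0, predictor_a), float)
    gb = np.asarray(grid_b if grid_b is not None else _default_predictor_grid(m0, predictor_b), float)
    ref = _resolve_reference(m0, reference_point)
    ka = m0.spec.predictors.index(predictor_a)
    kb = m0.spec.predictors.index(predictor_b)
    A, B = np.meshgrid(ga, gb, indexing="ij")
    n = A.size
    Xq = np.tile(ref, (n, 1))
    Xq[:, ka] = A.ravel()
    Xq[:, kb] = B.ravel()
    d = np.full(n, float(fixed_delay))
    t0 = _default_onset(m0) if onset_time is None else float(onset_time)
    draws = _effect_draws(res, target_ix, d, t0, Xq, np.tile(ref, (n, 1)), n_mc, seed)
    return _band_result(
        {predictor_a: ga, predictor_b: gb}, draws, level, target_param,
        (predictor_a, predictor_b), shape=(len(ga), len(gb)),
    )


def sigma_irf(res, predictor, **kw):
    """Impulse response of the scale parameter sigma (heteroscedasticity)."""
    kw.setdefault("target_param", "sigma")
    return irf_curve(res, predictor, **kw)


def nonstationarity_curve(
    res,
    predictor,
    fixed_delay=5.0,
    onset_grid=None,
    target_param="mu",
    value="+1sd",
    reference_point=None,
    n_mc=100,
    level=0.95,
    seed=None,
):
    """Effect of a predictor at a fixed delay, as a function of its onset time."""
    _check_predictor(res, predictor)
    m0 = _members(res)[0]
    target_ix = _param_index(m0, target_param)
    if onset_grid is None:
        lo = m0.stz.t_mean - 2.0 * m0.stz.t_std
        hi = m0.stz.t_mean + 2.0 * m0.stz.t_std
        onset_grid = np.linspace(max(lo, 0.0), hi, 51)
    onset_grid = np.asarray(onset_grid, dtype=float)
    ref = _resolve_reference(m0, reference_point)
    if predictor == RATE:
        x_query, x_ref = ref[None, :], None
    else:
        q = ref.copy()
        k = m0.spec.predictors.index(predictor)
        q[k] = _resolve_value(m0, predictor, value, ref)
        x_query, x_ref = q[None, :], ref[None, :]
    d = np.full(len(onset_grid), float(fixed_delay))
    draws = _effect_draws(res, target_ix, d, onset_grid, x_query, x_ref, n_mc, seed)
    return _band_result({"onset": onset_grid}, draws, level, target_param, (predictor,))
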
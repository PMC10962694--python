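"""Continuous-time deconvolutional regression with a neural impulse response.

The model maps a history of timestamped predictor vectors onto all parameters
of the response distribution at a query time ``tau``. For each event ``n``
with delay ``d_n = tau - t_n``, a feedforward impulse-response network maps
``[d_n; t_n; x_n]`` to a convolution-weight matrix ``G_n`` of shape
``S x (J+1)``; the response-distribution parameters are

    s = s0 + sum_n G_n diag(b) [1; x'_n]

where ``b`` is a coefficient vector whose leading slot weights a constant
*rate* bias (the "deconvolutional intercept": the baseline response evoked by
any event regardless of its properties), and ``s0`` is an ordinary intercept.
Random effects add zero-centered per-level deviations to ``b`` and ``s0``.

Usage follows the statsmodels convention: build a :class:`CDRNN` from an
event table and a response table, call :meth:`CDRNN.fit`, and work with the
returned :class:`~cdrnn.results.CDRNNResults`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import data as _data
from .families import get_family
from .nn import Adam, FeedforwardSpec, ffn_backward, ffn_forward, init_ffn, sample_dropout_masks
from .training import TrainConfig, FitDiagnostics, check_convergence


@dataclass(frozen=True)
class ModelSpec:
    """Architecture and constraint flags for one model.

    Parameters
    ----------
    predictors : tuple of str
        Predictor columns of the event table entering the model.
    response : str
        Response column of the response table.
    groups : tuple of str
        Random-effects grouping columns (e.g. participant).
    hidden : tuple of int
        Hidden-layer widths of the impulse-response network.
    activation : str
        Hidden activation; the output layer is always identity.
    f_in : str
        Input transform; only ``"identity"`` is supported for fitting
        (impulses equal predictors, J = K).
    causal : bool
        Force the impulse response to zero for negative delays (future
        events); on by default, with delay 0 included in the past.
    nonstationary : bool
        Feed the event timestamp ``t_n`` to the impulse-response network,
        letting effects drift over absolute time.
    heteroscedastic : bool
        Let events move non-location distribution parameters (e.g. sigma);
        when off, sigma is a single free constant from ``s0``.
    nonlinear : tuple of str or None
        Predictors fed to the impulse-response network (nonlinear effects);
        ``None`` means all. A predictor absent here but present in
        ``predictors`` still enters the convolution product, so its effect is
        linear in its value.
    dirac : bool
        Replace the network by an indicator on ``d = 0`` (discrete-time
        reduction); with identity input transform the model family collapses
        to linear regression.
    d_max : float
        History window in seconds: events with ``0 <= d <= d_max`` enter the
        convolution (symmetric window when ``causal`` is off). Must be large
        enough that kernel mass beyond it is negligible.
    family : str
        Response family name (``"normal"``).
    weight_penalty, ranef_penalty : float
        L2 penalty strengths on network weights and on random-effect
        deviations.
    ranef_coef, ranef_bias : bool
        Whether random effects apply to the coefficient vector ``b`` and to
        the intercept ``s0``.
    """

    predictors: tuple
    response: str = "y"
    groups: tuple = ()
    hidden: tuple = (32, 32)
    activation: str = "tanh"
    f_in: str = "identity"
    causal: bool = True
    nonstationary: bool = True
    heteroscedastic: bool = True
    nonlinear: tuple = None
    dirac: bool = False
    d_max: float = 10.0
    family: str = "normal"
    weight_penalty: float = 0.01
    ranef_penalty: float = 1.0
    ranef_coef: bool = True
    ranef_bias: bool = True

    def __post_init__(self):
        object.__setattr__(self, "predictors", tuple(self.predictors))
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(self, "hidden", tuple(self.hidden))
        if self.nonlinear is not None:
            unknown = set(self.nonlinear) - set(self.predictors)
            if unknown:
                raise ValueError(f"nonlinear names unknown predictors: {sorted(unknown)}")
            object.__setattr__(self, "nonlinear", tuple(self.nonlinear))
        if self.f_in not in ("identity", "feedforward"):
            raise ValueError(f"unknown f_in mode {self.f_in!r}")

    def replace(self, **kw) -> "ModelSpec":
        return dataclasses.replace(self, **kw)

    @property
    def nonlinear_set(self) -> tuple:
        return self.predictors if self.nonlinear is None else self.nonlinear

    def irf_input_names(self) -> tuple:
        """Ordered inputs of the impulse-response network."""
        names = ["d"]
        if self.nonstationary:
            names.append("t")
        names.extend(p for p in self.predictors if p in self.nonlinear_set)
        return tuple(names)


@dataclass
class Standardization:
    """Training-set statistics used to standardize network inputs."""

    x_mean: np.ndarray
    x_std: np.ndarray
    d_mean: float
    d_std: float
    t_mean: float
    t_std: float

    def std_x(self, X):
        return (np.asarray(X, dtype=float) - self.x_mean) / self.x_std

    def std_d(self, d):
        return (np.asarray(d, dtype=float) - self.d_mean) / self.d_std

    def std_t(self, t):
        return (np.asarray(t, dtype=float) - self.t_mean) / self.t_std


@dataclass
class Design:
    """Flattened (response sample, event) pair arrays for the engine.

    Pairs are grouped by sample: pairs of sample ``m`` occupy
    ``offsets[m]:offsets[m+1]``. ``U`` holds standardized impulse-response
    network inputs, ``E`` the rate-augmented standardized impulses
    ``[1; x']``, and ``zidx[factor]`` the random-effects level index per
    sample (-1 for unknown levels, which fall back to the population).
    """

    U: np.ndarray
    E: np.ndarray
    d_raw: np.ndarray
    sample_idx: np.ndarray
    offsets: np.ndarray
    y: np.ndarray
    zidx: dict
    tau: np.ndarray

    @property
    def M(self) -> int:
        return self.y.shape[0]

    @property
    def P(self) -> int:
        return self.d_raw.shape[0]

    def subset(self, ids: np.ndarray) -> "Design":
        ids = np.asarray(ids, dtype=int)
        starts = self.offsets[ids]
        lens = self.offsets[ids + 1] - starts
        total = int(lens.sum())
        if total:
            csum = np.concatenate([[0], np.cumsum(lens)])
            pair_ix = np.arange(total) - np.repeat(csum[:-1], lens) + np.repeat(starts, lens)
            new_sample_idx = np.repeat(np.arange(len(ids)), lens)
        else:
            pair_ix = np.empty(0, dtype=int)
            new_sample_idx = np.empty(0, dtype=int)
        csum = np.concatenate([[0], np.cumsum(lens)])
        return Design(
            U=self.U[pair_ix] if self.U is not None else None,
            E=self.E[pair_ix],
            d_raw=self.d_raw[pair_ix],
            sample_idx=new_sample_idx,
            offsets=csum.astype(int),
            y=self.y[ids],
            zidx={f: z[ids] for f, z in self.zidx.items()},
            tau=self.tau[ids],
        )


def build_design(
    events: pd.DataFrame,
    responses: pd.DataFrame,
    spec: ModelSpec,
    stz: Standardization,
    level_maps: dict,
    series_col: str = "series_id",
    time_col: str = "time",
) -> Design:
    """Assemble the pair arrays linking each response to its event history."""
    preds = list(spec.predictors)
    _data._require_columns(events, [series_col, time_col] + preds, "event")
    need = [series_col, time_col, spec.response] + list(spec.groups)
    _data._require_columns(responses, need, "response")

    ev_by_series = {}
    for sid, grp in events.groupby(series_col, sort=False):
        grp = grp.sort_values(time_col, kind="stable")
        ev_by_series[sid] = (
            grp[time_col].to_numpy(dtype=float),
            grp[preds].to_numpy(dtype=float),
        )

    d_parts, t_parts, x_parts, lens = [], [], [], []
    lo_d = 0.0 if spec.causal else -spec.d_max
    tau_all = responses[time_col].to_numpy(dtype=float)
    sid_all = responses[series_col].to_numpy()
    for tau, sid in zip(tau_all, sid_all):
        ev = ev_by_series.get(sid)
        if ev is None:
            lens.append(0)
            continue
        t_ev, X_ev = ev
        # events with lo_d <= tau - t <= d_max, i.e. tau - d_max <= t <= tau - lo_d
        i0 = np.searchsorted(t_ev, tau - spec.d_max, side="left")
        i1 = np.searchsorted(t_ev, tau - lo_d, side="right")
        lens.append(i1 - i0)
        if i1 > i0:
            d_parts.append(tau - t_ev[i0:i1])
            t_parts.append(t_ev[i0:i1])
            x_parts.append(X_ev[i0:i1])

    lens = np.asarray(lens, dtype=int)
    offsets = np.concatenate([[0], np.cumsum(lens)]).astype(int)
    if offsets[-1]:
        d_raw = np.concatenate(d_parts)
        t_raw = np.concatenate(t_parts)
        X_raw = np.vstack(x_parts)
    else:
        d_raw = np.empty(0)
        t_raw = np.empty(0)
        X_raw = np.empty((0, len(preds)))
    sample_idx = np.repeat(np.arange(len(lens)), lens)

    X_std = stz.std_x(X_raw)
    cols = [stz.std_d(d_raw)[:, None]]
    if spec.nonstationary:
        cols.append(stz.std_t(t_raw)[:, None])
    nl_ix = [i for i, p in enumerate(preds) if p in spec.nonlinear_set]
    if nl_ix:
        cols.append(X_std[:, nl_ix])
    U = np.hstack(cols) if not spec.dirac else None
    E = np.hstack([np.ones((X_std.shape[0], 1)), X_std])

    zidx = {}
    for f in spec.groups:
        lm = level_maps.get(f, {})
        zidx[f] = responses[f].map(lambda v: lm.get(v, -1)).to_numpy(dtype=int)

    return Design(
        U=U,
        E=E,
        d_raw=d_raw,
        sample_idx=sample_idx,
        offsets=offsets,
        y=responses[spec.response].to_numpy(dtype=float),
        zidx=zidx,
        tau=tau_all,
    )


# ---------------------------------------------------------------------------
# engine


def ffspec_for(spec: ModelSpec, family=None) -> FeedforwardSpec | None:
    if spec.dirac:
        return None
    fam = get_family(spec.family) if family is None else family
    S = fam.n_params
    J1 = len(spec.predictors) + 1
    return FeedforwardSpec(
        input_dim=len(spec.irf_input_names()),
        widths=tuple(spec.hidden) + (S * J1,),
        activations=(spec.activation,) * len(spec.hidden) + ("identity",),
    )


def output_mask(spec: ModelSpec, S: int, J1: int) -> np.ndarray:
    mask = np.ones((S, J1))
    if not spec.heteroscedastic:
        mask[1:, :] = 0.0
    return mask


def _mlp_params(theta: dict, ffspec: FeedforwardSpec):
    return [(theta[f"W{l}"], theta[f"b{l}"]) for l in range(ffspec.n_layers)]


def _per_sample(theta: dict, spec: ModelSpec, design: Design, what: str) -> np.ndarray:
    """Effective per-sample coefficient (``coef``) or intercept (``bias``).

    Under the homoscedastic constraint, random effects may not touch the
    non-location components of ``s0``: the scale is a single shared constant.
    """
    base = theta[what]
    out = np.tile(base, (design.M, 1))
    prefix = "rc:" if what == "coef" else "rb:"
    for f in spec.groups:
        key = prefix + f
        if key not in theta:
            continue
        z = design.zidx[f]
        valid = z >= 0
        if valid.any():
            out[valid] += theta[key][z[valid]]
    if what == "bias" and not spec.heteroscedastic and out.shape[1] > 1:
        out[:, 1:] = base[1:]
    return out


def forward(theta, spec, ffspec, family, design, masks=None, want_cache=False):
    """Forward pass: raw response-distribution parameters per sample.

    Returns ``(s_raw, aux)``; ``aux`` carries intermediates for backprop when
    ``want_cache`` is set.
    """
    S = family.n_params
    J1 = design.E.shape[1]
    if spec.dirac:
        ind = (np.abs(design.d_raw) < 1e-9).astype(float)
        G = ind[:, None, None] * np.ones((1, S, J1))
        cache = None
    else:
        out, cache = ffn_forward(ffspec, _mlp_params(theta, ffspec), design.U, masks)
        G = out.reshape(-1, S, J1)
    omask = output_mask(spec, S, J1)
    G = G * omask
    if spec.causal and design.P:
        G[design.d_raw < 0] = 0.0
    b_m = _per_sample(theta, spec, design, "coef")
    w = b_m[design.sample_idx] * design.E
    c = np.einsum("psj,pj->ps", G, w)
    s_raw = _per_sample(theta, spec, design, "bias")
    for j in range(S):
        s_raw[:, j] += np.bincount(design.sample_idx, weights=c[:, j], minlength=design.M)
    aux = {"G": G, "w": w, "b_m": b_m, "cache": cache, "omask": omask} if want_cache else None
    return s_raw, aux


def penalty_value(theta, spec, ffspec) -> float:
    pen = 0.0
    if ffspec is not None:
        for l in range(ffspec.n_layers):
            pen += spec.weight_penalty * float(np.sum(theta[f"W{l}"] ** 2))
    for k, v in theta.items():
        if k.startswith(("rc:", "rb:")):
            pen += spec.ranef_penalty * float(np.sum(v**2))
    return pen


def backward(theta, spec, ffspec, family, design, aux, ds_raw, pen_scale):
    """Gradients of (mean NLL + scaled penalties) for all parameters.

    ``ds_raw`` is the gradient of the data term with respect to the raw
    distribution parameters (already scaled by 1/batch size); ``pen_scale``
    scales the penalty gradients (1/total training samples).
    """
    grads = {}
    G, w, b_m, cache, omask = aux["G"], aux["w"], aux["b_m"], aux["cache"], aux["omask"]
    dc = ds_raw[design.sample_idx]  # (P, S)

    if not spec.dirac:
        dG = dc[:, :, None] * w[:, None, :]
        dG = dG * omask
        if spec.causal and design.P:
            dG[design.d_raw < 0] = 0.0
        mlp_grads, _ = ffn_backward(
            ffspec, _mlp_params(theta, ffspec), cache, dG.reshape(design.P, -1)
        )
        for l, (gW, gb) in enumerate(mlp_grads):
            grads[f"W{l}"] = gW + pen_scale * 2.0 * spec.weight_penalty * theta[f"W{l}"]
            grads[f"b{l}"] = gb

    dw = np.einsum("psj,ps->pj", G, dc)
    db_pair = dw * design.E  # (P, J+1) gradient wrt per-sample coefficient
    J1 = design.E.shape[1]
    db_m = np.zeros((design.M, J1))
    for j in range(J1):
        db_m[:, j] = np.bincount(
            design.sample_idx, weights=db_pair[:, j], minlength=design.M
        )
    grads["coef"] = db_m.sum(axis=0)
    grads["bias"] = ds_raw.sum(axis=0)

    for f in spec.groups:
        z = design.zidx[f]
        valid = z >= 0
        if "rc:" + f in theta:
            g = np.zeros_like(theta["rc:" + f])
            if valid.any():
                np.add.at(g, z[valid], db_m[valid])
            grads["rc:" + f] = g + pen_scale * 2.0 * spec.ranef_penalty * theta["rc:" + f]
        if "rb:" + f in theta:
            g = np.zeros_like(theta["rb:" + f])
            ds_b = ds_raw
            if not spec.heteroscedastic and ds_raw.shape[1] > 1:
                ds_b = ds_raw.copy()
                ds_b[:, 1:] = 0.0
            if valid.any():
                np.add.at(g, z[valid], ds_b[valid])
            grads["rb:" + f] = g + pen_scale * 2.0 * spec.ranef_penalty * theta["rb:" + f]
    return grads


def project_ranef(theta: dict) -> None:
    """Hard zero-sum projection of random-effect deviations across levels."""
    for k, v in theta.items():
        if k.startswith(("rc:", "rb:")):
            v -= v.mean(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# spec-facing single-instance operations


def input_transform(events: _data.EventSeries, params=None, mode="identity", ffspec=None):
    """Map predictors to impulses.

    Identity mode returns ``X`` unchanged (J = K). Feedforward mode applies a
    feedforward stack row-wise to ``[t_n; x_n]``.
    """
    if mode == "identity":
        return events.X
    if mode != "feedforward":
        raise ValueError(f"unknown f_in mode {mode!r}")
    if ffspec is None or params is None:
        raise ValueError("feedforward input transform needs ffspec and params")
    inp = np.column_stack([events.t, events.X])
    out, _ = ffn_forward(ffspec, params, inp)
    return out


def irf_apply(
    d_n: float,
    t_n: float,
    xp_n: np.ndarray,
    theta: dict,
    spec: ModelSpec,
    ffspec: FeedforwardSpec,
    family=None,
) -> np.ndarray:
    """Evaluate the impulse-response network for one (delay, time, impulse).

    ``xp_n`` must already be standardized; inputs excluded by constraints
    (timestamps under stationarity, impulses under linearity) are dropped.
    Returns the ``S x (J+1)`` convolution-weight matrix, zero under causal
    masking when the delay is negative.
    """
    fam = get_family(spec.family) if family is None else family
    S = fam.n_params
    J1 = len(spec.predictors) + 1
    names = spec.irf_input_names()
    xp_n = np.atleast_1d(np.asarray(xp_n, dtype=float))
    if len(xp_n) != len(spec.predictors):
        raise ValueError("impulse vector length does not match predictors")
    vals = {"d": d_n, "t": t_n}
    for i, p in enumerate(spec.predictors):
        vals[p] = xp_n[i]
    u = np.array([vals[n] for n in names], dtype=float)
    out, _ = ffn_forward(ffspec, _mlp_params(theta, ffspec), u[None, :])
    G = out.reshape(S, J1) * output_mask(spec, S, J1)
    if spec.causal and d_n < 0:
        G = np.zeros_like(G)
    return G


def convolve(s0: np.ndarray, b: np.ndarray, G_seq, Xp: np.ndarray) -> np.ndarray:
    """Temporal convolution read-out: ``s = s0 + sum_n G_n diag(b) [1; x'_n]``.

    Contributions across events are strictly additive; an empty sequence
    returns ``s0``.
    """
    s0 = np.asarray(s0, dtype=float)
    b = np.asarray(b, dtype=float)
    Xp = np.atleast_2d(np.asarray(Xp, dtype=float)) if len(G_seq) else np.empty((0, b.size - 1))
    s = s0.astype(float).copy()
    for n, G in enumerate(G_seq):
        G = np.asarray(G, dtype=float)
        e = np.concatenate([[1.0], Xp[n]])
        if G.shape != (s0.size, b.size) or e.size != b.size:
            raise ValueError(f"shape mismatch in convolution at event {n}")
        s = s + G @ (b * e)
    return s


# ---------------------------------------------------------------------------
# the model object


class CDRNN:
    """Continuous-time deconvolutional regression model (unfitted).

    Parameters
    ----------
    events : DataFrame
        Event table (series id, time, predictor columns).
    responses : DataFrame
        Response table (series id, time, response column, grouping columns,
        optionally a ``partition`` column with train/exploratory/test labels).
    spec : ModelSpec
    series_col, time_col : str
        Column names shared by both tables.

    When a ``partition`` column is present, standardization statistics,
    random-effects levels and the fitting objective use the training rows
    only; otherwise all rows are treated as training data.
    """

    def __init__(
        self,
        events: pd.DataFrame,
        responses: pd.DataFrame,
        spec: ModelSpec,
        series_col: str = "series_id",
        time_col: str = "time",
    ):
        if spec.f_in != "identity":
            raise NotImplementedError(
                "fitting supports the identity input transform only"
            )
        self.spec = spec
        self.family = get_family(spec.family)
        self.series_col = series_col
        self.time_col = time_col
        self.events = events
        self.responses = responses

        if "partition" in responses.columns:
            train = responses.loc[responses["partition"] == _data.TRAIN]
            if not len(train):
                raise ValueError("training partition is empty")
        else:
            train = responses
        self.train_responses = train

        self.level_maps = {
            f: {v: i for i, v in enumerate(pd.unique(train[f]))} for f in spec.groups
        }

        preds = list(spec.predictors)
        X = events[preds].to_numpy(dtype=float)
        x_std = X.std(axis=0)
        x_std[x_std == 0] = 1.0
        # provisional pass to get delay/time statistics from training pairs
        prov = Standardization(
            x_mean=X.mean(axis=0), x_std=x_std, d_mean=0.0, d_std=1.0, t_mean=0.0, t_std=1.0
        )
        d0 = build_design(
            events, train, spec, prov, self.level_maps, series_col, time_col
        )
        if d0.P:
            t_raw = d0.tau[d0.sample_idx] - d0.d_raw
            d_std = float(d0.d_raw.std()) or 1.0
            t_sd = float(t_raw.std()) or 1.0
            self.stz = Standardization(
                x_mean=prov.x_mean,
                x_std=prov.x_std,
                d_mean=float(d0.d_raw.mean()),
                d_std=d_std,
                t_mean=float(t_raw.mean()),
                t_std=t_sd,
            )
        else:
            self.stz = prov
        self.train_design = build_design(
            events, train, spec, self.stz, self.level_maps, series_col, time_col
        )
        self.ffspec = ffspec_for(spec, self.family)

    @classmethod
    def from_dataframes(cls, events, responses, **kw) -> "CDRNN":
        return cls(events, responses, **kw)

    # -- fitting ------------------------------------------------------------

    def _init_theta(self, rng: np.random.Generator) -> dict:
        spec = self.spec
        S = self.family.n_params
        J1 = len(spec.predictors) + 1
        theta: dict = {}
        if self.ffspec is not None:
            for l, (W, b) in enumerate(init_ffn(self.ffspec, rng, out_scale=0.1)):
                theta[f"W{l}"] = W
                theta[f"b{l}"] = b
        theta["coef"] = np.ones(J1)
        theta["bias"] = self.family.init_raw(self.train_design.y)
        for f in spec.groups:
            n_lev = len(self.level_maps[f])
            if spec.ranef_coef:
                theta["rc:" + f] = np.zeros((n_lev, J1))
            if spec.ranef_bias:
                theta["rb:" + f] = np.zeros((n_lev, S))
        return theta

    def loglik(self, theta: dict, design: Design | None = None) -> float:
        """Deterministic mean log likelihood per sample (dropout off)."""
        design = self.train_design if design is None else design
        s_raw, _ = forward(theta, self.spec, self.ffspec, self.family, design)
        linked = self.family.link(s_raw)
        return float(self.family.loglik(design.y, linked).mean())

    def fit(self, config: TrainConfig | None = None, verbose: bool = False):
        """Fit by Adam on the penalized negative log likelihood.

        Dropout is active during training (the variational approximation);
        random-effect deviations are re-projected to zero sum each epoch.
        Training stops at ``max_epochs`` or when the time-loss criterion
        declares convergence. Deterministic given ``config.seed``.
        """
        from .results import CDRNNResults  # local import to avoid a cycle

        config = TrainConfig() if config is None else config
        design = self.train_design
        if design.M == 0:
            raise ValueError("training partition is empty")
        rng = np.random.default_rng(config.seed)
        theta = self._init_theta(rng)
        adam = Adam(lr=config.learning_rate)
        M = design.M

        metric_design = design
        if config.convergence.eval_metric == "exploratory_loglik":
            expl = self.responses.loc[self.responses.get("partition") == _data.EXPLORATORY]
            if not len(expl):
                raise ValueError("exploratory metric requested but partition is empty")
            metric_design = build_design(
                self.events, expl, self.spec, self.stz, self.level_maps,
                self.series_col, self.time_col,
            )

        history: list = []
        converged_at = None
        best_metric = -np.inf
        best_theta = None
        for epoch in range(1, config.max_epochs + 1):
            if config.lr_decay != 1.0:
                adam.lr = config.learning_rate * config.lr_decay ** (epoch - 1)
            perm = rng.permutation(M)
            for lo in range(0, M, config.batch_size):
                ids = perm[lo : lo + config.batch_size]
                batch = design.subset(ids) if len(ids) < M else design
                masks = None
                if self.ffspec is not None and config.dropout > 0:
                    masks = sample_dropout_masks(
                        self.ffspec, config.dropout, batch.P, rng
                    )
                s_raw, aux = forward(
                    theta, self.spec, self.ffspec, self.family, batch,
                    masks=masks, want_cache=True,
                )
                nll, ds = self.family.nll_grad(batch.y, s_raw)
                obj = nll.mean() + penalty_value(theta, self.spec, self.ffspec) / M
                if not np.isfinite(obj):
                    raise FloatingPointError(
                        f"non-finite objective at epoch {epoch}; "
                        "consider lowering the learning rate"
                    )
                grads = backward(
                    theta, self.spec, self.ffspec, self.family, batch, aux,
                    ds / len(ids), 1.0 / M,
                )
                adam.step(theta, grads)
            project_ranef(theta)

            if epoch % config.convergence.eval_interval == 0:
                metric = self.loglik(theta, metric_design)
                history.append(metric)
                if config.restore_best and metric > best_metric:
                    best_metric = metric
                    best_theta = {k: v.copy() for k, v in theta.items()}
                conv, _diag = check_convergence(
                    history, alpha=config.convergence.alpha,
                    window=config.convergence.window,
                )
                if verbose and epoch % 50 == 0:
                    print(f"epoch {epoch}: metric {metric:.5f}")
                if conv:
                    converged_at = epoch
                    break

        if config.restore_best and best_theta is not None:
            theta = best_theta
        final_obj = -self.loglik(theta) * M + penalty_value(theta, self.spec, self.ffspec)
        diagnostics = FitDiagnostics(
            metric_history=list(history),
            convergence_epoch=converged_at,
            final_objective=float(final_obj),
            seed=config.seed,
        )
        return CDRNNResults(
            spec=self.spec,
            config=config,
            theta=theta,
            stz=self.stz,
            level_maps=self.level_maps,
            diagnostics=diagnostics,
            series_col=self.series_col,
            time_col=self.time_col,
        )
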
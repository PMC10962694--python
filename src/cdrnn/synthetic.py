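"""Ground-truth data generator for variably spaced event streams.

Events arrive at fixed or exponentially spaced intervals and carry
standard-normal predictor values. The response mean is the superposition of
known continuous-time kernels:

    mu(tau) = intercept + participant deviation
              + sum_n [ rate_kernel(d_n) + sum_k a_k(...) * x_nk ] * m(t_n)

with ``d_n = tau - t_n``, an optional nonstationary gain ``m(t)`` (a linear
ramp over the series), and noise ``y ~ Normal(mu, sigma(tau))``. The scale
can be heteroscedastic: ``log sigma(tau)`` receives its own convolution of
the predictors, ``sigma(tau) = sigma0 * exp(sum_n sum_k gamma_k * x_nk *
kernel_k(d_n))``, so the generating process matches the distributional
regression the model family is designed to recover. Response samples are
either event-aligned (one per event, reading-like) or on a fixed grid
(fMRI-like, e.g. every 2 s). The generator records the exact mean and scale
of every sample, which gives the best attainable log likelihood on the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st


class Kernel:
    """A continuous-time response kernel: evaluable at any delay, zero for d < 0."""

    def __call__(self, d):
        d = np.asarray(d, dtype=float)
        out = np.where(d >= 0, self._value(np.maximum(d, 0.0)), 0.0)
        return out


@dataclass
class ExponentialKernel(Kernel):
    """``a * exp(-lam * d)`` for d >= 0."""

    a: float = 1.0
    lam: float = 1.0

    def _value(self, d):
        return self.a * np.exp(-self.lam * d)


@dataclass
class DoubleGammaKernel(Kernel):
    """HRF-like difference of two gamma densities.

    ``A * (gamma_pdf(d; a1, b1) - c * gamma_pdf(d; a2, b2))``, with the
    widely used canonical shape as default: peak near 5 s, undershoot around
    15 s with relative amplitude ``c = 1/6``.
    """

    A: float = 1.0
    a1: float = 6.0
    b1: float = 1.0
    a2: float = 16.0
    b2: float = 1.0
    c: float = 1.0 / 6.0

    def _value(self, d):
        g1 = _st.gamma.pdf(d, self.a1, scale=1.0 / self.b1)
        g2 = _st.gamma.pdf(d, self.a2, scale=1.0 / self.b2)
        return self.A * (g1 - self.c * g2)


@dataclass
class DiracKernel(Kernel):
    """``a`` exactly at d = 0, zero elsewhere (discrete-time reduction)."""

    a: float = 1.0

    def _value(self, d):
        return np.where(np.abs(d) < 1e-9, self.a, 0.0)


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    ``spacing`` is ``("fixed", gap)`` or ``("exponential", mean_gap)``;
    ``sampling`` is ``("event",)`` (one response per event, reading-like) or
    ``("interval", dt)`` (fixed-interval, fMRI-like). ``hetero_gamma`` maps
    predictor names to the log-scale convolution gain; ``drift`` is the total
    fractional change of the nonstationary gain m(t) across the series
    (m ramps linearly from 1 to 1 + drift). ``ranef_sd`` is the SD of
    per-participant intercept deviations.
    """

    n_events: int = 2000
    n_participants: int = 4
    predictors: tuple = ("x1", "x2")
    spacing: tuple = ("exponential", 0.3)
    sampling: tuple = ("event",)
    intercept: float = 1.0
    sigma0: float = 1.0
    hetero_gamma: dict = field(default_factory=dict)
    drift: float = 0.0
    ranef_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be positive")
        if self.spacing[0] not in ("fixed", "exponential"):
            raise ValueError(f"unknown spacing model {self.spacing[0]!r}")
        if self.sampling[0] not in ("event", "interval"):
            raise ValueError(f"unknown sampling model {self.sampling[0]!r}")
        if self.spacing[1] <= 0 or (self.sampling[0] == "interval" and self.sampling[1] <= 0):
            raise ValueError("all scales must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


def generate_events(config: SimConfig) -> pd.DataFrame:
    """Timestamped standard-normal predictors, one series per participant."""
    rng = np.random.default_rng(config.seed)
    per = config.n_events // config.n_participants
    counts = [per] * config.n_participants
    counts[-1] += config.n_events - per * config.n_participants
    rows = []
    for p, n in enumerate(counts):
        if config.spacing[0] == "fixed":
            t = np.arange(n) * config.spacing[1]
        else:
            gaps = rng.exponential(config.spacing[1], size=n)
            t = np.concatenate([[0.0], np.cumsum(gaps[:-1])])
        X = rng.standard_normal((n, len(config.predictors)))
        df = pd.DataFrame(X, columns=list(config.predictors))
        df.insert(0, "time", t)
        df.insert(0, "series_id", f"p{p}")
        df.insert(0, "participant", f"p{p}")
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def generate_responses(
    events: pd.DataFrame, kernels: dict, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convolve events with the ground-truth kernels and add noise.

    ``kernels`` maps predictor names (and optionally ``"rate"``) to
    :class:`Kernel` objects. Returns ``(responses, truth)`` where the truth
    table records the exact mean and scale of every sample. Response times
    before the first event are allowed (pure intercept).
    """
    rng = np.random.default_rng(config.seed + 1)
    preds = list(config.predictors)
    unknown = set(kernels) - set(preds) - {"rate"}
    if unknown:
        raise ValueError(f"kernels reference unknown predictors: {sorted(unknown)}")
    resp_rows, truth_rows = [], []
    ranef = {}
    for i, p in enumerate(pd.unique(events["participant"])):
        ranef[p] = rng.normal(0.0, config.ranef_sd) if config.ranef_sd > 0 else 0.0
    for sid, grp in events.groupby("series_id", sort=False):
        grp = grp.sort_values("time", kind="stable")
        t_ev = grp["time"].to_numpy(dtype=float)
        X_ev = grp[preds].to_numpy(dtype=float)
        part = grp["participant"].iloc[0]
        T = t_ev[-1] if len(t_ev) else 0.0
        if config.sampling[0] == "event":
            tau = t_ev.copy()
        else:
            dt = config.sampling[1]
            tau = np.arange(0.0, T + dt, dt)
        # nonstationary gain at event onsets: linear ramp 1 .. 1 + drift
        m_t = 1.0 + config.drift * (t_ev / T if T > 0 else 0.0)
        D = tau[:, None] - t_ev[None, :]  # (n_tau, n_ev) signed delays
        mu = np.full(len(tau), config.intercept + ranef[part])
        log_sig = np.zeros(len(tau))
        if "rate" in kernels:
            mu = mu + (kernels["rate"](D) * m_t[None, :]).sum(axis=1)
        for k, p in enumerate(preds):
            if p in kernels:
                KD = kernels[p](D)
                mu = mu + (KD * (X_ev[:, k] * m_t)[None, :]).sum(axis=1)
                g = config.hetero_gamma.get(p, 0.0)
                if g:
                    log_sig = log_sig + g * (KD * X_ev[:, k][None, :]).sum(axis=1)
        sigma = config.sigma0 * np.exp(log_sig)
        y = rng.normal(mu, sigma)
        resp_rows.append(
            pd.DataFrame(
                {
                    "series_id": sid,
                    "participant": part,
                    "time": tau,
                    "y": y,
                }
            )
        )
        truth_rows.append(
            pd.DataFrame({"series_id": sid, "time": tau, "mu": mu, "sigma": sigma})
        )
    return pd.concat(resp_rows, ignore_index=True), pd.concat(truth_rows, ignore_index=True)


def oracle_loglik(responses: pd.DataFrame, truth: pd.DataFrame) -> np.ndarray:
    """Per-sample log likelihood under the generating distribution.

    This is the expected upper bound (within sampling noise) on any fitted
    model's likelihood on the same data.
    """
    mu = truth["mu"].to_numpy(dtype=float)
    sigma = truth["sigma"].to_numpy(dtype=float)
    y = responses["y"].to_numpy(dtype=float)
    z = (y - mu) / sigma
    return -0.5 * math.log(2.0 * math.pi) - np.log(sigma) - 0.5 * z * z


def true_irf(kernels: dict, name: str, d_grid, delta: float = 1.0) -> np.ndarray:
    """Ground-truth effect curve: change in mu from a ``delta`` increase."""
    d_grid = np.asarray(d_grid, dtype=float)
    if name not in kernels:
        return np.zeros_like(d_grid)
    return kernels[name](d_grid) * delta


QUICKSTART_SEED = 101

#: kernels generating the quickstart fixture: fast positive effect of x1,
#: slower negative effect of x2, and a small positive rate response.
QUICKSTART_KERNELS = {
    "x1": ExponentialKernel(a=1.0, lam=5.0),
    "x2": ExponentialKernel(a=-0.5, lam=2.0),
    "rate": ExponentialKernel(a=0.3, lam=5.0),
}


def quickstart_config(seed: int = QUICKSTART_SEED) -> SimConfig:
    return SimConfig(
        n_events=2000,
        n_participants=4,
        predictors=("x1", "x2"),
        spacing=("exponential", 0.3),
        sampling=("event",),
        intercept=1.0,
        sigma0=1.0,
        ranef_sd=0.2,
        seed=seed,
    )


def quickstart_fixture(seed: int = QUICKSTART_SEED):
    """Small deterministic dataset used across the tests and docs.

    Four participants, 2000 events with exponential spacing (mean 0.3 s),
    two standard-normal predictors convolved with exponential kernels,
    event-aligned responses, unit noise, and per-participant random
    intercepts. Returns ``(events, responses, truth, kernels, config)``;
    responses carry a chunk-cycled partition column (25-sample chunks).
    """
    from .data import PartitionConfig, partition_responses

    config = quickstart_config(seed)
    events = generate_events(config)
    responses, truth = generate_responses(events, QUICKSTART_KERNELS, config)
    responses = partition_responses(
        responses,
        PartitionConfig(scheme="chunk_cycle", chunk_len=25),
        participant_col="participant",
    )
    return events, responses, truth, QUICKSTART_KERNELS, config
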
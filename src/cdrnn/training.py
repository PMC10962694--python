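"""Training configuration and the time-loss convergence criterion.

Convergence is declared when performance has stopped changing with training
time: for each of the most recent ``window`` evaluation epochs, the Pearson
correlation between the metric history up to that epoch and elapsed training
time (epoch index) is tested against zero at level ``alpha``; the run has
converged once at least half of those tests fail to reject the null of no
correlation. The unusually liberal default ``alpha = 0.5`` makes the
criterion conservative: it is *hard* to fail to reject, so convergence is
only declared on a genuine plateau.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class ConvergenceConfig:
    alpha: float = 0.5
    window: int = 100
    eval_metric: str = "train_loglik"  # or "exploratory_loglik"
    eval_interval: int = 1

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.window < 2:
            raise ValueError("window must be at least 2")
        if self.eval_interval < 1:
            raise ValueError("eval_interval must be positive")
        if self.eval_metric not in ("train_loglik", "exploratory_loglik"):
            raise ValueError(f"unknown eval metric {self.eval_metric!r}")


@dataclass
class TrainConfig:
    """Optimization settings; defaults are the package's own choices."""

    learning_rate: float = 1e-3
    batch_size: int = 1024
    max_epochs: int = 2000
    dropout: float = 0.1
    seed: int = 0
    restore_best: bool = True
    lr_decay: float = 1.0  # multiplicative per-epoch decay of the learning rate
    convergence: ConvergenceConfig = field(default_factory=ConvergenceConfig)

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("rates and sizes must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


@dataclass
class FitDiagnostics:
    metric_history: list
    convergence_epoch: int | None
    final_objective: float
    seed: int


def _pearson_p_by_endpoint(
    y: np.ndarray, endpoints: np.ndarray, window: int
) -> np.ndarray:
    """Two-sided p-values of the no-correlation test of metric vs time.

    For each endpoint ``i`` the test covers the most recent ``window``
    observations up to ``y[i-1]`` (fewer when the history is shorter).
    Vectorized via cumulative sums; constant (zero-variance) stretches yield
    p = 1 (fail to reject), as do stretches too short to test.
    """
    n_all = len(y)
    x = np.arange(n_all, dtype=float)
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cx = np.concatenate([[0.0], np.cumsum(x)])
    cxy = np.concatenate([[0.0], np.cumsum(x * y)])
    cxx = np.concatenate([[0.0], np.cumsum(x * x)])
    cyy = np.concatenate([[0.0], np.cumsum(y * y)])
    hi = endpoints
    lo = np.maximum(0, endpoints - window)
    n = (hi - lo).astype(float)
    sx, sy = cx[hi] - cx[lo], cy[hi] - cy[lo]
    sxy, sxx, syy = cxy[hi] - cxy[lo], cxx[hi] - cxx[lo], cyy[hi] - cyy[lo]
    cov = sxy - sx * sy / n
    vx = sxx - sx * sx / n
    vy = syy - sy * sy / n
    p = np.ones_like(n)
    ok = (n > 2) & (vx > 0) & (vy > 1e-300)
    r = np.zeros_like(n)
    r[ok] = cov[ok] / np.sqrt(vx[ok] * vy[ok])
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    denom = 1.0 - r * r
    tiny = denom[ok] <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt(np.where(denom > 0, df / np.maximum(denom, 1e-300), np.inf))
    p[ok] = 2.0 * stats.t.sf(np.abs(tstat[ok]), df[ok])
    p[ok] = np.where(tiny, 0.0, p[ok])
    return p


def check_convergence(metric_history, alpha: float = 0.5, window: int = 100):
    """Time-loss convergence check.

    For each of the last ``window`` evaluation epochs, tests the correlation
    of the metric with training time (over the most recent ``window``
    evaluations up to that epoch) at level ``alpha``. Converged iff at least
    ``window / 2`` of the tests fail to reject; never converged before
    ``window`` epochs exist.

    Returns ``(converged, diagnostics)`` where diagnostics carries the
    per-endpoint p-values and the count of non-significant tests.
    """
    y = np.asarray(metric_history, dtype=float)
    if y.size and not np.all(np.isfinite(y)):
        raise ValueError("metric history contains non-finite values")
    if y.size < window:
        return False, {"n_fail_to_reject": 0, "p_values": np.empty(0)}
    endpoints = np.arange(y.size - window + 1, y.size + 1)
    p = _pearson_p_by_endpoint(y, endpoints, window)
    n_fail = int((p > alpha).sum())
    return n_fail >= window / 2.0, {"n_fail_to_reject": n_fail, "p_values": p}
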
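"""Fitted-model results: prediction, likelihood evaluation, posterior draws,
effect queries, serialization, and a text summary.

A :class:`CDRNNResults` is self-contained — it carries the model spec, the
fitted parameters, the training-set standardization constants and the
random-effects level maps — so it can score new event/response tables without
the original model object.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import model as _model
from .families import get_family
from .nn import sample_dropout_masks
from .training import ConvergenceConfig, FitDiagnostics, TrainConfig

CHECKPOINT_FORMAT_VERSION = 1


@dataclass
class CDRNNResults:
    """Estimates and diagnostics from one fitted model."""

    spec: _model.ModelSpec
    config: TrainConfig
    theta: dict
    stz: _model.Standardization
    level_maps: dict
    diagnostics: FitDiagnostics
    series_col: str = "series_id"
    time_col: str = "time"

    def __post_init__(self):
        self.family = get_family(self.spec.family)
        self.ffspec = _model.ffspec_for(self.spec, self.family)

    # -- prediction ---------------------------------------------------------

    def _design(self, events: pd.DataFrame, responses: pd.DataFrame) -> _model.Design:
        design = _model.build_design(
            events, responses, self.spec, self.stz, self.level_maps,
            self.series_col, self.time_col,
        )
        for f, z in design.zidx.items():
            n_unk = int((z < 0).sum())
            if n_unk:
                warnings.warn(
                    f"{n_unk} response sample(s) have unknown level(s) of "
                    f"grouping factor {f!r}; falling back to the population "
                    "prediction for that factor",
                    stacklevel=3,
                )
        return design

    def _linked(self, design: _model.Design, masks=None) -> np.ndarray:
        s_raw, _ = _model.forward(
            self.theta, self.spec, self.ffspec, self.family, design, masks=masks
        )
        return self.family.link(s_raw)

    def predict(self, events: pd.DataFrame, responses: pd.DataFrame) -> pd.DataFrame:
        """Per-sample linked distribution parameters and log likelihoods.

        Deterministic given the checkpoint and inputs (dropout off).
        """
        design = self._design(events, responses)
        linked = self._linked(design)
        ll = self.family.loglik(design.y, linked)
        out = pd.DataFrame(
            {
                self.series_col: responses[self.series_col].to_numpy(),
                self.time_col: design.tau,
                self.spec.response: design.y,
            }
        )
        if self.spec.family == "normal":
            out["mu"] = linked[:, 0]
            out["sigma"] = linked[:, 1]
        else:  # pragma: no cover - only normal implemented end-to-end
            for j in range(linked.shape[1]):
                out[f"s{j}"] = linked[:, j]
        out["loglik"] = ll
        return out

    def loglik_vector(self, events: pd.DataFrame, responses: pd.DataFrame) -> np.ndarray:
        design = self._design(events, responses)
        return self.family.loglik(design.y, self._linked(design))

    def loglik(self, events, responses) -> float:
        return float(self.loglik_vector(events, responses).sum())

    # -- approximate posterior ----------------------------------------------

    def posterior_sample(self, n_samples: int, seed: int | None = None) -> np.ndarray:
        """Seeds of ``n_samples`` Monte Carlo dropout draws.

        Each seed determines one stochastic forward parameterization (one
        resampled set of dropout masks). With ``dropout = 0`` all draws are
        degenerate (identical to the deterministic pass). Reproducible given
        ``seed``.
        """
        if n_samples < 1:
            raise ValueError("n_samples must be at least 1")
        rng = np.random.default_rng(seed)
        return rng.integers(0, 2**31 - 1, size=n_samples)

    def draw_masks(self, draw_seed, n_rows: int):
        """Dropout masks for one posterior draw.

        A draw is one sampled network: a single unit mask per hidden layer,
        shared across all inputs it is applied to (broadcast over rows). This
        keeps constraint-induced degeneracies exact within each draw — a
        stationary model's draw is constant in onset time, a linear one is
        linear in the predictor.
        """
        if self.ffspec is None or self.config.dropout <= 0 or draw_seed is None:
            return None
        rng = np.random.default_rng(int(draw_seed))
        return sample_dropout_masks(self.ffspec, self.config.dropout, 1, rng)

    # -- effect queries -------------------------------------------------------

    def irf_curve(self, predictor, **kw):
        """Change in a response-distribution parameter from one event, by delay."""
        from . import effects

        return effects.irf_curve(self, predictor, **kw)

    def effect_surface(self, predictor, **kw):
        from . import effects

        return effects.effect_surface(self, predictor, **kw)

    def functional_form_slice(self, predictor, fixed_delay=5.0, **kw):
        from . import effects

        return effects.functional_form_slice(self, predictor, fixed_delay, **kw)

    def interaction_surface(self, predictor_a, predictor_b, fixed_delay=5.0, **kw):
        from . import effects

        return effects.interaction_surface(self, predictor_a, predictor_b, fixed_delay, **kw)

    def sigma_irf(self, predictor, **kw):
        from . import effects

        return effects.sigma_irf(self, predictor, **kw)

    def nonstationarity_curve(self, predictor, fixed_delay=5.0, onset_grid=None, **kw):
        from . import effects

        return effects.nonstationarity_curve(self, predictor, fixed_delay, onset_grid, **kw)

    def history_window_diagnostic(self, factor: float = 2.0, n_points: int = 401) -> dict:
        """Fraction of estimated IRF mass lying beyond the history window.

        The convolution truncates the event history at ``d_max``; this
        diagnostic extrapolates each predictor's fitted location-IRF out to
        ``factor * d_max`` and reports the share of absolute curve mass
        beyond ``d_max``. Values near zero indicate negligible truncation
        error for the fitted kernels.
        """
        d_max = self.spec.d_max
        grid = np.linspace(0.0, factor * d_max, n_points)
        out = {}
        for p in ("rate",) + self.spec.predictors:
            curve = self.irf_curve(p, delay_grid=grid, n_mc=1).estimate
            total = np.trapezoid(np.abs(curve), grid)
            beyond = np.trapezoid(np.abs(curve[grid > d_max]), grid[grid > d_max])
            out[p] = float(beyond / total) if total > 0 else 0.0
        return out

    def linear_coefficients(self) -> dict:
        """Raw-scale intercept and slopes implied by the Dirac reduction.

        Only meaningful for a Dirac-reduced model with identity input
        transform, where the model family collapses to linear regression:
        ``mu = intercept + sum_k slope_k * x_k`` for event-aligned samples
        with a single coincident event.
        """
        if not self.spec.dirac:
            raise ValueError("linear coefficients require the Dirac reduction")
        b = self.theta["coef"]
        slopes = b[1:] / self.stz.x_std
        intercept = float(
            self.theta["bias"][0] + b[0] - np.sum(b[1:] * self.stz.x_mean / self.stz.x_std)
        )
        return {
            "intercept": intercept,
            "slopes": dict(zip(self.spec.predictors, slopes)),
        }

    # -- reporting ------------------------------------------------------------

    def summary(self) -> str:
        spec = self.spec
        buf = io.StringIO()
        w = buf.write
        w("Continuous-time deconvolutional regression (neural IRF)\n")
        w("=" * 56 + "\n")
        w(f"Response:            {spec.response} ~ {spec.family}\n")
        w(f"Predictors (J={len(spec.predictors)}):    {', '.join(spec.predictors)}\n")
        flags = []
        flags.append("causal" if spec.causal else "acausal")
        flags.append("nonstationary" if spec.nonstationary else "stationary")
        flags.append("heteroscedastic" if spec.heteroscedastic else "homoscedastic")
        if spec.dirac:
            flags.append("dirac-reduced")
        nl = spec.nonlinear_set
        if set(nl) != set(spec.predictors):
            flags.append(f"nonlinear on: {', '.join(nl) if nl else 'none'}")
        w(f"Constraints:         {', '.join(flags)}\n")
        if self.ffspec is not None:
            w(
                f"IRF network:         {self.ffspec.input_dim} -> "
                + " -> ".join(str(d) for d in self.ffspec.widths)
                + f" ({spec.activation})\n"
            )
        w(f"History window:      0..{spec.d_max} s\n")
        n_par = sum(v.size for v in self.theta.values())
        w(f"Trainable params:    {n_par}\n")
        d = self.diagnostics
        conv = d.convergence_epoch if d.convergence_epoch is not None else "not reached"
        w(f"Epochs run:          {len(d.metric_history)} (converged: {conv})\n")
        if d.metric_history:
            w(f"Final metric:        {d.metric_history[-1]:.5f} (mean loglik/sample)\n")
        w(f"Penalized objective: {d.final_objective:.3f}\n")
        w(f"Seed:                {d.seed}\n\n")
        w("Coefficients b (scale of each impulse-response column):\n")
        names = ["rate"] + list(spec.predictors)
        for name, val in zip(names, self.theta["coef"]):
            w(f"  {name:<18s} {val:+.4f}\n")
        linked0 = self.family.link(self.theta["bias"][None, :])[0]
        if spec.family == "normal":
            w(f"Intercept s0:        mu={linked0[0]:+.4f}, sigma={linked0[1]:.4f}\n")
        for f in spec.groups:
            sds = []
            if "rc:" + f in self.theta:
                sds.append(f"coef sd={self.theta['rc:' + f].std():.4f}")
            if "rb:" + f in self.theta:
                sds.append(f"bias sd={self.theta['rb:' + f].std():.4f}")
            w(f"Random effects ({f}, {len(self.level_maps[f])} levels): "
              + ", ".join(sds) + "\n")
        w("\nEffect shapes are queried by perturbation: see irf_curve(),\n")
        w("functional_form_slice(), interaction_surface(), sigma_irf(),\n")
        w("nonstationarity_curve().\n")
        return buf.getvalue()

    # -- serialization --------------------------------------------------------

    def save(self, path) -> None:
        """Write a versioned checkpoint archive (arrays + JSON metadata)."""
        meta = {
            "format_version": CHECKPOINT_FORMAT_VERSION,
            "spec": _spec_to_dict(self.spec),
            "config": _config_to_dict(self.config),
            "stz": {
                "x_mean": self.stz.x_mean.tolist(),
                "x_std": self.stz.x_std.tolist(),
                "d_mean": self.stz.d_mean,
                "d_std": self.stz.d_std,
                "t_mean": self.stz.t_mean,
                "t_std": self.stz.t_std,
            },
            "level_maps": {f: {str(k): v for k, v in m.items()} for f, m in self.level_maps.items()},
            "level_key_repr": {
                f: {str(k): type(k).__name__ for k in m} for f, m in self.level_maps.items()
            },
            "diagnostics": {
                "metric_history": list(self.diagnostics.metric_history),
                "convergence_epoch": self.diagnostics.convergence_epoch,
                "final_objective": self.diagnostics.final_objective,
                "seed": self.diagnostics.seed,
            },
            "series_col": self.series_col,
            "time_col": self.time_col,
            "theta_keys": list(self.theta.keys()),
        }
        arrays = {f"theta__{k}": v for k, v in self.theta.items()}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "CDRNNResults":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(bytes(z["__meta__"].tobytes()).decode())
            if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
                raise ValueError("unsupported checkpoint format version")
            theta = {k: np.array(z[f"theta__{k}"]) for k in meta["theta_keys"]}
        spec = _model.ModelSpec(**{
            k: (tuple(v) if isinstance(v, list) else v) for k, v in meta["spec"].items()
        })
        cfg = meta["config"]
        config = TrainConfig(
            learning_rate=cfg["learning_rate"],
            batch_size=cfg["batch_size"],
            max_epochs=cfg["max_epochs"],
            dropout=cfg["dropout"],
            seed=cfg["seed"],
            convergence=ConvergenceConfig(**cfg["convergence"]),
        )
        stz = _model.Standardization(
            x_mean=np.array(meta["stz"]["x_mean"]),
            x_std=np.array(meta["stz"]["x_std"]),
            d_mean=meta["stz"]["d_mean"],
            d_std=meta["stz"]["d_std"],
            t_mean=meta["stz"]["t_mean"],
            t_std=meta["stz"]["t_std"],
        )
        level_maps = {}
        for f, m in meta["level_maps"].items():
            kinds = meta["level_key_repr"].get(f, {})
            conv = {}
            for k, v in m.items():
                kind = kinds.get(k, "str")
                if kind in ("int", "int64", "int32"):
                    conv[int(k)] = v
                elif kind in ("float", "float64"):
                    conv[float(k)] = v
                else:
                    conv[k] = v
            level_maps[f] = conv
        diag = FitDiagnostics(**meta["diagnostics"])
        return cls(
            spec=spec, config=config, theta=theta, stz=stz,
            level_maps=level_maps, diagnostics=diag,
            series_col=meta["series_col"], time_col=meta["time_col"],
        )


def _spec_to_dict(spec: _model.ModelSpec) -> dict:
    d = asdict(spec)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def _config_to_dict(config: TrainConfig) -> dict:
    d = asdict(config)
    return d
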
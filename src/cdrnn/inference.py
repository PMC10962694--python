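"""Generalization-based hypothesis testing.

A null hypothesis is expressed as a *constraint* on the model: ablating a
predictor, forcing its effect to be linear, forcing stationarity, or forcing
homoscedasticity. Full and constrained ensembles are fitted on the training
partition, both are evaluated on a held-out partition, and the per-sample
conditional log likelihoods are compared with a paired permutation test.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import data as _data
from .model import CDRNN, ModelSpec
from .training import TrainConfig


@dataclass(frozen=True)
class ConstraintSet:
    """Constraint flags mapping a null hypothesis onto a model spec.

    ``ablate``: predictors removed from the model entirely. ``linear``:
    predictors removed from the impulse-response network's inputs but kept in
    the convolution product (``"all"`` for every predictor). ``stationary``:
    the event timestamp is withheld from the network. ``homoscedastic``:
    events may move only the location parameter, and the scale collapses to a
    single free constant. ``causal``: zero response to future events.
    """

    ablate: tuple = ()
    linear: object = ()
    stationary: bool = False
    homoscedastic: bool = False
    causal: bool = True

    def __post_init__(self):
        object.__setattr__(self, "ablate", tuple(self.ablate))
        if self.linear != "all":
            object.__setattr__(self, "linear", tuple(self.linear))

    def describe(self) -> str:
        parts = []
        if self.ablate:
            parts.append("ablate " + ",".join(self.ablate))
        if self.linear == "all":
            parts.append("linear(all)")
        elif self.linear:
            parts.append("linear " + ",".join(self.linear))
        if self.stationary:
            parts.append("stationary")
        if self.homoscedastic:
            parts.append("homoscedastic")
        if not self.causal:
            parts.append("acausal")
        return "+".join(parts) if parts else "none"


def build_null(spec: ModelSpec, constraints: ConstraintSet) -> ModelSpec:
    """Apply a constraint set to a model spec, yielding the null model's spec."""
    preds = set(spec.predictors)
    for p in constraints.ablate:
        if p not in preds:
            raise ValueError(f"cannot ablate unknown predictor {p!r}")
    new_preds = tuple(p for p in spec.predictors if p not in constraints.ablate)
    if constraints.linear == "all":
        nonlinear = ()
    elif constraints.linear:
        for p in constraints.linear:
            if p not in preds:
                raise ValueError(f"cannot linearize unknown predictor {p!r}")
        nonlinear = tuple(
            p for p in spec.nonlinear_set
            if p in new_preds and p not in constraints.linear
        )
    elif spec.nonlinear is None:
        nonlinear = None
    else:
        nonlinear = tuple(p for p in spec.nonlinear if p in new_preds)
    return spec.replace(
        predictors=new_preds,
        nonlinear=nonlinear,
        nonstationary=spec.nonstationary and not constraints.stationary,
        heteroscedastic=spec.heteroscedastic and not constraints.homoscedastic,
        causal=constraints.causal,
    )


class CDRNNEnsemble:
    """A set of independently seeded fits combined as a predictive mixture.

    The ensemble's per-sample log likelihood is the log of the mean of the
    member predictive densities (log-mean-exp of member log likelihoods), a
    proper mixture rather than an average of parameters. Effect queries pool
    credible bands over members and dropout draws.
    """

    def __init__(self, members):
        if not members:
            raise ValueError("ensemble needs at least one member")
        self.members = list(members)

    def __len__(self):
        return len(self.members)

    def loglik_vector(self, events, responses) -> np.ndarray:
        lls = np.stack(
            [m.loglik_vector(events, responses) for m in self.members], axis=0
        )
        from scipy.special import logsumexp

        return logsumexp(lls, axis=0) - np.log(len(self.members))

    def loglik(self, events, responses) -> float:
        return float(self.loglik_vector(events, responses).sum())

    def member_logliks(self, events, responses) -> np.ndarray:
        return np.array([m.loglik_vector(events, responses).sum() for m in self.members])

    # effect queries pool draws over members via effects._members
    def irf_curve(self, predictor, **kw):
        from . import effects

        return effects.irf_curve(self, predictor, **kw)

    def functional_form_slice(self, predictor, fixed_delay=5.0, **kw):
        from . import effects

        return effects.functional_form_slice(self, predictor, fixed_delay, **kw)

    def sigma_irf(self, predictor, **kw):
        from . import effects

        return effects.sigma_irf(self, predictor, **kw)

    def nonstationarity_curve(self, predictor, fixed_delay=5.0, onset_grid=None, **kw):
        from . import effects

        return effects.nonstationarity_curve(self, predictor, fixed_delay, onset_grid, **kw)


def ensemble_fit(
    events: pd.DataFrame,
    responses: pd.DataFrame,
    spec: ModelSpec,
    n_members: int = 10,
    seeds=None,
    config: TrainConfig | None = None,
    **model_kw,
) -> CDRNNEnsemble:
    """Fit ``n_members`` models differing only in their random seed."""
    import dataclasses

    config = TrainConfig() if config is None else config
    if seeds is None:
        seeds = [config.seed + i for i in range(n_members)]
    if len(seeds) != n_members:
        raise ValueError("need one seed per ensemble member")
    members = []
    for s in seeds:
        cfg = dataclasses.replace(config, seed=int(s))
        members.append(CDRNN(events, responses, spec, **model_kw).fit(cfg))
    return CDRNNEnsemble(members)


@dataclass
class PermutationTestResult:
    statistic: float
    p_value: float
    n_perm: int
    observed_diff: float
    description: str = ""


def paired_permutation_test(
    lla: np.ndarray,
    llb: np.ndarray,
    n_perm: int = 10000,
    seed: int | None = None,
    ids_a=None,
    ids_b=None,
    cluster=None,
) -> PermutationTestResult:
    """Paired permutation test on per-sample log likelihoods of two models.

    The statistic is the absolute total difference ``|sum(lla - llb)|``
    (two-sided). The null distribution is built by independently swapping
    each pair's model labels with probability 1/2, ``n_perm`` times; the
    p-value uses add-one smoothing: ``(1 + #{null >= observed}) / (1 +
    n_perm)``. When ``cluster`` is given (one id per sample), labels are
    swapped per cluster rather than per sample.
    """
    lla = np.asarray(lla, dtype=float)
    llb = np.asarray(llb, dtype=float)
    if lla.shape != llb.shape:
        raise ValueError("likelihood vectors must be aligned")
    if ids_a is not None and ids_b is not None:
        if not np.array_equal(np.asarray(ids_a), np.asarray(ids_b)):
            raise ValueError("sample identifiers do not align across models")
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    diffs = lla - llb
    if cluster is not None:
        cluster = np.asarray(cluster)
        _, inv = np.unique(cluster, return_inverse=True)
        diffs = np.bincount(inv, weights=diffs)
    stat = abs(float(diffs.sum()))
    rng = np.random.default_rng(seed)
    n = diffs.shape[0]
    count = 0
    chunk = max(1, min(n_perm, int(2e7) // max(n, 1)))
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        signs = rng.integers(0, 2, size=(k, n)) * 2 - 1
        null = np.abs(signs @ diffs)
        count += int((null >= stat - 1e-12).sum())
        done += k
    p = (1.0 + count) / (1.0 + n_perm)
    return PermutationTestResult(
        statistic=stat, p_value=float(p), n_perm=n_perm,
        observed_diff=float((lla - llb).sum()),
    )


@dataclass
class ComparisonReport:
    """Out-of-sample comparison of a full model against a constrained null."""

    constraints: ConstraintSet
    partition: str
    full_loglik: float
    null_loglik: float
    delta_loglik: float
    p_value: float
    statistic: float
    n_perm: int
    n_samples: int
    member_logliks_full: np.ndarray
    member_logliks_null: np.ndarray
    seeds: tuple

    def summary(self) -> str:
        buf = io.StringIO()
        w = buf.write
        w("Out-of-sample model comparison (paired permutation test)\n")
        w("-" * 56 + "\n")
        w(f"Null constraints:   {self.constraints.describe()}\n")
        w(f"Held-out partition: {self.partition} ({self.n_samples} samples)\n")
        w(f"Ensemble loglik:    full {self.full_loglik:.3f} | null {self.null_loglik:.3f}\n")
        w(f"Delta loglik:       {self.delta_loglik:+.3f}\n")
        w(f"Permutations:       {self.n_perm}\n")
        w(f"p-value:            {self.p_value:.4g}\n")
        w(f"Member logliks (full): "
          + ", ".join(f"{v:.1f}" for v in self.member_logliks_full) + "\n")
        w(f"Member logliks (null): "
          + ", ".join(f"{v:.1f}" for v in self.member_logliks_null) + "\n")
        w(f"Seeds:              {list(self.seeds)}\n")
        return buf.getvalue()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "constraints": [self.constraints.describe()],
                "partition": [self.partition],
                "full_loglik": [self.full_loglik],
                "null_loglik": [self.null_loglik],
                "delta_loglik": [self.delta_loglik],
                "statistic": [self.statistic],
                "p_value": [self.p_value],
                "n_perm": [self.n_perm],
                "n_samples": [self.n_samples],
            }
        )


def compare(
    events: pd.DataFrame,
    responses: pd.DataFrame,
    spec: ModelSpec,
    constraints: ConstraintSet,
    n_members: int = 10,
    n_perm: int = 10000,
    partition: str = _data.TEST,
    config: TrainConfig | None = None,
    seed: int | None = None,
    **model_kw,
) -> ComparisonReport:
    """Fit full and constrained ensembles; test held-out likelihood difference."""
    import dataclasses

    config = TrainConfig() if config is None else config
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    if "partition" not in responses.columns:
        raise ValueError("responses need a partition column; see partition_responses")
    held = responses.loc[responses["partition"] == partition]
    if not len(held):
        raise ValueError(f"held-out partition {partition!r} is empty")

    null_spec = build_null(spec, constraints)
    full = ensemble_fit(
        events, responses, spec, n_members=n_members, config=config, **model_kw
    )
    if null_spec == spec:
        null = full
    else:
        null = ensemble_fit(
            events, responses, null_spec, n_members=n_members, config=config, **model_kw
        )
    lla = full.loglik_vector(events, held)
    llb = null.loglik_vector(events, held)
    test = paired_permutation_test(lla, llb, n_perm=n_perm, seed=config.seed)
    return ComparisonReport(
        constraints=constraints,
        partition=partition,
        full_loglik=float(lla.sum()),
        null_loglik=float(llb.sum()),
        delta_loglik=float(lla.sum() - llb.sum()),
        p_value=test.p_value,
        statistic=test.statistic,
        n_perm=n_perm,
        n_samples=len(held),
        member_logliks_full=full.member_logliks(events, held),
        member_logliks_null=null.member_logliks(events, held),
        seeds=tuple(m.diagnostics.seed for m in full.members),
    )
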
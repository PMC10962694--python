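"""Shared fixtures: synthetic datasets and fitted models reused across tests.

The heavier fitted objects are session-scoped so that recovery studies,
effect-query tests and the acceptance suite share one set of fits.
"""

import pytest

from cdrnn.data import PartitionConfig, partition_responses
from cdrnn.inference import ensemble_fit
from cdrnn.model import CDRNN, ModelSpec
from cdrnn.synthetic import (
    ExponentialKernel,
    SimConfig,
    generate_events,
    generate_responses,
    quickstart_fixture,
)
from cdrnn.training import ConvergenceConfig, TrainConfig

# study conditions for the kernel-recovery fit on the quickstart fixture
QS_SPEC = ModelSpec(predictors=("x1", "x2"), groups=("participant",), d_max=2.5)
QS_TRAIN = TrainConfig(
    seed=1,
    max_epochs=3000,
    dropout=0.1,
    lr_decay=0.9992,
    convergence=ConvergenceConfig(window=100, eval_metric="exploratory_loglik"),
)

# heteroscedastic study: log-scale gain 0.5 on x1, sigma(x) = exp(0.5 x) at the
# kernel peak
HET_CONFIG = SimConfig(
    n_events=2000,
    n_participants=4,
    predictors=("x1", "x2"),
    spacing=("exponential", 0.3),
    sampling=("event",),
    intercept=1.0,
    sigma0=1.0,
    hetero_gamma={"x1": 0.5},
    ranef_sd=0.2,
    seed=202,
)
HET_KERNELS = {"x1": ExponentialKernel(1.0, 5.0), "x2": ExponentialKernel(-0.5, 2.0)}
HET_TRAIN = TrainConfig(
    seed=1,
    max_epochs=2000,
    dropout=0.1,
    lr_decay=0.9988,
    convergence=ConvergenceConfig(window=100, eval_metric="exploratory_loglik"),
)


def make_small_data(seed=7, n_events=600, **overrides):
    config = SimConfig(
        n_events=n_events,
        n_participants=2,
        predictors=("x1", "x2"),
        spacing=("exponential", 0.3),
        sampling=("event",),
        intercept=1.0,
        sigma0=1.0,
        ranef_sd=0.2,
        seed=seed,
        **overrides,
    )
    kernels = {"x1": ExponentialKernel(1.0, 5.0), "x2": ExponentialKernel(-0.5, 2.0)}
    events = generate_events(config)
    responses, truth = generate_responses(events, kernels, config)
    responses = partition_responses(
        responses, PartitionConfig(scheme="chunk_cycle", chunk_len=25), "participant"
    )
    return events, responses, truth, kernels, config


SMALL_SPEC = ModelSpec(predictors=("x1", "x2"), groups=("participant",), d_max=2.0)


def small_train_config(seed=3, **kw):
    kw.setdefault("max_epochs", 150)
    kw.setdefault("dropout", 0.1)
    kw.setdefault("convergence", ConvergenceConfig(window=500))
    return TrainConfig(seed=seed, **kw)


@pytest.fixture(scope="session")
def quickstart():
    return quickstart_fixture()


@pytest.fixture(scope="session")
def quickstart_ensemble(quickstart):
    events, responses, _truth, _kernels, _config = quickstart
    return ensemble_fit(events, responses, QS_SPEC, n_members=4, config=QS_TRAIN)


@pytest.fixture(scope="session")
def hetero_study():
    events = generate_events(HET_CONFIG)
    responses, truth = generate_responses(events, HET_KERNELS, HET_CONFIG)
    responses = partition_responses(
        responses, PartitionConfig(scheme="chunk_cycle", chunk_len=25), "participant"
    )
    ens = ensemble_fit(events, responses, QS_SPEC, n_members=3, config=HET_TRAIN)
    return events, responses, truth, ens


@pytest.fixture(scope="session")
def small_data():
    return make_small_data()


@pytest.fixture(scope="session")
def small_fit(small_data):
    events, responses, *_ = small_data
    return CDRNN(events, responses, SMALL_SPEC).fit(small_train_config())


@pytest.fixture(scope="session")
def small_fit_nodrop(small_data):
    events, responses, *_ = small_data
    return CDRNN(events, responses, SMALL_SPEC).fit(small_train_config(dropout=0.0))
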
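"""Convolutional read-out and prediction semantics: additivity, causal
masking, and equivalence with independent step-by-step computation."""

import numpy as np
import pandas as pd
import pytest

from cdrnn.families import get_family
from cdrnn.model import (
    CDRNN,
    ModelSpec,
    build_design,
    convolve,
    forward,
    output_mask,
)
from cdrnn.nn import ffn_apply


def brute_force_convolve(s0, b, G_seq, Xp):
    """Element-by-element oracle for the convolution read-out."""
    s0 = np.asarray(s0, dtype=float)
    s = s0.copy()
    for n, G in enumerate(G_seq):
        e = np.concatenate([[1.0], np.atleast_2d(Xp)[n]])
        for i in range(s.size):
            acc = 0.0
            for j in range(len(b)):
                acc += G[i][j] * b[j] * e[j]
            s[i] += acc
    return s


class TestConvolve:
    def test_empty_sequence_returns_intercept(self):
        np.testing.assert_array_equal(
            convolve(np.array([1.0, 2.0]), np.array([1.0]), [], np.empty((0, 0))),
            [1.0, 2.0],
        )

    def test_hand_computed_single_event(self):
        # 0.5 * 0 * 1 + 2 * 1 * 3 = 6
        s = convolve(
            np.array([0.0]),
            np.array([0.0, 1.0]),
            [np.array([[0.5, 2.0]])],
            np.array([[3.0]]),
        )
        assert s[0] == pytest.approx(6.0)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(trial)
        S, J, N = rng.integers(1, 4), rng.integers(1, 4), 5
        s0 = rng.standard_normal(S)
        b = rng.standard_normal(J + 1)
        G_seq = [rng.standard_normal((S, J + 1)) for _ in range(N)]
        Xp = rng.standard_normal((N, J))
        np.testing.assert_allclose(
            convolve(s0, b, G_seq, Xp),
            brute_force_convolve(s0, b, G_seq, Xp),
            rtol=1e-12,
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="event 0"):
            convolve(np.zeros(2), np.zeros(2), [np.zeros((2, 5))], np.ones((1, 1)))


def tiny_model(responses_extra=None, **spec_kw):
    """A two-series toy problem with an untrained (random-init) model."""
    rng = np.random.default_rng(11)
    events = pd.DataFrame(
        {
            "series_id": ["a"] * 5 + ["b"] * 4,
            "time": [0.0, 0.4, 0.9, 1.5, 2.0, 0.0, 0.5, 0.7, 1.1],
            "x1": rng.standard_normal(9),
            "x2": rng.standard_normal(9),
            "participant": ["pa"] * 5 + ["pb"] * 4,
        }
    )
    responses = pd.DataFrame(
        {
            "series_id": ["a", "a", "b"],
            "time": [1.0, 2.1, 1.2],
            "y": [0.3, -0.1, 0.8],
            "participant": ["pa", "pa", "pb"],
        }
    )
    if responses_extra is not None:
        responses = pd.concat([responses, responses_extra], ignore_index=True)
    spec_kw.setdefault("predictors", ("x1", "x2"))
    spec_kw.setdefault("groups", ("participant",))
    spec_kw.setdefault("d_max", 5.0)
    spec = ModelSpec(**spec_kw)
    model = CDRNN(events, responses, spec)
    theta = model._init_theta(np.random.default_rng(5))
    # random, nonzero random effects to exercise composition
    for k in theta:
        theta[k] = theta[k] + 0.2 * np.random.default_rng(6).standard_normal(theta[k].shape)
    return events, responses, model, theta


class TestEngineComposition:
    def test_forward_equals_stepwise_module_composition(self):
        _events, _responses, model, theta = tiny_model()
        design = model.train_design
        spec, ffspec, fam = model.spec, model.ffspec, model.family
        s_engine, _ = forward(theta, spec, ffspec, fam, design)
        omask = output_mask(spec, fam.n_params, design.E.shape[1])
        params = [(theta[f"W{l}"], theta[f"b{l}"]) for l in range(ffspec.n_layers)]
        for m in range(design.M):
            lo, hi = design.offsets[m], design.offsets[m + 1]
            G_seq, Xp = [], []
            for p in range(lo, hi):
                G = ffn_apply(ffspec, params, design.U[p]).reshape(
                    fam.n_params, design.E.shape[1]
                )
                G = G * omask
                if spec.causal and design.d_raw[p] < 0:
                    G = np.zeros_like(G)
                G_seq.append(G)
                Xp.append(design.E[p, 1:])
            z = design.zidx["participant"][m]
            b_m = theta["coef"] + theta["rc:participant"][z]
            s0_m = theta["bias"] + theta["rb:participant"][z]
            s_manual = convolve(s0_m, b_m, G_seq, np.array(Xp))
            np.testing.assert_allclose(s_engine[m], s_manual, rtol=1e-10)

    def test_superposition_of_single_events(self):
        # raw parameters are additive over events: s(A+B) - s0 = (s(A)-s0) + (s(B)-s0)
        _events, _responses, model, theta = tiny_model(groups=())
        spec, ffspec, fam = model.spec, model.ffspec, model.family
        ev_a = pd.DataFrame(
            {"series_id": ["s"], "time": [0.2], "x1": [1.3], "x2": [-0.4]}
        )
        ev_b = pd.DataFrame(
            {"series_id": ["s"], "time": [0.8], "x1": [-0.6], "x2": [0.9]}
        )
        resp = pd.DataFrame({"series_id": ["s"], "time": [1.0], "y": [0.0]})

        def s_of(events):
            d = build_design(events, resp, spec, model.stz, {}, "series_id", "time")
            return forward(theta, spec, ffspec, fam, d)[0][0]

        s0 = theta["bias"]
        s_ab = s_of(pd.concat([ev_a, ev_b], ignore_index=True))
        s_a, s_b = s_of(ev_a), s_of(ev_b)
        np.testing.assert_allclose(s_ab - s0, (s_a - s0) + (s_b - s0), rtol=1e-10)

    def test_duplicated_event_doubles_contribution(self):
        _events, _responses, model, theta = tiny_model(groups=())
        spec, ffspec, fam = model.spec, model.ffspec, model.family
        ev = pd.DataFrame({"series_id": ["s"], "time": [0.5], "x1": [0.7], "x2": [0.1]})
        resp = pd.DataFrame({"series_id": ["s"], "time": [1.0], "y": [0.0]})

        def s_of(events):
            d = build_design(events, resp, spec, model.stz, {}, "series_id", "time")
            return forward(theta, spec, ffspec, fam, d)[0][0]

        single = s_of(ev) - theta["bias"]
        double = s_of(pd.concat([ev, ev], ignore_index=True)) - theta["bias"]
        np.testing.assert_allclose(double, 2.0 * single, rtol=1e-10)

    def test_causal_model_ignores_future_events(self):
        events, responses, model, theta = tiny_model()
        base, _ = forward(theta, model.spec, model.ffspec, model.family, model.train_design)
        # corrupt events that lie in the future of samples 0 (tau=1.0, series a)
        # and 2 (tau=1.2, series b); sample 1 (tau=2.1) is excluded below
        edited = events.copy()
        future = edited["time"] > 1.3
        edited.loc[future, ["x1", "x2"]] = 999.0
        d2 = build_design(
            edited, model.train_responses, model.spec, model.stz,
            model.level_maps, "series_id", "time",
        )
        # only compare samples whose window precedes the edits
        alt, _ = forward(theta, model.spec, model.ffspec, model.family, d2)
        np.testing.assert_array_equal(base[[0, 2]], alt[[0, 2]])

    def test_zero_network_weights_give_pure_intercept(self):
        _events, _responses, model, theta = tiny_model(groups=())
        for l in range(model.ffspec.n_layers):
            theta[f"W{l}"] = np.zeros_like(theta[f"W{l}"])
            theta[f"b{l}"] = np.zeros_like(theta[f"b{l}"])
        s_raw, _ = forward(theta, model.spec, model.ffspec, model.family, model.train_design)
        np.testing.assert_allclose(s_raw, np.tile(theta["bias"], (s_raw.shape[0], 1)))


class TestPredict:
    def test_output_table_and_determinism(self, small_fit, small_data):
        events, responses, *_ = small_data
        sub = responses.head(50)
        p1 = small_fit.predict(events, sub)
        p2 = small_fit.predict(events, sub)
        pd.testing.assert_frame_equal(p1, p2)
        assert {"mu", "sigma", "loglik", "y"} <= set(p1.columns)
        assert (p1["sigma"] > 0).all()
        ll = get_family("normal").loglik(
            p1["y"].to_numpy(), p1[["mu", "sigma"]].to_numpy()
        )
        np.testing.assert_allclose(ll, p1["loglik"], rtol=1e-10)

    def test_unknown_level_falls_back_to_population(self, small_fit, small_data):
        events, responses, *_ = small_data
        sub = responses.head(5).copy()
        sub["participant"] = "never-seen"
        with pytest.warns(UserWarning, match="unknown level"):
            alien = small_fit.predict(events, sub)
        assert np.isfinite(alien["loglik"]).all()

    def test_missing_column_rejected(self, small_fit, small_data):
        events, responses, *_ = small_data
        with pytest.raises(ValueError, match="x2"):
            small_fit.predict(events.drop(columns=["x2"]), responses.head(5))
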
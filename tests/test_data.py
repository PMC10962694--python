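import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdrnn.data import (
    EventSeries,
    PartitionConfig,
    assign_partition_chunk,
    assign_partition_sentence,
    compute_delays,
    filter_et,
    filter_spr,
    partition_responses,
    split_by_regression,
)


def make_series(t, X=None, names=("x",)):
    t = np.asarray(t, dtype=float)
    if X is None:
        X = np.zeros((len(t), len(names)))
    return EventSeries(series_id="s", t=t, X=X, predictor_names=names)


class TestDelays:
    @pytest.mark.parametrize(
        "tau,t,expected",
        [
            (10.0, [1.0, 4.0, 9.0], [9.0, 6.0, 1.0]),
            (10.0, [12.0], [-2.0]),  # future event: negative delay
            (5.0, [5.0], [0.0]),  # coincident event
            (0.0, [], []),
        ],
    )
    def test_examples(self, tau, t, expected):
        d = compute_delays(make_series(t), tau)
        np.testing.assert_array_equal(d, expected)

    @given(
        st.lists(st.floats(-100, 100), min_size=1, max_size=20),
        st.floats(-100, 100),
        st.floats(-1e3, 1e3),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_translation_equivariance(self, ts, tau, shift):
        ts = sorted(ts)
        d0 = compute_delays(make_series(ts), tau)
        d1 = compute_delays(make_series([t + shift for t in ts]), tau + shift)
        np.testing.assert_allclose(d0, d1, atol=1e-6)


class TestEventSeries:
    def test_rejects_decreasing_timestamps(self):
        with pytest.raises(ValueError, match="nondecreasing"):
            make_series([1.0, 0.5])

    def test_rejects_missing_values(self):
        with pytest.raises(ValueError, match="missing"):
            make_series([0.0], X=np.array([[np.nan]]))

    def test_simultaneous_events_allowed(self):
        s = make_series([1.0, 1.0, 2.0])
        assert s.n_events == 3


class TestSentencePartition:
    @pytest.mark.parametrize(
        "e,u,expected",
        [(0, 0, "train"), (1, 0, "train"), (1, 1, "exploratory"), (3, 0, "test")],
    )
    def test_examples(self, e, u, expected):
        assert assign_partition_sentence(e, u) == expected

    def test_rejects_negative_indices(self):
        with pytest.raises(ValueError):
            assign_partition_sentence(-1, 0)

    def test_full_cycle_proportions(self):
        # over any complete modulus cycle: half train, a quarter each of the rest
        labels = [assign_partition_sentence(e, u) for e in range(4) for u in range(4)]
        assert labels.count("train") == 8
        assert labels.count("exploratory") == 4
        assert labels.count("test") == 4


class TestChunkPartition:
    def test_chunk_shares_label(self):
        labels = {assign_partition_chunk(i, 0, chunk_len=15) for i in range(15)}
        assert len(labels) == 1

    def test_chunk_len_one_cycles_per_sample(self):
        labels = [assign_partition_chunk(i, 0, chunk_len=1) for i in range(4)]
        assert labels == ["train", "train", "exploratory", "test"]

    @pytest.mark.parametrize("chunk_len", [1, 3, 15])
    def test_enumeration_half_train(self, chunk_len):
        labels = [
            assign_partition_chunk(i, 0, chunk_len=chunk_len)
            for i in range(4 * chunk_len)
        ]
        assert labels.count("train") == 2 * chunk_len

    def test_rejects_bad_chunk_len(self):
        with pytest.raises(ValueError):
            assign_partition_chunk(0, 0, chunk_len=0)

    def test_participant_phase(self):
        a = assign_partition_chunk(0, 0, chunk_len=5)
        b = assign_partition_chunk(0, 2, chunk_len=5)
        assert (a, b) == ("train", "exploratory")


class TestPartitionResponses:
    def test_chunk_cycle_table(self):
        df = pd.DataFrame(
            {"participant": ["a"] * 8 + ["b"] * 8, "y": np.zeros(16)}
        )
        out = partition_responses(
            df, PartitionConfig(scheme="chunk_cycle", chunk_len=2), "participant"
        )
        counts = out["partition"].value_counts()
        assert counts["train"] == 8
        assert counts["exploratory"] == 4
        assert counts["test"] == 4

    def test_sentence_cycle_requires_unit_col(self):
        df = pd.DataFrame({"participant": ["a"], "y": [0.0]})
        with pytest.raises(ValueError, match="unit_col"):
            partition_responses(df, PartitionConfig(), "participant")


def spr_table(durations, participants=None, start=None, end=None):
    n = len(durations)
    return pd.DataFrame(
        {
            "duration_ms": durations,
            "participant": participants or ["p0"] * n,
            "sentence_start": start or [False] * n,
            "sentence_end": end or [False] * n,
        }
    )


class TestFilterSPR:
    def test_duration_bounds(self):
        # strict bounds: 100 and 3000 themselves survive
        df = spr_table([50, 150, 200, 3500, 400, 600])
        kept, rep = filter_spr(df, {}, min_responses=1)
        assert len(kept) == 4
        assert rep["duration"] == 2

    def test_boundary_values_survive(self):
        kept, _ = filter_spr(spr_table([100, 3000]), {}, min_responses=1)
        assert len(kept) == 2

    def test_missed_questions_removes_participant(self):
        df = spr_table([200] * 5)
        kept, rep = filter_spr(df, {"p0": 5}, min_responses=1)
        assert len(kept) == 0
        assert rep["missed_questions_participants"] == 1

    def test_identity_when_no_rule_fires(self):
        df = spr_table([200] * 120)
        kept, rep = filter_spr(df, {"p0": 0})
        assert len(kept) == 120
        assert rep["output_rows"] == rep["input_rows"]

    def test_few_responses_rule(self):
        df = spr_table([200] * 50)
        kept, rep = filter_spr(df, {})
        assert len(kept) == 0
        assert rep["few_responses_participants"] == 1

    def test_idempotent_and_counts_sum(self):
        df = spr_table(
            [50, 200, 200, 4000] + [200] * 120,
            start=[False, True] + [False] * 122,
        )
        kept, rep = filter_spr(df, {})
        kept2, rep2 = filter_spr(kept, {})
        pd.testing.assert_frame_equal(kept, kept2)
        assert rep2["output_rows"] == rep2["input_rows"]
        removed = (
            rep["duration"]
            + rep["sentence_boundary"]
            + rep["missed_questions_rows"]
            + rep["few_responses_rows"]
        )
        assert rep["input_rows"] - rep["output_rows"] == removed

    def test_missing_column_named(self):
        with pytest.raises(ValueError, match="duration_ms"):
            filter_spr(pd.DataFrame({"participant": []}), {})


def et_table(**overrides):
    base = {
        "fixated": [True],
        "saccade_len": [1.0],
        "blink": [False],
        "sentence_start": [False],
        "sentence_end": [False],
        "line_start": [False],
        "line_end": [False],
    }
    base.update(overrides)
    return pd.DataFrame(base)


class TestFilterET:
    def test_saccade_strictly_longer_than_four(self):
        kept5, _ = filter_et(et_table(saccade_len=[5.0]))
        kept4, _ = filter_et(et_table(saccade_len=[4.0]))
        assert len(kept5) == 0
        assert len(kept4) == 1

    def test_blink_excluded(self):
        kept, rep = filter_et(et_table(blink=[True]))
        assert len(kept) == 0
        assert rep["blink"] == 1

    def test_clean_fixation_retained(self):
        kept, _ = filter_et(et_table())
        assert len(kept) == 1

    def test_unfixated_excluded(self):
        kept, rep = filter_et(et_table(fixated=[False]))
        assert len(kept) == 0
        assert rep["unfixated"] == 1

    def test_idempotent(self):
        df = pd.concat(
            [et_table(), et_table(blink=[True]), et_table(saccade_len=[9.0])],
            ignore_index=True,
        )
        kept, rep = filter_et(df)
        kept2, _ = filter_et(kept)
        pd.testing.assert_frame_equal(kept, kept2)
        assert rep["input_rows"] - rep["output_rows"] == 2


class TestSplitByRegression:
    def test_indicator_masking_and_conservation(self):
        df = pd.DataFrame({"p": [3.0, 3.0, -1.5], "in_regression": [True, False, True]})
        out = split_by_regression(df, ["p"])
        assert out["p_plusreg"].tolist() == [3.0, 0.0, -1.5]
        assert out["p_minusreg"].tolist() == [0.0, 3.0, 0.0]
        np.testing.assert_allclose(out["p_plusreg"] + out["p_minusreg"], df["p"])

    def test_missing_indicator_rejected(self):
        with pytest.raises(ValueError, match="in_regression"):
            split_by_regression(pd.DataFrame({"p": [1.0]}), ["p"])
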
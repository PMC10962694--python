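"""Domain containers, delay arithmetic, dataset partitioning, and exclusion filters.

The package works on two delimited tables:

* an **event table** — one row per stimulus event, with a series identifier,
  a timestamp in seconds, and K numeric predictor columns;
* a **response table** — one row per response sample, with a series
  identifier, a timestamp in seconds, one or more numeric response columns,
  and optional categorical grouping columns (e.g. participant).

Both are ordinary :class:`pandas.DataFrame` objects throughout; the light
dataclasses here exist to make invariants explicit and to give the numeric
core typed views of one series at a time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRAIN = "train"
EXPLORATORY = "exploratory"
TEST = "test"
UNASSIGNED = "unassigned"

#: default mapping from ``(e + u) mod 4`` to partition labels: outputs 0 and 1
#: go to training, 2 to the exploratory set, 3 to the test set.
DEFAULT_LABEL_MAP = {0: TRAIN, 1: TRAIN, 2: EXPLORATORY, 3: TEST}


@dataclass
class EventSeries:
    """Timestamped predictor vectors for one stimulus stream.

    Attributes
    ----------
    series_id : hashable
        Identifier shared with the response samples convolved against it.
    t : ndarray, shape (N,)
        Event timestamps in seconds, nondecreasing. Simultaneous events are
        permitted and order-stable.
    X : ndarray, shape (N, K)
        Predictor values; no missing entries.
    predictor_names : tuple of str
    """

    series_id: object
    t: np.ndarray
    X: np.ndarray
    predictor_names: tuple

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != self.t.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but t has {self.t.shape[0]} entries"
            )
        if self.X.shape[1] != len(self.predictor_names):
            raise ValueError("predictor_names length does not match X columns")
        if self.X.shape[1] < 1:
            raise ValueError("at least one predictor is required")
        if np.isnan(self.X).any():
            raise ValueError("X contains missing values")
        if self.t.size and np.any(np.diff(self.t) < 0):
            raise ValueError("event timestamps must be nondecreasing")

    @property
    def n_events(self) -> int:
        return self.t.shape[0]


@dataclass
class ResponseSample:
    """One response observation at time ``tau`` with random-effects levels."""

    series_id: object
    tau: float
    y: np.ndarray
    z: dict = field(default_factory=dict)  # grouping factor -> level
    partition_label: str = UNASSIGNED

    def __post_init__(self):
        self.y = np.atleast_1d(np.asarray(self.y, dtype=float))
        if self.y.size < 1:
            raise ValueError("response must have at least one dimension")


@dataclass
class PartitionConfig:
    """How to cycle response units through the modulus-4 partition."""

    scheme: str = "sentence_cycle"  # or "chunk_cycle"
    chunk_len: int = 15
    label_map: dict = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))

    def __post_init__(self):
        if self.scheme not in ("sentence_cycle", "chunk_cycle"):
            raise ValueError(f"unknown partition scheme {self.scheme!r}")
        if self.scheme == "chunk_cycle" and self.chunk_len < 1:
            raise ValueError("chunk_len must be a positive integer")
        if set(self.label_map) != {0, 1, 2, 3}:
            raise ValueError("label_map must cover modulus outputs 0..3")


def compute_delays(events: EventSeries, tau: float) -> np.ndarray:
    """Signed delays ``d_n = tau - t_n`` between a response and each event.

    Negative entries indicate events in the future of the response; an empty
    series yields an empty vector.
    """
    return np.asarray(tau, dtype=float) - events.t


def assign_partition_sentence(e: int, u: int, label_map: dict | None = None) -> str:
    """Partition label for sentence ``e`` seen by participant ``u``.

    Cycles ``(e + u) mod 4`` through the label map so that every participant
    sees a different phase of the sentence cycle.
    """
    if e < 0 or u < 0:
        raise ValueError("sentence and participant indices must be nonnegative")
    label_map = DEFAULT_LABEL_MAP if label_map is None else label_map
    return label_map[(int(e) + int(u)) % 4]


def assign_partition_chunk(
    sample_index: int, u: int, chunk_len: int = 15, label_map: dict | None = None
) -> str:
    """Partition label for fixed-interval sample ``sample_index`` of participant ``u``.

    Consecutive runs of ``chunk_len`` samples share a label; chunks cycle
    through the modulus-4 map as ``(floor(i / chunk_len) + u) mod 4``.
    """
    if chunk_len < 1:
        raise ValueError("chunk_len must be a positive integer")
    if sample_index < 0 or u < 0:
        raise ValueError("indices must be nonnegative")
    label_map = DEFAULT_LABEL_MAP if label_map is None else label_map
    return label_map[(int(sample_index) // int(chunk_len) + int(u)) % 4]


def partition_responses(
    responses: pd.DataFrame,
    config: PartitionConfig,
    participant_col: str,
    unit_col: str | None = None,
) -> pd.DataFrame:
    """Attach a ``partition`` column to a response table.

    For ``sentence_cycle``, ``unit_col`` names the sentence-index column. For
    ``chunk_cycle``, samples are numbered 0.. within each participant in row
    order and chunked. Participants are phased by their rank order.
    """
    out = responses.copy()
    u_codes = pd.Categorical(out[participant_col]).codes.astype(int)
    if config.scheme == "sentence_cycle":
        if unit_col is None:
            raise ValueError("sentence_cycle requires unit_col (sentence index)")
        e = out[unit_col].to_numpy(dtype=int)
        mod = (e + u_codes) % 4
    else:
        idx = out.groupby(participant_col, sort=False).cumcount().to_numpy()
        mod = (idx // config.chunk_len + u_codes) % 4
    out["partition"] = pd.Series(mod, index=out.index).map(config.label_map)
    return out


def _require_columns(df: pd.DataFrame, cols, what: str):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table is missing required column(s): {missing}")


def filter_spr(
    df: pd.DataFrame,
    question_miss_counts: dict,
    duration_col: str = "duration_ms",
    participant_col: str = "participant",
    sent_start_col: str = "sentence_start",
    sent_end_col: str = "sentence_end",
    min_ms: float = 100.0,
    max_ms: float = 3000.0,
    max_missed: int = 4,
    min_responses: int = 100,
) -> tuple[pd.DataFrame, dict]:
    """Exclusion rules for self-paced-reading tables.

    Removes rows whose duration is shorter than 100 ms or longer than 3000 ms
    (strict bounds), rows that start or end a sentence, all rows of
    participants who missed 4 or more subsequent comprehension questions, and
    finally all rows of participants left with fewer than 100 responses after
    the other filters. Returns the filtered table and a per-rule report.
    Because the order of the sentence-boundary rule relative to the
    100-response count is underdetermined, the report carries the participant
    counts under both orders.
    """
    _require_columns(
        df, [duration_col, participant_col, sent_start_col, sent_end_col], "SPR"
    )
    report: dict = {"input_rows": len(df)}

    dur = df[duration_col].to_numpy(dtype=float)
    bad_dur = (dur < min_ms) | (dur > max_ms)
    report["duration"] = int(bad_dur.sum())
    kept = df.loc[~bad_dur]

    boundary = kept[sent_start_col].astype(bool) | kept[sent_end_col].astype(bool)
    report["sentence_boundary"] = int(boundary.sum())
    kept = kept.loc[~boundary]

    missed = kept[participant_col].map(lambda p: question_miss_counts.get(p, 0))
    bad_q = missed >= max_missed
    report["missed_questions_rows"] = int(bad_q.sum())
    report["missed_questions_participants"] = int(
        kept.loc[bad_q, participant_col].nunique()
    )
    kept = kept.loc[~bad_q]

    counts = kept[participant_col].value_counts()
    few = counts[counts < min_responses].index
    report["few_responses_rows"] = int(kept[participant_col].isin(few).sum())
    report["few_responses_participants"] = len(few)
    kept = kept.loc[~kept[participant_col].isin(few)]

    # alternative order: count responses before the boundary rule
    pre_bound = df.loc[~bad_dur]
    pre_missed = pre_bound[participant_col].map(
        lambda p: question_miss_counts.get(p, 0)
    )
    pre_counts = pre_bound.loc[pre_missed < max_missed, participant_col].value_counts()
    report["few_responses_participants_pre_boundary"] = int(
        (pre_counts < min_responses).sum()
    )

    report["output_rows"] = len(kept)
    return kept, report


def filter_et(
    df: pd.DataFrame,
    fixated_col: str = "fixated",
    saccade_len_col: str = "saccade_len",
    blink_col: str = "blink",
    boundary_cols: tuple = (
        "sentence_start",
        "sentence_end",
        "screen_start",
        "screen_end",
        "document_start",
        "document_end",
        "line_start",
        "line_end",
    ),
    max_saccade: float = 4.0,
) -> tuple[pd.DataFrame, dict]:
    """Exclusion rules for eye-tracking fixation tables.

    Removes unfixated items, items following saccades strictly longer than 4
    words, items starting or ending a sentence/screen/document/line, and items
    whose duration included a blink.
    """
    _require_columns(df, [fixated_col, saccade_len_col, blink_col], "eye-tracking")
    present_bounds = [c for c in boundary_cols if c in df.columns]
    report: dict = {"input_rows": len(df)}

    unfix = ~df[fixated_col].astype(bool)
    report["unfixated"] = int(unfix.sum())
    kept = df.loc[~unfix]

    long_sacc = kept[saccade_len_col].to_numpy(dtype=float) > max_saccade
    report["long_saccade"] = int(long_sacc.sum())
    kept = kept.loc[~long_sacc]

    if present_bounds:
        boundary = kept[list(present_bounds)].astype(bool).any(axis=1)
    else:
        boundary = pd.Series(False, index=kept.index)
    report["boundary"] = int(boundary.sum())
    kept = kept.loc[~boundary]

    blink = kept[blink_col].astype(bool)
    report["blink"] = int(blink.sum())
    kept = kept.loc[~blink]

    report["output_rows"] = len(kept)
    return kept, report


def split_by_regression(
    df: pd.DataFrame,
    predictor_names,
    in_regression_col: str = "in_regression",
    suffixes: tuple = ("_plusreg", "_minusreg"),
) -> pd.DataFrame:
    """Partition each predictor into in-regression and out-of-regression variants.

    Each predictor ``p`` becomes ``p_plusreg`` (its value on rows inside a
    regressive eye movement, 0 elsewhere) and ``p_minusreg`` (the complement),
    so the two variants sum to the original column.
    """
    if in_regression_col not in df.columns:
        raise ValueError(f"missing in-regression column {in_regression_col!r}")
    _require_columns(df, predictor_names, "predictor")
    out = df.copy()
    mask = df[in_regression_col].astype(bool).to_numpy()
    for p in predictor_names:
        vals = df[p].to_numpy(dtype=float)
        out[p + suffixes[0]] = np.where(mask, vals, 0.0)
        out[p + suffixes[1]] = np.where(mask, 0.0, vals)
    return out


def read_events(
    path,
    series_col: str = "series_id",
    time_col: str = "time",
    predictors=None,
    sep: str = ",",
) -> pd.DataFrame:
    """Read an event table from delimited text and validate required columns."""
    df = pd.read_csv(path, sep=sep)
    _require_columns(df, [series_col, time_col], "event")
    if predictors is not None:
        _require_columns(df, predictors, "event")
    return df


def read_responses(
    path,
    series_col: str = "series_id",
    time_col: str = "time",
    response=None,
    groups=(),
    sep: str = ",",
) -> pd.DataFrame:
    """Read a response table from delimited text and validate required columns."""
    df = pd.read_csv(path, sep=sep)
    need = [series_col, time_col] + list(groups)
    if response is not None:
        need.append(response)
    _require_columns(df, need, "response")
    return df


def events_from_frame(
    df: pd.DataFrame, predictors, series_col="series_id", time_col="time"
) -> dict:
    """Split an event table into :class:`EventSeries`, keyed by series id."""
    out = {}
    for sid, grp in df.groupby(series_col, sort=False):
        grp = grp.sort_values(time_col, kind="stable")
        out[sid] = EventSeries(
            series_id=sid,
            t=grp[time_col].to_numpy(dtype=float),
            X=grp[list(predictors)].to_numpy(dtype=float),
            predictor_names=tuple(predictors),
        )
    return out
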
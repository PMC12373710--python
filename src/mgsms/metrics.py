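"""Microstate parameters: occurrence, coverage, duration, transitions.

For a state with segments totalling T_k seconds (n_k segments) inside a
window of length T seconds:

    coverage   = T_k / T          (fraction of the window)
    occurrence = n_k / T          (segments per second)
    duration   = T_k / n_k        (mean segment length; 0 when n_k = 0)

so that coverage = occurrence x duration (in seconds) holds exactly.
Segments truncated by a window boundary count toward coverage and duration,
but a boundary never creates a transition: transition counts c(i -> j) are
adjacent within-window segment pairs, and TP(i -> j) = c(i -> j) / sum_j
c(i -> j).  Rows with no outgoing transition are undefined (NaN), never
zero-filled, and are excluded from aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import EPOCH_LEN, EPOCH_PRE, INTERVALS
from .segmentation import LabelSequence


@dataclass(frozen=True)
class TransitionMatrix:
    """Conditional transition probabilities with their raw counts."""

    probs: np.ndarray  # (K, K), NaN rows where undefined
    counts: np.ndarray  # (K, K) integer counts
    states: tuple[str, ...]
    mode: str


def interval_bounds(fs: float) -> dict[str, tuple[int, int]]:
    """Half-open sample ranges of the three analysis intervals in an epoch."""
    b0 = int(round(EPOCH_PRE * fs))
    b1 = int(round((EPOCH_PRE + 0.3) * fs))
    b2 = int(round(EPOCH_LEN * fs))
    return {"fixation": (0, b0), "visual": (b0, b1), "memory": (b1, b2)}


def slice_interval(seq: LabelSequence, interval: str) -> LabelSequence:
    """Restrict an epoch's labels to one analysis interval.

    Segments are re-derived with truncation at the boundaries; concatenating
    the three slices reconstructs the epoch labels exactly.
    """
    if interval not in INTERVALS:
        raise ValueError(f"unknown interval: {interval!r}")
    lo, hi = interval_bounds(seq.fs)[interval]
    return LabelSequence(
        labels=seq.labels[lo:hi], fs=seq.fs, mode=seq.mode, states=seq.states
    )


def params(seq: LabelSequence) -> pd.DataFrame:
    """Occurrence/coverage/duration table, one row per state."""
    if seq.n_samples == 0:
        raise ValueError("empty label sequence")
    total_s = seq.n_samples / seq.fs
    dwell = np.zeros(len(seq.states))
    nseg = np.zeros(len(seq.states), dtype=int)
    for state, _, length in seq.segments:
        dwell[state] += length / seq.fs
        nseg[state] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        duration = np.where(nseg > 0, dwell / np.maximum(nseg, 1), 0.0)
    return pd.DataFrame(
        {
            "state": list(seq.states),
            "occurrence": nseg / total_s,
            "coverage": dwell / total_s,
            "duration_ms": duration * 1000.0,
            "n_segments": nseg,
        }
    )


def transitions(seq: LabelSequence) -> TransitionMatrix:
    """Conditional segment-to-segment transition probabilities."""
    segs = seq.segments
    if not segs:
        raise ValueError("label sequence has no segments")
    k = len(seq.states)
    counts = np.zeros((k, k), dtype=np.int64)
    for (a, _, _), (b, _, _) in zip(segs, segs[1:]):
        counts[a, b] += 1
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = counts / row_sums
    probs[row_sums.ravel() == 0] = np.nan
    return TransitionMatrix(
        probs=probs, counts=counts, states=seq.states, mode=seq.mode
    )


# ---------------------------------------------------------------------------
# tidy tables across trials


def params_table(
    sequences: dict[tuple[int, int], LabelSequence],
    intervals: tuple[str, ...] = INTERVALS,
) -> pd.DataFrame:
    """Tidy per-(subject, trial, interval, state) parameter table.

    ``sequences`` maps (subject, trial) to that epoch's label sequence.
    """
    frames = []
    for (subject, trial), seq in sequences.items():
        for interval in intervals:
            part = params(slice_interval(seq, interval))
            part.insert(0, "interval", interval)
            part.insert(0, "trial", trial)
            part.insert(0, "subject", subject)
            frames.append(part)
    if not frames:
        return pd.DataFrame(
            columns=["subject", "trial", "interval", "state", "occurrence",
                     "coverage", "duration_ms", "n_segments"]
        )
    return pd.concat(frames, ignore_index=True)


def tp_table(
    sequences: dict[tuple[int, int], LabelSequence],
    intervals: tuple[str, ...] = ("memory",),
) -> pd.DataFrame:
    """Tidy per-(subject, trial, interval, from, to) transition table.

    Undefined rows (no outgoing transition) appear as NaN probabilities.
    """
    rows = []
    for (subject, trial), seq in sequences.items():
        for interval in intervals:
            tm = transitions(slice_interval(seq, interval))
            for i, src in enumerate(tm.states):
                for j, dst in enumerate(tm.states):
                    if i == j:
                        continue
                    rows.append(
                        {
                            "subject": subject,
                            "trial": trial,
                            "interval": interval,
                            "from": src,
                            "to": dst,
                            "tp": tm.probs[i, j],
                            "count": int(tm.counts[i, j]),
                        }
                    )
    return pd.DataFrame(rows)


_GROUPERS = {
    "subject": ["subject"],
    "subject_position": ["subject", "target_index"],
    "subject_condition": ["subject", "condition"],
    "subject_error_group": ["subject", "error_group"],
}


def aggregate(
    table: pd.DataFrame,
    by: str,
    value_cols: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Average per-trial parameters within groups.

    ``by`` is one of subject, subject_position, subject_condition,
    subject_error_group.  NaN values (undefined TP rows) are excluded from
    the mean rather than treated as zero; empty groups are dropped.  The
    group size is reported as ``n_trials``.
    """
    if by not in _GROUPERS:
        raise ValueError(f"unknown grouping: {by!r}")
    keys = _GROUPERS[by]
    extra = [c for c in ("interval", "state", "from", "to") if c in table.columns]
    keys = keys + extra
    if value_cols is None:
        value_cols = tuple(
            c
            for c in ("occurrence", "coverage", "duration_ms", "tp", "error_dva")
            if c in table.columns
        )
    grouped = table.groupby(keys, dropna=False, observed=True)
    out = grouped[list(value_cols)].mean().reset_index()
    out["n_trials"] = grouped["trial"].nunique().to_numpy() if "trial" in table else grouped.size().to_numpy()
    return out
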
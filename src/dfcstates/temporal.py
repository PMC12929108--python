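"""Temporal properties of per-subject connectivity-state sequences.

Fractional windows (FW, per-state proportion of a subject's windows), mean
dwell time (MDT, mean length of maximal consecutive runs in a state, in
window units; states never visited contribute 0) and the number of
state-to-state transitions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StateTimeline",
    "TemporalSummary",
    "run_length_encode",
    "fractional_windows",
    "mean_dwell_time",
    "n_transitions",
    "summarize_timeline",
    "timelines_from_labels",
    "temporal_metrics_table",
]


@dataclass
class StateTimeline:
    """Ordered state labels (1..K) over one subject's windows."""

    subject_id: str
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.size == 0:
            raise ValueError("timeline must be nonempty")
        if self.labels.min() < 1:
            raise ValueError("state labels must be 1-based")


@dataclass
class TemporalSummary:
    subject_id: str
    fractional_windows: np.ndarray  # length K, sums to 1
    mean_dwell_time: np.ndarray  # length K, window units
    n_transitions: int


def run_length_encode(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(run values, run lengths) of the maximal constant runs in ``labels``."""
    labels = np.asarray(labels)
    change = np.flatnonzero(np.diff(labels) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [labels.size]))
    return labels[starts], ends - starts


def _check_labels(timeline: StateTimeline, k: int) -> np.ndarray:
    if timeline.labels.max() > k:
        raise ValueError(f"timeline contains a state above K={k}")
    return timeline.labels


def fractional_windows(timeline: StateTimeline, k: int) -> np.ndarray:
    """Per-state share of the subject's windows (sums to 1)."""
    labels = _check_labels(timeline, k)
    counts = np.bincount(labels, minlength=k + 1)[1 : k + 1]
    return counts / labels.size


def mean_dwell_time(timeline: StateTimeline, k: int) -> np.ndarray:
    """Mean maximal-run length per state, in window units (0 if never visited).

    Boundary-truncated runs (at the start or end of the scan) are included.
    """
    labels = _check_labels(timeline, k)
    values, lengths = run_length_encode(labels)
    out = np.zeros(k)
    for s in range(1, k + 1):
        mask = values == s
        if mask.any():
            out[s - 1] = lengths[mask].mean()
    return out


def n_transitions(timeline: StateTimeline) -> int:
    """Number of positions where the state changes between adjacent windows."""
    return int(np.count_nonzero(np.diff(timeline.labels)))


def summarize_timeline(timeline: StateTimeline, k: int) -> TemporalSummary:
    return TemporalSummary(
        subject_id=timeline.subject_id,
        fractional_windows=fractional_windows(timeline, k),
        mean_dwell_time=mean_dwell_time(timeline, k),
        n_transitions=n_transitions(timeline),
    )


def timelines_from_labels(
    labels: np.ndarray, row_index: list[tuple[str, int]]
) -> list[StateTimeline]:
    """Split pooled (subject, window)-indexed labels into per-subject timelines.

    Window order within each subject follows the window number in
    ``row_index``; subject order follows first appearance.
    """
    labels = np.asarray(labels)
    order: dict[str, list[tuple[int, int]]] = {}
    for i, (sid, w) in enumerate(row_index):
        order.setdefault(sid, []).append((w, i))
    timelines = []
    for sid, pairs in order.items():
        pairs.sort()
        timelines.append(StateTimeline(sid, labels[[i for _, i in pairs]]))
    return timelines


def temporal_metrics_table(
    timelines: list[StateTimeline],
    k: int,
    manifest: pd.DataFrame | None = None,
    repetition_time: float | None = None,
) -> pd.DataFrame:
    """Tidy per-subject table: FW_s, MDT_s (windows) and transition count.

    With ``repetition_time`` given, MDT is also emitted in seconds
    (``MDT_sec_s = MDT_s * TR``) as a convenience column.
    """
    rows = []
    for tl in timelines:
        s = summarize_timeline(tl, k)
        row: dict = {"subject_id": s.subject_id}
        for i in range(k):
            row[f"FW_{i + 1}"] = s.fractional_windows[i]
        for i in range(k):
            row[f"MDT_{i + 1}"] = s.mean_dwell_time[i]
        if repetition_time is not None:
            for i in range(k):
                row[f"MDT_sec_{i + 1}"] = s.mean_dwell_time[i] * repetition_time
        row["n_transitions"] = s.n_transitions
        rows.append(row)
    table = pd.DataFrame(rows)
    if manifest is not None:
        table = manifest.merge(table, on="subject_id", how="right")
    return table
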
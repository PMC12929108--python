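"""Sliding-window functional connectivity.

Per-subject rectangular (boxcar) windows over ROI time series, windowed
Pearson correlation matrices, the Fisher z (arctanh) transform, and the
dFC variability map (entrywise standard deviation of z across windows).
Windows are 0-based and half-open: window ``i`` covers rows
``[i*step, i*step + width)``.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import detrend as _linear_detrend

logger = logging.getLogger(__name__)

__all__ = [
    "InputError",
    "ROITimeSeries",
    "WindowSpec",
    "WindowedFC",
    "FisherZSeries",
    "DFCVariabilityMap",
    "extract_windows",
    "window_correlation",
    "fisher_z",
    "sliding_window_fc",
    "fisher_z_series",
    "dfc_variability",
    "read_roi_table",
    "save_z_series",
    "load_z_series",
]

#: |r| is clipped to this bound before arctanh so z stays finite
R_CLIP = 1.0 - 1e-7


class InputError(ValueError):
    """Invalid input data or window specification."""


@dataclass
class ROITimeSeries:
    """One subject's T x N ROI time-series matrix."""

    subject_id: str
    data: np.ndarray
    roi_labels: list[str]
    repetition_time: float = 2.64  # seconds per volume

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise InputError("time series must be a T x N matrix with T >= 2")
        if not np.all(np.isfinite(self.data)):
            t, n = np.argwhere(~np.isfinite(self.data))[0]
            raise InputError(
                f"subject {self.subject_id}: non-finite value at row {t}, column {n}"
            )
        if len(self.roi_labels) != self.data.shape[1]:
            raise InputError("roi_labels length must match the number of columns")
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise InputError("roi_labels must be unique")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    def detrended(self) -> "ROITimeSeries":
        """Linearly detrended copy (optional upstream-style cleanup)."""
        return ROITimeSeries(
            self.subject_id,
            _linear_detrend(self.data, axis=0),
            list(self.roi_labels),
            self.repetition_time,
        )


@dataclass
class WindowSpec:
    """Sliding-window geometry in TR units (defaults: width 30, step 1)."""

    width: int = 30
    step: int = 1

    def __post_init__(self) -> None:
        if self.width < 2:
            raise InputError("window width must be at least 2")
        if self.step < 1:
            raise InputError("window step must be at least 1")

    def n_windows(self, n_timepoints: int) -> int:
        if self.width > n_timepoints:
            raise InputError(
                f"window width {self.width} exceeds series length {n_timepoints}"
            )
        return (n_timepoints - self.width) // self.step + 1

    def start_indices(self, n_timepoints: int) -> np.ndarray:
        return np.arange(self.n_windows(n_timepoints)) * self.step


@dataclass
class WindowedFC:
    """Per-window N x N Pearson correlation matrices for one subject."""

    subject_id: str
    windows: np.ndarray  # W x N x N
    window_start_indices: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]


@dataclass
class FisherZSeries:
    """Fisher-z transformed windowed connectivity (zero diagonal)."""

    subject_id: str
    z: np.ndarray  # W x N x N
    window_start_indices: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.z.shape[0]


@dataclass
class DFCVariabilityMap:
    """Entrywise SD of z over windows — the subject's dFC variability."""

    subject_id: str
    sd_matrix: np.ndarray


def extract_windows(series: ROITimeSeries, spec: WindowSpec) -> list[np.ndarray]:
    """Slice the series into ``floor((T - width)/step) + 1`` boxcar segments."""
    starts = spec.start_indices(series.n_timepoints)
    return [series.data[s : s + spec.width] for s in starts]


def window_correlation(segment: np.ndarray) -> np.ndarray:
    """Pearson correlation across columns of one window segment.

    Zero-variance columns cannot carry a correlation; their rows/columns are
    set to 0 (diagonal kept at 1) and a warning is logged, so downstream
    clustering never sees non-finite values.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.shape[0] < 2:
        raise InputError("window segments need at least 2 rows")
    sd = segment.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning(
            "zero-variance column(s) %s in window; correlations set to 0",
            np.flatnonzero(degenerate).tolist(),
        )
        segment = segment.copy()
        # unit noise placeholder avoids 0/0; entries are overwritten below
        segment[:, degenerate] = np.arange(segment.shape[0])[:, None]
    r = np.corrcoef(segment, rowvar=False)
    if degenerate.any():
        r[degenerate, :] = 0.0
        r[:, degenerate] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return (r + r.T) / 2.0


def fisher_z(r_matrix: np.ndarray) -> np.ndarray:
    """arctanh of the off-diagonal entries, |r| clipped to 1 - 1e-7; zero diagonal."""
    r = np.asarray(r_matrix, dtype=float)
    if np.any(np.abs(r) > 1.0 + 1e-12):
        raise InputError("correlation entries must lie in [-1, 1]")
    z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    np.fill_diagonal(z, 0.0)
    return z


def sliding_window_fc(series: ROITimeSeries, spec: WindowSpec) -> WindowedFC:
    """Windowed Pearson connectivity for one subject."""
    segments = extract_windows(series, spec)
    mats = np.stack([window_correlation(seg) for seg in segments])
    return WindowedFC(
        subject_id=series.subject_id,
        windows=mats,
        window_start_indices=spec.start_indices(series.n_timepoints),
    )


def fisher_z_series(wfc: WindowedFC) -> FisherZSeries:
    """Fisher-z transform each window of a :class:`WindowedFC`."""
    z = np.stack([fisher_z(m) for m in wfc.windows])
    return FisherZSeries(
        subject_id=wfc.subject_id,
        z=z,
        window_start_indices=np.asarray(wfc.window_start_indices),
    )


def dfc_variability(z_series: FisherZSeries) -> DFCVariabilityMap:
    """Entrywise sample SD (ddof=1) of z across windows."""
    if z_series.n_windows < 2:
        raise InputError("dFC variability needs at least 2 windows")
    sd = z_series.z.std(axis=0, ddof=1)
    np.fill_diagonal(sd, 0.0)
    return DFCVariabilityMap(subject_id=z_series.subject_id, sd_matrix=sd)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_roi_table(
    path: str | Path, subject_id: str | None = None, repetition_time: float = 2.64
) -> ROITimeSeries:
    """Read a delimited ROI time-series table (header row = ROI labels)."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    if df.isna().any().any():
        rows, cols = np.where(df.isna().to_numpy())
        raise InputError(
            f"{path.name}: missing/NaN cell at row {rows[0]}, column {df.columns[cols[0]]!r}"
        )
    return ROITimeSeries(
        subject_id=subject_id or path.stem,
        data=df.to_numpy(dtype=float),
        roi_labels=[str(c) for c in df.columns],
        repetition_time=repetition_time,
    )


def save_z_series(z_series: FisherZSeries, directory: str | Path, spec: WindowSpec) -> Path:
    """Persist a z-series as NPZ with a JSON sidecar (shape, window spec, id)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    npz = directory / f"{z_series.subject_id}_z.npz"
    np.savez_compressed(
        npz, z=z_series.z.astype(np.float32), starts=z_series.window_start_indices
    )
    sidecar = {
        "subject_id": z_series.subject_id,
        "shape": list(z_series.z.shape),
        "window_width": spec.width,
        "window_step": spec.step,
    }
    npz.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return npz


def load_z_series(npz_path: str | Path) -> FisherZSeries:
    npz_path = Path(npz_path)
    sidecar = json.loads(npz_path.with_suffix(".json").read_text())
    with np.load(npz_path) as payload:
        return FisherZSeries(
            subject_id=sidecar["subject_id"],
            z=payload["z"].astype(np.float64),
            window_start_indices=payload["starts"],
        )
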
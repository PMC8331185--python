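"""Fluorescence trace processing: dF/F normalization, smoothing, peak
detection, raster construction, and paired peak-train correlation.

Conventions: frames are 0-based; the baseline F0 is the mean of the first
``f0_frames`` (default 50) raw values; peak thresholds default to
``k`` x MAD above a running-median baseline because published recordings
used manually chosen thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import find_peaks

from .errors import (
    DataError,
    DegenerateBaselineError,
    InsufficientDataError,
    UndefinedStatisticError,
    ValidationError,
)


@dataclass
class Trace:
    """A per-frame fluorescence trace (arbitrary units or dF/F)."""

    values: np.ndarray
    fps: float = 2.0
    label: str = ""
    channel: str = "green"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValidationError("trace must be a non-empty 1-D array")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class PeakTrain:
    """Strictly increasing peak frame indices from one trace."""

    peak_frames: np.ndarray
    threshold_used: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.peak_frames = np.asarray(self.peak_frames, dtype=int)
        if self.peak_frames.size and np.any(np.diff(self.peak_frames) <= 0):
            raise ValidationError("peak frames must be strictly increasing")

    def __len__(self) -> int:
        return self.peak_frames.size

    def indicator(self, n_frames: int) -> np.ndarray:
        if self.peak_frames.size and self.peak_frames.max() >= n_frames:
            raise ValidationError("peak frame beyond n_frames")
        v = np.zeros(n_frames, dtype=np.uint8)
        v[self.peak_frames] = 1
        return v


@dataclass
class Raster:
    """Binary source x frame matrix of activity peaks."""

    rows: list[str]
    matrix: np.ndarray
    fps: float = 2.0


def delta_f_over_f(trace: Trace, f0_frames: int = 50) -> Trace:
    """Normalize a raw trace to (F - F0)/F0 with F0 the mean of the first
    ``f0_frames`` values."""
    if len(trace) < f0_frames:
        raise InsufficientDataError(
            f"trace has {len(trace)} frames < f0_frames={f0_frames}"
        )
    f0 = float(np.mean(trace.values[:f0_frames]))
    if f0 == 0.0:
        raise DegenerateBaselineError("F0 is zero")
    return Trace((trace.values - f0) / f0, trace.fps, trace.label, trace.channel)


def moving_average(trace: Trace, window: int = 100) -> Trace:
    """Centered moving mean; edge windows shrink symmetrically so the length
    is preserved without padding with invented data."""
    if window < 1:
        raise ValidationError("window must be >= 1")
    if window > len(trace):
        raise InsufficientDataError(f"window {window} exceeds trace length {len(trace)}")
    sm = (
        pd.Series(trace.values)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return Trace(sm, trace.fps, trace.label, trace.channel)


def detect_peaks(
    trace: Trace,
    threshold: float | None = None,
    k_mad: float = 3.0,
    baseline_window: int = 200,
    min_separation: int = 1,
) -> PeakTrain:
    """Local maxima above threshold, separated by >= ``min_separation`` frames.

    ``threshold`` is an absolute value; when None, the threshold is a
    per-frame ``baseline + k_mad * MAD`` with ``baseline`` a centered
    ``baseline_window``-frame running median and MAD the median absolute
    deviation of the trace around that baseline.
    """
    if min_separation < 1:
        raise ValidationError("min_separation must be >= 1")
    v = trace.values
    if not np.all(np.isfinite(v)):
        raise DataError("trace contains non-finite values")
    if threshold is not None:
        height = np.full_like(v, float(threshold))
        thr_used = float(threshold)
    else:
        baseline = (
            pd.Series(v).rolling(baseline_window, center=True, min_periods=1)
            .median().to_numpy()
        )
        mad = float(np.median(np.abs(v - baseline)))
        height = baseline + k_mad * mad
        thr_used = float(np.median(height))
    peaks, _ = find_peaks(v, height=height, distance=min_separation)
    return PeakTrain(peaks, thr_used, trace.label)


def build_raster(trains: list[PeakTrain], n_frames: int) -> Raster:
    """Stack peak trains into a binary source x frame matrix."""
    mat = np.zeros((len(trains), n_frames), dtype=np.uint8)
    for i, tr in enumerate(trains):
        mat[i] = tr.indicator(n_frames)
    return Raster([tr.label for tr in trains], mat)


def peak_correlation(
    train_a: PeakTrain,
    train_b: PeakTrain,
    n_frames: int,
    tolerance: int = 0,
) -> float:
    """Pearson correlation of the two binarized peak indicator vectors,
    each dilated by +/- ``tolerance`` frames to absorb small timing offsets.

    Raises :class:`UndefinedStatisticError` when either dilated indicator is
    constant (all zeros or all ones) -- the correlation is then undefined,
    which is signaled rather than reported as a number.
    """
    if n_frames <= 1:
        raise InsufficientDataError("n_frames must be > 1")
    if len(train_a) == 0 or len(train_b) == 0:
        raise InsufficientDataError("each train needs at least one peak")
    ia = train_a.indicator(n_frames).astype(bool)
    ib = train_b.indicator(n_frames).astype(bool)
    if tolerance > 0:
        structure = np.ones(2 * tolerance + 1, dtype=bool)
        ia = ndimage.binary_dilation(ia, structure=structure)
        ib = ndimage.binary_dilation(ib, structure=structure)
    ia = ia.astype(float)
    ib = ib.astype(float)
    if ia.std() == 0 or ib.std() == 0:
        raise UndefinedStatisticError("constant indicator: Pearson r undefined")
    return float(np.corrcoef(ia, ib)[0, 1])


@dataclass
class EpochBins:
    """Events grouped into epochs of the pre-ecdysis span."""

    bins: dict[str, np.ndarray]
    n_excluded: int = 0
    boundaries: tuple[float, ...] = field(default_factory=tuple)


def bin_epochs(
    event_frames,
    p0_start: int,
    p1_onset: int,
    boundaries: tuple[float, float] | None = None,
    names: tuple[str, str, str] = ("early", "mid", "late"),
) -> EpochBins:
    """Assign event frames to early/mid/late epochs of [p0_start, p1_onset).

    Default boundaries are the tertiles of the span.  Bins are half-open;
    an event exactly on a boundary goes to the later bin.  Events at or
    after ``p1_onset`` (or before ``p0_start``) are excluded and counted.
    """
    if p1_onset <= p0_start:
        raise ValidationError("p1_onset must follow p0_start")
    frames = np.asarray(event_frames, dtype=float)
    if boundaries is None:
        span = p1_onset - p0_start
        boundaries = (p0_start + span / 3.0, p0_start + 2.0 * span / 3.0)
    b1, b2 = boundaries
    if not (p0_start <= b1 <= b2 <= p1_onset):
        raise ValidationError("epoch boundaries must be ordered within the span")
    in_span = (frames >= p0_start) & (frames < p1_onset)
    n_excluded = int((~in_span).sum())
    kept = frames[in_span]
    idx = np.searchsorted(np.array([b1, b2]), kept, side="right")
    bins = {name: kept[idx == i].astype(int) for i, name in enumerate(names)}
    return EpochBins(bins, n_excluded, (b1, b2))
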
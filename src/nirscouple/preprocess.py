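"""Signal cleaning: spike smoothing, motion-artifact correction, decimation, alignment.

The NIRS concentration channels carry two artifact classes that must be
removed before phase analysis: single-sample spikes (suppressed by a 5-s
centered moving average) and step/transient motion artifacts (corrected
locally by cubic smoothing splines on flagged segments). The ABP channel
is decimated from 1000 Hz to the NIRS rate with an anti-aliasing FIR
filter; it is never smoothed with the 5-s window, which would destroy the
0.6-2 Hz cardiac oscillation the coupling analysis needs.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import make_smoothing_spline
from scipy.stats import median_abs_deviation

from .errors import (
    ArtifactSaturationError,
    InsufficientOverlapError,
    InvalidArgumentError,
)
from .timeseries import NIRS_CHANNELS, Recording, TimeSeries

__all__ = [
    "moving_average",
    "spline_motion_correct",
    "downsample",
    "align",
    "preprocess_recording",
]


def moving_average(series: TimeSeries, window: float = 5.0) -> TimeSeries:
    """Centered moving mean with window rounded to the nearest odd sample count.

    Edges use shrinking windows (no padding), so the output has the same
    length and sampling rate as the input.

    Parameters
    ----------
    window : float
        Window width in seconds; must cover at least 2 sample periods and
        not exceed the series length.
    """
    n_win = int(round(window * series.sampling_rate))
    if n_win < 2:
        raise InvalidArgumentError("window must span at least 2 sample periods")
    if n_win > series.n_samples:
        raise InvalidArgumentError("window longer than the series")
    if n_win % 2 == 0:  # nearest odd count
        n_win += 1
    out = (
        pd.Series(series.values)
        .rolling(n_win, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return series.with_values(out)


def _flag_segments(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of ``mask`` as half-open (start, stop) index pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[0::2], idx[1::2]))


def spline_motion_correct(
    series: TimeSeries,
    detection_window: float = 2.0,
    threshold_sd: float = 4.0,
    smoothing_lam: float | None = None,
) -> TimeSeries:
    """Detect and correct step-like motion artifacts with cubic smoothing splines.

    Segments where the moving standard deviation (over ``detection_window``
    seconds) exceeds ``threshold_sd`` times the series' robust scale
    (1.4826 x median absolute deviation) are flagged, then extended forward
    until the local level returns near the pre-artifact baseline (so a
    step-plus-decay transient is covered in full, up to 30 s). Each flagged
    segment is modelled by a cubic smoothing spline which is subtracted;
    the residual is re-leveled onto a linear bridge between the clean
    samples at the segment edges, restoring continuity. Samples outside
    flagged segments are returned unchanged.

    Raises
    ------
    ArtifactSaturationError
        If more than 90% of samples are flagged.
    """
    if detection_window < 1.0:
        raise InvalidArgumentError("detection_window must be >= 1 s")
    x = series.values
    n = x.size
    n_win = max(2, int(round(detection_window * series.sampling_rate)))
    mov_sd = (
        pd.Series(x).rolling(n_win, center=True, min_periods=2).std().to_numpy()
    )
    mov_sd = np.nan_to_num(mov_sd)
    scale = median_abs_deviation(x, scale="normal")
    if scale == 0:
        scale = float(np.std(x)) or 1.0
    mask = mov_sd > threshold_sd * scale
    if not mask.any():
        return series.with_values(x.copy())
    if mask.mean() > 0.9:
        raise ArtifactSaturationError(
            f"{mask.mean():.0%} of {series.label!r} flagged as artifact"
        )

    out = x.copy()
    t = series.times
    k = max(1, int(round(0.25 * series.sampling_rate)))
    w_ext = max(1, int(round(0.5 * series.sampling_rate)))
    max_ext = int(round(30.0 * series.sampling_rate))
    segments = []
    for i0, i1 in _flag_segments(mask):
        left = x[max(0, i0 - k):i0]
        lo = left.mean() if left.size else x[i0:i1].mean()
        # follow a step/decay transient until the level returns to baseline
        j = i1
        while (j + w_ext <= n and j - i1 < max_ext
               and abs(x[j:j + w_ext].mean() - lo) > 2.0 * scale):
            j += w_ext
        if segments and i0 <= segments[-1][1]:
            segments[-1] = (segments[-1][0], max(j, segments[-1][1]))
        else:
            segments.append((i0, j))
    for i0, i1 in segments:
        seg = slice(i0, i1)
        ts, xs = t[seg], x[seg]
        if i1 - i0 >= 5:
            # lam=None: generalized cross-validation picks the smoothing,
            # letting the spline track the artifact (jump included)
            trend = make_smoothing_spline(ts, xs, lam=smoothing_lam)(ts)
        else:
            trend = xs.copy()
        resid = xs - trend
        # anchor levels from the clean neighbours (mean of up to 0.25 s each side)
        k = max(1, int(round(0.25 * series.sampling_rate)))
        left = x[max(0, i0 - k):i0]
        right = x[i1:i1 + k]
        lo = left.mean() if left.size else (right.mean() if right.size else xs.mean())
        hi = right.mean() if right.size else lo
        bridge = np.linspace(lo, hi, i1 - i0)
        out[seg] = resid + bridge
    return series.with_values(out)


def downsample(series: TimeSeries, target_rate: float = 20.0) -> TimeSeries:
    """Anti-aliased decimation to ``target_rate`` (integer factor required).

    A polyphase FIR low-pass (Kaiser window, stopband at the new Nyquist,
    >= 60 dB attenuation) is applied before taking every ``factor``-th
    sample.
    """
    factor = series.sampling_rate / target_rate
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise InvalidArgumentError(
            f"rate {series.sampling_rate} Hz is not an integer multiple of "
            f"{target_rate} Hz"
        )
    factor = int(round(factor))
    if factor == 1:
        return series.with_values(series.values.copy())
    out = signal.resample_poly(series.values, up=1, down=factor,
                               window=("kaiser", 7.0))
    return series.with_values(out, sampling_rate=float(target_rate))


def align(recording: Recording, min_overlap: float = 600.0) -> Recording:
    """Trim all channels to the maximal common time span.

    Channels are assumed to share a nominal common start, so alignment is
    truncation to the shortest channel duration. Raises
    :class:`InsufficientOverlapError` when the common span is below
    ``min_overlap`` seconds (default 10 min).
    """
    common = min(ts.duration for ts in recording.channels.values())
    if common < min_overlap:
        raise InsufficientOverlapError(
            f"common span {common:.1f} s < required {min_overlap:.1f} s"
        )

    def trim(ts: TimeSeries) -> TimeSeries:
        n = int(round(common * ts.sampling_rate))
        return ts.with_values(ts.values[:n])

    return recording.map_channels(trim, operation="align",
                                  min_overlap=min_overlap)


def preprocess_recording(
    recording: Recording,
    smoothing_window: float = 5.0,
    detection_window: float = 2.0,
    threshold_sd: float = 4.0,
    target_rate: float = 20.0,
    min_overlap: float = 600.0,
) -> tuple[Recording, Recording]:
    """Full preprocessing chain for one recording.

    Order: motion-artifact correction on the NIRS channels, 5-s moving
    average on the NIRS channels, decimation of ABP to the NIRS rate,
    alignment. Returns ``(smoothed, corrected_unsmoothed)``: the first is
    the input to phase extraction, the second (artifact-corrected but not
    smoothed) is the input to the tissue-oxygenation computation.
    """
    corrected = recording.map_channels(
        lambda ts: spline_motion_correct(ts, detection_window, threshold_sd),
        labels=NIRS_CHANNELS,
        operation="spline_motion_correct",
        detection_window=detection_window, threshold_sd=threshold_sd,
    )
    smoothed = corrected.map_channels(
        lambda ts: moving_average(ts, smoothing_window),
        labels=NIRS_CHANNELS,
        operation="moving_average", window=smoothing_window,
    )

    def ds(rec: Recording) -> Recording:
        return rec.map_channels(
            lambda ts: downsample(ts, target_rate), labels=["ABP"],
            operation="downsample", target_rate=target_rate,
        )

    return (align(ds(smoothed), min_overlap),
            align(ds(corrected), min_overlap))
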
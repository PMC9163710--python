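"""Tissue oxygenation index (TOI).

TOI = 100 * O2Hb / (O2Hb + HHb), the fraction of total hemoglobin that is
oxygenated, a regional oxygen-saturation surrogate. It requires
absolute-equivalent concentrations (device-exported or synthetic baseline
plus fluctuation); it is undefined for pure zero-mean change signals, so
non-positive denominators are rejected.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, InvalidArgumentError
from .timeseries import TimeSeries

__all__ = ["ToiSummary", "toi_series", "summarize_toi"]


@dataclass(frozen=True)
class ToiSummary:
    """Per-subject TOI summary: left, right and bilateral-mean TOI in %."""

    ltoi: float
    rtoi: float

    @property
    def mean_toi(self) -> float:
        return (self.ltoi + self.rtoi) / 2.0


def toi_series(o2hb: TimeSeries, hhb: TimeSeries) -> TimeSeries:
    """Pointwise 100 * O2Hb / (O2Hb + HHb), in percent.

    Raises
    ------
    InvalidArgumentError
        On mismatched lengths or sampling rates.
    DegenerateInputError
        If the total-hemoglobin denominator is non-positive anywhere; the
        message names the first offending sample index.
    """
    if o2hb.n_samples != hhb.n_samples or o2hb.sampling_rate != hhb.sampling_rate:
        raise InvalidArgumentError("O2Hb and HHb must share length and rate")
    total = o2hb.values + hhb.values
    bad = np.flatnonzero(total <= 0)
    if bad.size:
        raise DegenerateInputError(
            f"non-positive total hemoglobin at sample {bad[0]}"
        )
    return TimeSeries(100.0 * o2hb.values / total, o2hb.sampling_rate,
                      label="TOI", units="%")


def summarize_toi(toi_left: TimeSeries, toi_right: TimeSeries) -> ToiSummary:
    """Time means of the left/right TOI series over the analyzed span."""
    if toi_left.n_samples == 0 or toi_right.n_samples == 0:
        raise InvalidArgumentError("empty TOI series")
    return ToiSummary(float(toi_left.values.mean()),
                      float(toi_right.values.mean()))
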
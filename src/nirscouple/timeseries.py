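"""Basic time-series containers shared across the pipeline.

A :class:`TimeSeries` is a uniformly sampled real-valued signal with a
sampling rate and unit metadata. A :class:`Recording` bundles the five
channels of one subject's session: four NIRS concentration channels at
20 Hz (oxy-/deoxyhemoglobin, left and right prefrontal cortex) and one
continuous arterial-blood-pressure channel at 1000 Hz.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidArgumentError

#: Canonical channel labels of one subject recording.
NIRS_CHANNELS = ("O2Hb_L", "HHb_L", "O2Hb_R", "HHb_R")
ALL_CHANNELS = NIRS_CHANNELS + ("ABP",)


@dataclass
class TimeSeries:
    """Uniformly sampled signal.

    Parameters
    ----------
    values : array of float
        Sample values in ``units``.
    sampling_rate : float
        Samples per second, > 0.
    label : str
        Channel label, e.g. ``"O2Hb_L"``.
    units : str
        Physical units of the samples (``"umol/L"``, ``"mmHg"``, ``"%"``).
    """

    values: np.ndarray
    sampling_rate: float
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InvalidArgumentError("TimeSeries values must be 1-D")
        if not self.sampling_rate > 0:
            raise InvalidArgumentError("sampling_rate must be > 0")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError(
                f"non-finite values in series {self.label!r}"
            )

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        """Span covered by the samples, in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.sampling_rate

    def with_values(self, values: np.ndarray, **meta) -> "TimeSeries":
        """Copy of this series with new values (and optionally new metadata)."""
        return replace(self, values=np.asarray(values, dtype=float), **meta)


@dataclass
class Recording:
    """One subject's synchronized multichannel session.

    ``channels`` maps the canonical labels to series; NIRS channels are
    nominally at 20 Hz and ABP at 1000 Hz until :func:`~nirscouple.preprocess.align`
    brings everything to a common rate. ``provenance`` accumulates a log of
    every operation applied, with parameters, for reproducibility.
    """

    channels: dict[str, TimeSeries]
    subject_id: str = ""
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in ALL_CHANNELS if c not in self.channels]
        if missing:
            raise InvalidArgumentError(f"recording missing channels: {missing}")

    @property
    def duration(self) -> float:
        """Common duration in seconds (minimum across channels)."""
        return min(ts.duration for ts in self.channels.values())

    def log(self, operation: str, **params) -> None:
        self.provenance.append({"operation": operation, **params})

    def map_channels(self, fn, labels=None, operation: str = "", **params) -> "Recording":
        """Return a new Recording with ``fn`` applied to the named channels."""
        labels = set(labels if labels is not None else self.channels)
        new = {
            lab: (fn(ts) if lab in labels else ts)
            for lab, ts in self.channels.items()
        }
        rec = Recording(new, subject_id=self.subject_id,
                        provenance=list(self.provenance))
        if operation:
            rec.log(operation, channels=sorted(labels), **params)
        return rec
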
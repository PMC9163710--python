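"""Instantaneous phase extraction with the complex Morlet wavelet.

Each oscillation of interest lives in a fixed frequency band: very-low
frequency (0.02-0.07 Hz) and low frequency (0.07-0.2 Hz) for the
hemoglobin signals, 0.6-2 Hz for the cardiac component of arterial blood
pressure. The continuous wavelet transform with the complex Morlet mother
wavelet

    psi(u) = pi**(-1/4) * exp(i*2*pi*u) * exp(-u**2 / 2)

is evaluated on a logarithmic frequency grid across the band (scale-to-
frequency map f = 1/s, L2 normalization 1/sqrt(s)); the band's single
phase is the unwrapped argument of the band-averaged complex coefficient.
The analytic sign convention is chosen so that the extracted phase of a
physical oscillation increases with time. Samples within the cone of
influence (sqrt(2)*s seconds at each edge) of the band's lowest frequency
are excluded from the valid span.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientOverlapError, InvalidArgumentError, TooShortError
from .timeseries import TimeSeries

__all__ = [
    "Band", "VLF", "LF", "CARDIAC",
    "WaveletField", "PhaseSeries",
    "morlet_cwt", "band_phase", "common_valid_span", "extract_band_phase",
]


@dataclass(frozen=True)
class Band:
    """A named frequency band [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise InvalidArgumentError("band requires 0 < f_lo < f_hi")


#: Canonical analysis bands.
VLF = Band("VLF", 0.02, 0.07)
LF = Band("LF", 0.07, 0.2)
CARDIAC = Band("CARDIAC", 0.6, 2.0)


@dataclass
class WaveletField:
    """Complex wavelet coefficients of one signal over one band.

    ``coefficients`` has shape (n_frequencies, n_times); ``frequencies``
    is strictly increasing; ``coi_margin`` gives, per frequency, the edge
    margin in seconds inside which coefficients are boundary-contaminated.
    """

    coefficients: np.ndarray
    frequencies: np.ndarray
    coi_margin: np.ndarray
    sampling_rate: float
    band: Band


@dataclass
class PhaseSeries:
    """Unwrapped instantaneous phase of one band of one signal.

    ``phase`` covers the full record; ``valid_span`` = (start, end) in
    seconds marks the cone-trimmed region downstream analysis may use.
    """

    phase: np.ndarray
    sampling_rate: float
    band: Band | None = None
    valid_span: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if self.valid_span is None:
            self.valid_span = (0.0, self.phase.size / self.sampling_rate)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.phase.size) / self.sampling_rate

    def valid_slice(self, span: tuple[float, float] | None = None) -> np.ndarray:
        """Phase samples restricted to ``span`` (default: own valid span)."""
        lo, hi = span if span is not None else self.valid_span
        i0 = int(np.ceil(lo * self.sampling_rate))
        i1 = int(np.floor(hi * self.sampling_rate)) + 1
        return self.phase[i0:min(i1, self.phase.size)]


def _morlet_ft(omega: np.ndarray) -> np.ndarray:
    """Fourier transform of the Morlet mother wavelet (central frequency 1).

    FT convention psi_hat(w) = int psi(u) exp(-i w u) du; supported on
    w > 0 (analytic wavelet, negligible negative-frequency leakage).
    """
    out = np.zeros_like(omega)
    pos = omega > 0
    out[pos] = np.pi ** (-0.25) * np.sqrt(2.0 * np.pi) * np.exp(
        -0.5 * (omega[pos] - 2.0 * np.pi) ** 2
    )
    return out


def morlet_cwt(series: TimeSeries, band: Band,
               voices_per_octave: int = 16) -> WaveletField:
    """Continuous wavelet transform of ``series`` over ``band``.

    The frequency grid is logarithmic with ``voices_per_octave`` voices,
    endpoints inclusive. Computed in the Fourier domain with zero padding
    to the next power of two past twice the record length.

    Raises
    ------
    TooShortError
        If the record is shorter than 3 periods of the band's lowest
        frequency.
    """
    if voices_per_octave < 8:
        raise InvalidArgumentError("voices_per_octave must be >= 8")
    if series.duration < 3.0 / band.f_lo:
        raise TooShortError(
            f"need >= {3.0 / band.f_lo:.0f} s for band {band.name}, "
            f"have {series.duration:.0f} s"
        )
    n_oct = np.log2(band.f_hi / band.f_lo)
    m = int(np.ceil(n_oct * voices_per_octave))
    freqs = band.f_lo * 2.0 ** np.linspace(0.0, n_oct, m + 1)

    n = series.n_samples
    n_fft = int(2 ** np.ceil(np.log2(2 * n)))
    x_hat = np.fft.fft(series.values - series.values.mean(), n_fft)
    omega = 2.0 * np.pi * np.fft.fftfreq(n_fft, d=1.0 / series.sampling_rate)

    coef = np.empty((freqs.size, n), dtype=complex)
    for i, f in enumerate(freqs):
        s = 1.0 / f
        # W(s,.) = IFFT[ x_hat * sqrt(s) * psi_hat(s*omega) ]
        coef[i] = np.fft.ifft(x_hat * np.sqrt(s) * _morlet_ft(s * omega))[:n]
    coi = np.sqrt(2.0) / freqs
    return WaveletField(coef, freqs, coi, series.sampling_rate, band)


def band_phase(field: WaveletField, min_cycles: float = 5.0) -> PhaseSeries:
    """Single unwrapped phase of the band, from the band-averaged coefficient.

    The complex coefficients are averaged across the frequency grid at each
    time point and the phase is the unwrapped argument of that average.
    The valid span excludes the cone-of-influence margin at the band's
    lowest frequency from both edges; if fewer than ``min_cycles`` periods
    of ``f_lo`` remain, a :class:`TooShortError` is raised.
    """
    if field.coefficients.size == 0:
        raise InvalidArgumentError("empty wavelet field")
    avg = field.coefficients.mean(axis=0)
    phase = np.unwrap(np.angle(avg))
    n = phase.size
    margin = float(field.coi_margin.max())  # margin of the lowest frequency
    t_end = (n - 1) / field.sampling_rate
    span = (margin, t_end - margin)
    if span[1] - span[0] < min_cycles / field.band.f_lo:
        raise TooShortError(
            f"valid span {span[1] - span[0]:.0f} s < {min_cycles} cycles of "
            f"{field.band.f_lo} Hz"
        )
    return PhaseSeries(phase, field.sampling_rate, field.band, span)


def common_valid_span(phases: list[PhaseSeries]) -> tuple[float, float]:
    """Intersection of the valid spans of several phase series."""
    if not phases:
        raise InvalidArgumentError("no phase series given")
    rates = [p.sampling_rate for p in phases]
    if max(rates) - min(rates) > 1e-4 * max(rates):
        raise InvalidArgumentError("phase series must share a sampling rate")
    lo = max(p.valid_span[0] for p in phases)
    hi = min(p.valid_span[1] for p in phases)
    if hi <= lo:
        raise InsufficientOverlapError("valid spans do not overlap")
    return (lo, hi)


def extract_band_phase(series: TimeSeries, band: Band,
                       voices_per_octave: int = 16,
                       min_cycles: float = 5.0) -> PhaseSeries:
    """Convenience: CWT + band-averaged phase in one call."""
    return band_phase(morlet_cwt(series, band, voices_per_octave), min_cycles)
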
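"""Welch PSD estimation, band-average power and per-channel power maps.

Signals come in volts; densities go out in µV²/Hz (1 V²/Hz = 1e12 µV²/Hz).
"Band average power" here means the integral of the one-sided density over a
frequency band — a power in µV² — not the mean density value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .recording import EEGRecording, FrequencyBand, ValidationError

V2_TO_UV2 = 1e12


@dataclass(frozen=True)
class WelchParams:
    """Welch estimator settings: 2 s Hamming segments, 50% overlap by default."""

    segment_length_s: float = 2.0
    overlap_fraction: float = 0.5
    window: str = "hamming"
    detrend: str = "constant"

    def __post_init__(self) -> None:
        if not self.segment_length_s > 0:
            raise ValidationError("segment_length_s must be positive")
        if not (0 <= self.overlap_fraction < 1):
            raise ValidationError("overlap_fraction must be in [0, 1)")
        if self.window not in ("hamming", "hann"):
            raise ValidationError(f"unsupported window {self.window!r}")
        if self.detrend not in ("none", "constant"):
            raise ValidationError(f"unsupported detrend {self.detrend!r}")


@dataclass
class PSDEstimate:
    """One-sided Welch PSD: frequency grid in Hz, density in µV²/Hz."""

    freqs: np.ndarray
    density: np.ndarray
    fs: float
    params: WelchParams = field(default_factory=WelchParams)


def welch_psd(x: np.ndarray, fs: float,
              params: WelchParams | None = None) -> PSDEstimate:
    """Averaged modified periodogram of a single-channel signal in volts."""
    params = params or WelchParams()
    x = np.asarray(x, dtype=float)
    nperseg = int(round(params.segment_length_s * fs))
    if x.size < nperseg:
        raise ValidationError(
            f"signal of {x.size} samples is shorter than one Welch segment "
            f"({nperseg} samples)"
        )
    noverlap = int(round(params.overlap_fraction * nperseg))
    detrend = False if params.detrend == "none" else "constant"
    freqs, pxx = signal.welch(x, fs=fs, window=params.window, nperseg=nperseg,
                              noverlap=noverlap, detrend=detrend,
                              scaling="density")
    return PSDEstimate(freqs=freqs, density=pxx * V2_TO_UV2, fs=fs,
                       params=params)


def band_average_power(psd: PSDEstimate, band: FrequencyBand) -> float:
    """Integral of the density over [f_low, f_high], in µV².

    Band edges falling between grid points are included by linear
    interpolation of the bounding bins.
    """
    f, d = psd.freqs, psd.density
    if band.f_low < f[0] or band.f_high > f[-1]:
        raise ValidationError(
            f"band ({band.f_low}, {band.f_high}) Hz outside the PSD grid "
            f"[{f[0]}, {f[-1]}] Hz"
        )
    inside = (f > band.f_low) & (f < band.f_high)
    grid = np.concatenate(([band.f_low], f[inside], [band.f_high]))
    dens = np.concatenate(([np.interp(band.f_low, f, d)], d[inside],
                           [np.interp(band.f_high, f, d)]))
    return float(np.trapezoid(dens, grid))


def channel_power_at_frequency(rec: EEGRecording, f: float,
                               params: WelchParams | None = None) -> np.ndarray:
    """Welch density of each channel, linearly interpolated at frequency ``f``."""
    if not (0 <= f < rec.fs / 2):
        raise ValidationError(f"frequency {f} Hz outside [0, fs/2)")
    out = np.empty(rec.n_channels)
    for i in range(rec.n_channels):
        psd = welch_psd(rec.data[i], rec.fs, params)
        out[i] = np.interp(f, psd.freqs, psd.density)
    return out


def normalized_power_map(values: np.ndarray) -> np.ndarray:
    """Min–max normalization of per-channel power into [0, 1].

    A constant input maps to all zeros (no spatial contrast to display).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("need at least 2 channels to normalize")
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)
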
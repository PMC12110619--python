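"""Bandpass filter design, stability analysis and zero-phase application.

Three families are supported: windowed-sinc FIR, IIR Butterworth and IIR
Chebyshev Type I.  IIR designs are deliberately materialized as single
transfer-function polynomials — numerator over denominator — rather than
second-order sections.  High-order narrowband designs in this representation
are numerically fragile: coefficient round-off pushes poles across the unit
circle well before the ideal (zpk) design would become unstable.  That
fragility is part of the behavior this package models: the optimizer screens
candidates by the pole radii of exactly this polynomial form and discards
the unstable ones, so the maximum usable order is a property of the
representation, not of the ideal prototype.

To the same end, the IIR pipeline performs the classic polynomial-domain
construction: analog lowpass prototype → polynomial transfer function →
lowpass-to-bandpass transform → bilinear transform with cutoff prewarping.

Zero-phase filtering runs the filter forward and backward (the ``filtfilt``
technique), squaring the amplitude response and cancelling phase distortion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
from scipy import signal

from .recording import ValidationError


@dataclass
class FIRFilter:
    """Linear-phase FIR bandpass filter: y[n] = Σ_k h[k]·x[n−k]."""

    h: np.ndarray
    f_low: float
    f_high: float
    fs: float

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        if self.h.ndim != 1 or self.h.size < 2:
            raise ValidationError("FIR coefficient sequence must have length ≥ 2")
        if not np.all(np.isfinite(self.h)):
            raise ValidationError("FIR coefficients must be finite")
        if not np.allclose(self.h, self.h[::-1], atol=1e-12):
            raise ValidationError("FIR coefficients must be symmetric (linear phase)")

    @property
    def order(self) -> int:
        return self.h.size - 1

    @property
    def family(self) -> str:
        return "fir"

    def ba(self) -> tuple[np.ndarray, np.ndarray]:
        return self.h, np.ones(1)

    def to_json(self) -> str:
        return json.dumps({
            "family": "fir", "order": self.order, "f_low": self.f_low,
            "f_high": self.f_high, "fs": self.fs, "h": self.h.tolist(),
        })


@dataclass
class IIRFilterTF:
    """IIR bandpass filter in single transfer-function polynomial form.

    Implements y[n] = Σ_k num[k]·x[n−k] − Σ_{k≥1} den[k]·y[n−k] with the
    denominator normalized to den[0] = 1 (feedforward ``num``, feedback
    ``den``).
    """

    num: np.ndarray
    den: np.ndarray
    design_order: int
    family: str  # butterworth | chebyshev1
    f_low: float
    f_high: float
    fs: float
    ripple_fraction: float | None = None

    def __post_init__(self) -> None:
        self.num = np.asarray(self.num, dtype=float)
        self.den = np.asarray(self.den, dtype=float)
        if self.den.size == 0:
            raise ValidationError("denominator must be non-empty")
        if not (np.all(np.isfinite(self.num)) and np.all(np.isfinite(self.den))):
            raise ValidationError("filter coefficients must be finite")
        if abs(self.den[0] - 1.0) > 1e-12:
            raise ValidationError("denominator leading coefficient must be 1")
        expected = 2 * self.design_order + 1
        if self.num.size != expected or self.den.size != expected:
            raise ValidationError(
                f"bandpass TF of design order {self.design_order} needs "
                f"{expected} coefficients per polynomial"
            )

    @property
    def order(self) -> int:
        return self.design_order

    def ba(self) -> tuple[np.ndarray, np.ndarray]:
        return self.num, self.den

    def to_json(self) -> str:
        return json.dumps({
            "family": self.family, "order": self.design_order,
            "ripple_fraction": self.ripple_fraction, "f_low": self.f_low,
            "f_high": self.f_high, "fs": self.fs,
            "num": self.num.tolist(), "den": self.den.tolist(),
        })


Filter = Union[FIRFilter, IIRFilterTF]


@dataclass
class StabilityReport:
    stable: bool
    max_pole_magnitude: float
    poles: np.ndarray = field(default_factory=lambda: np.empty(0, complex))


def _validate_band(f_low: float, f_high: float, fs: float) -> None:
    if not fs > 0:
        raise ValidationError(f"sampling rate must be positive, got {fs}")
    if not (0 < f_low < f_high < fs / 2):
        raise ValidationError(
            f"need 0 < f_low < f_high < fs/2; got ({f_low}, {f_high}) at fs={fs}"
        )


def design_fir_bandpass(order: int, f_low: float, f_high: float,
                        fs: float) -> FIRFilter:
    """Hamming-windowed-sinc bandpass with unit gain at the band midpoint.

    Band edges are the −6 dB points of the windowed-sinc design.  The taps
    are rescaled after design so the magnitude at (f_low+f_high)/2 is exactly
    one, which makes band powers of filtered and unfiltered signals directly
    comparable.
    """
    _validate_band(f_low, f_high, fs)
    if order < 2:
        raise ValidationError(f"FIR order must be ≥ 2, got {order}")
    h = signal.firwin(order + 1, [f_low, f_high], fs=fs, pass_zero=False,
                      window="hamming")
    mid = 0.5 * (f_low + f_high)
    _, resp = signal.freqz(h, worN=[mid], fs=fs)
    h = h / np.abs(resp[0])
    return FIRFilter(h=h, f_low=f_low, f_high=f_high, fs=fs)


def _analog_bandpass_poly(proto_zpk, f_low: float, f_high: float,
                          fs: float) -> tuple[np.ndarray, np.ndarray]:
    # prewarp the digital band edges so the bilinear transform lands them exactly
    w1 = 2 * fs * np.tan(np.pi * f_low / fs)
    w2 = 2 * fs * np.tan(np.pi * f_high / fs)
    b, a = signal.zpk2tf(*proto_zpk)
    b, a = signal.lp2bp(b, a, wo=np.sqrt(w1 * w2), bw=w2 - w1)
    return signal.bilinear(b, a, fs=fs)


def design_butterworth_bandpass(order: int, f_low: float, f_high: float,
                                fs: float) -> IIRFilterTF:
    """Digital Butterworth bandpass in TF polynomial form.

    Maximally flat passband; gain at each cutoff is 1/√2 (−3 dB) up to the
    round-off of the polynomial representation.
    """
    _validate_band(f_low, f_high, fs)
    if order < 1:
        raise ValidationError(f"order must be ≥ 1, got {order}")
    num, den = _analog_bandpass_poly(signal.buttap(order), f_low, f_high, fs)
    num, den = num / den[0], den / den[0]
    return IIRFilterTF(num=num, den=den, design_order=order,
                       family="butterworth", f_low=f_low, f_high=f_high, fs=fs)


def design_chebyshev1_bandpass(order: int, ripple_fraction: float, f_low: float,
                               f_high: float, fs: float) -> IIRFilterTF:
    """Chebyshev Type I bandpass in TF polynomial form.

    ``ripple_fraction`` δ is the peak-to-trough passband amplitude ripple as a
    fraction of the peak gain: gain oscillates between 1−δ and 1 inside the
    passband.  Converted internally to the decibel ripple −20·log10(1−δ).
    """
    _validate_band(f_low, f_high, fs)
    if not (0 < ripple_fraction < 0.2):
        raise ValidationError(
            f"ripple_fraction must be in (0, 0.2), got {ripple_fraction}"
        )
    if order < 1:
        raise ValidationError(f"order must be ≥ 1, got {order}")
    rp_db = -20.0 * np.log10(1.0 - ripple_fraction)
    num, den = _analog_bandpass_poly(signal.cheb1ap(order, rp_db),
                                     f_low, f_high, fs)
    num, den = num / den[0], den / den[0]
    return IIRFilterTF(num=num, den=den, design_order=order, family="chebyshev1",
                       f_low=f_low, f_high=f_high, fs=fs,
                       ripple_fraction=ripple_fraction)


def stability_report(filt: Filter) -> StabilityReport:
    """Pole analysis of the filter as materialized in TF polynomial form.

    Poles are the eigenvalues of the companion matrix of the denominator;
    stability requires every pole strictly inside the unit circle.  Poles on
    the circle count as unstable.  FIR filters have no feedback and are
    always stable.
    """
    if isinstance(filt, FIRFilter):
        return StabilityReport(stable=True, max_pole_magnitude=0.0)
    den = filt.den
    if den.size == 0:
        raise ValidationError("empty denominator")
    poles = np.roots(den)
    max_mag = float(np.abs(poles).max()) if poles.size else 0.0
    return StabilityReport(stable=bool(max_mag < 1.0),
                           max_pole_magnitude=max_mag, poles=poles)


def magnitude_response(filt: Filter, freqs: Sequence[float],
                       fs: float | None = None) -> np.ndarray:
    """|H(e^{j2πf/fs})| evaluated from the coefficient polynomials."""
    fs = filt.fs if fs is None else fs
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs < 0) or np.any(freqs > fs / 2):
        raise ValidationError("frequencies must lie in [0, fs/2]")
    b, a = filt.ba()
    _, resp = signal.freqz(b, a, worN=freqs, fs=fs)
    return np.abs(resp)


def _padlen(filt: Filter) -> int:
    b, a = filt.ba()
    return 3 * (max(b.size, a.size) - 1)


def apply_zero_phase(x: np.ndarray, filt: Filter) -> np.ndarray:
    """Forward–backward (zero-phase) filtering with odd-reflection padding.

    The effective amplitude response is |H|² and the net phase response is
    zero.  Unstable filters are rejected: running an unstable recursion, even
    bidirectionally, produces divergent output.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValidationError("apply_zero_phase expects a 1D signal")
    report = stability_report(filt)
    if not report.stable:
        raise ValidationError(
            f"unstable filter (max pole magnitude "
            f"{report.max_pole_magnitude:.6g}); design discarded"
        )
    pad = _padlen(filt)
    if x.size <= pad:
        raise ValidationError(
            f"signal of {x.size} samples is too short for edge padding of {pad}"
        )
    b, a = filt.ba()
    return signal.filtfilt(b, a, x, padtype="odd", padlen=pad)
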
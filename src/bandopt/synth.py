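"""Synthetic multi-channel EEG with controlled spectral content and artifacts.

The generator emulates the acquisition setting the rest of the package is
built around: a 64-channel cap sampled at 500 Hz, rhythmic band-limited
activity (beta strongest under cognitive engagement) riding on 1/f
background noise, contaminated by eye blinks (low-frequency frontal
transients around 0.02 V), broadband muscle noise, flatlined electrodes and
channels that lost scalp contact (decorrelated from their neighbors).

Oscillations are realized as fixed-frequency sinusoids with one random phase
per oscillation, shared across channels and scaled by per-channel weights —
the signature of volume conduction from a common cortical source, and the
reason neighboring electrodes on a real cap are strongly correlated.  This
keeps the band-power ground truth analytic: a tone of RMS amplitude r
contributes exactly r² to the power of any band containing it.  The 1/f
background is spectrally shaped white noise (FFT magnitudes scaled by
f^(−1/2)), rescaled to the requested RMS per channel, and split into a
cap-wide shared field plus per-channel independent noise so that neighbor
correlations of clean channels sit realistically high.

Everything is driven by explicit integer seeds: the same spec produces
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .montages import builtin_montage
from .recording import EEGRecording, FrequencyBand, Montage, ValidationError

Annotation = tuple[str, int, float, float]  # (kind, channel, start_s, end_s)


@dataclass
class Oscillation:
    """One rhythmic component: a tone at ``center_freq`` inside ``band``."""

    band: FrequencyBand
    center_freq: float
    rms_amplitude: float  # volts
    channel_weights: np.ndarray | None = None  # per-channel gain, default 1

    def __post_init__(self) -> None:
        if self.rms_amplitude < 0:
            raise ValidationError("rms_amplitude must be ≥ 0")
        if not (self.band.f_low <= self.center_freq <= self.band.f_high):
            raise ValidationError(
                f"center_freq {self.center_freq} Hz outside band "
                f"[{self.band.f_low}, {self.band.f_high}] Hz"
            )


@dataclass
class SynthSpec:
    """Specification of a clean synthetic recording."""

    n_channels: int = 64
    duration_s: float = 60.0
    fs: float = 500.0
    oscillations: list[Oscillation] = field(default_factory=list)
    noise_rms: float = 10e-6  # 1/f background, volts
    noise_spatial_corr: float = 0.8  # shared fraction of background variance
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValidationError("n_channels must be ≥ 1")
        if not self.duration_s > 0:
            raise ValidationError("duration_s must be positive")
        if not self.fs > 0:
            raise ValidationError("fs must be positive")
        if self.noise_rms < 0:
            raise ValidationError("noise_rms must be ≥ 0")
        if not (0 <= self.noise_spatial_corr <= 1):
            raise ValidationError("noise_spatial_corr must be in [0, 1]")
        for osc in self.oscillations:
            if osc.center_freq >= self.fs / 2:
                raise ValidationError(
                    f"oscillation at {osc.center_freq} Hz is not below the "
                    f"Nyquist frequency {self.fs / 2} Hz"
                )


@dataclass
class ArtifactSpec:
    """Artifact contamination plan; empty by default (identity)."""

    blink_rate_per_min: float = 0.0
    blink_peak_amplitude: float = 0.02  # volts — implausibly large for neural EEG
    muscle_band: FrequencyBand = field(
        default_factory=lambda: FrequencyBand("muscle", 45.0, 100.0))
    muscle_rms: float = 0.0  # volts
    muscle_channels: list[int] | None = None  # default: temporal electrodes
    flat_channels: list[tuple[int, float, float]] = field(default_factory=list)
    decorrelated_channels: list[int] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.blink_rate_per_min < 0 or self.muscle_rms < 0:
            raise ValidationError("rates and amplitudes must be ≥ 0")
        for _, _, dur in self.flat_channels:
            if dur < 0:
                raise ValidationError("flat segment durations must be ≥ 0")


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                fs: float, rms: float) -> np.ndarray:
    """1/f-power noise by spectral shaping, exact per-channel RMS."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** -0.5  # amplitude ∝ f^(−1/2) ⇒ power ∝ 1/f
    x = np.fft.irfft(spec * shaping, n=n_samples, axis=1)
    cur = x.std(axis=1, keepdims=True)
    cur[cur == 0] = 1.0
    return x * (rms / cur)


def generate_recording(spec: SynthSpec) -> EEGRecording:
    """Realize a clean recording from a :class:`SynthSpec` (seed-deterministic)."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs
    data = np.zeros((spec.n_channels, n))

    for osc in spec.oscillations:
        w = (np.ones(spec.n_channels) if osc.channel_weights is None
             else np.asarray(osc.channel_weights, dtype=float))
        if w.shape != (spec.n_channels,):
            raise ValidationError("channel_weights length must equal n_channels")
        phase = rng.uniform(0, 2 * np.pi)
        amp = osc.rms_amplitude * np.sqrt(2.0)
        data += (w[:, None] * amp
                 * np.sin(2 * np.pi * osc.center_freq * t[None, :] + phase))

    if spec.noise_rms > 0:
        rho = spec.noise_spatial_corr
        shared = _pink_noise(rng, 1, n, spec.fs, spec.noise_rms)
        indep = _pink_noise(rng, spec.n_channels, n, spec.fs, spec.noise_rms)
        bg = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indep
        # finite-sample covariance between the components perturbs the sum's
        # variance; rescale so each channel carries exactly the stated RMS
        data += bg * (spec.noise_rms / bg.std(axis=1, keepdims=True))

    if spec.n_channels == 64:
        montage = builtin_montage("biosemi64")
        labels, montage_id = montage.labels, "biosemi64"
    else:
        labels, montage_id = [f"ch{i}" for i in range(spec.n_channels)], None
    return EEGRecording(data=data, fs=spec.fs, channel_labels=labels,
                        montage_id=montage_id)


def _blink_pulse(fs: float, peak: float) -> np.ndarray:
    """One-sided exponential-decay pulse, 300 ms support."""
    n = int(round(0.3 * fs))
    tau = 0.06 * fs  # samples; decays to <1% over the support
    return peak * np.exp(-np.arange(n) / tau)


def _region_channels(rec: EEGRecording, montage: Montage | None,
                     region: str) -> list[int]:
    if montage is None and rec.montage_id is not None:
        try:
            montage = builtin_montage(rec.montage_id)
        except KeyError:
            montage = None
    if montage is not None and montage.regions is not None \
            and montage.labels == rec.channel_labels:
        chans = [i for i, r in enumerate(montage.regions) if r.endswith(region)]
        if chans:
            return chans
    # no usable montage: fall back to the leading quarter of channels
    return list(range(max(1, rec.n_channels // 4)))


def inject_artifacts(rec: EEGRecording, art: ArtifactSpec,
                     montage: Montage | None = None,
                     ) -> tuple[EEGRecording, list[Annotation]]:
    """Contaminate a recording; returns the new recording plus annotations.

    Blinks land on frontal electrodes (when a montage is available) as
    low-frequency transients of the stated peak amplitude; muscle noise is
    bandpassed white noise on temporal electrodes by default; flat segments
    are exactly constant; decorrelated channels are replaced wholesale by
    independent 1/f noise of matched RMS.  An empty spec returns the input
    unchanged.
    """
    rng = np.random.default_rng(art.seed)
    out = rec.copy()
    events: list[Annotation] = []

    # flat segments first: they must survive later additive noise on other
    # channels, and other artifacts are not injected on top of them
    spans: dict[int, list[tuple[float, float]]] = {}
    for ch, start_s, dur_s in art.flat_channels:
        if not (0 <= ch < rec.n_channels):
            raise ValidationError(f"flat channel {ch} out of range")
        for s0, s1 in spans.get(ch, []):
            if start_s < s1 and start_s + dur_s > s0:
                raise ValidationError(
                    f"overlapping flat segments on channel {ch}")
        spans.setdefault(ch, []).append((start_s, start_s + dur_s))
        i0 = int(round(start_s * rec.fs))
        i1 = min(int(round((start_s + dur_s) * rec.fs)), rec.n_samples)
        if i0 >= rec.n_samples or i1 <= i0:
            continue
        out.data[ch, i0:i1] = out.data[ch, i0]
        events.append(("flat", ch, start_s, start_s + dur_s))

    if art.blink_rate_per_min > 0:
        frontal = _region_channels(rec, montage, "frontal")
        n_blinks = rng.poisson(art.blink_rate_per_min * rec.duration_s / 60.0)
        pulse = _blink_pulse(rec.fs, art.blink_peak_amplitude)
        starts = np.sort(rng.uniform(0, rec.duration_s - 0.3,
                                     size=n_blinks)) if n_blinks else []
        for t0 in starts:
            i0 = int(round(t0 * rec.fs))
            seg = min(pulse.size, rec.n_samples - i0)
            for ch in frontal:
                out.data[ch, i0:i0 + seg] += pulse[:seg]
                events.append(("blink", ch, float(t0), float(t0 + 0.3)))

    if art.muscle_rms > 0:
        art.muscle_band.validate_for_fs(rec.fs)
        chans = (art.muscle_channels if art.muscle_channels is not None
                 else _region_channels(rec, montage, "temporal"))
        sos = _sig.butter(4, [art.muscle_band.f_low, art.muscle_band.f_high],
                          btype="bandpass", fs=rec.fs, output="sos")
        for ch in chans:
            if not (0 <= ch < rec.n_channels):
                raise ValidationError(f"muscle channel {ch} out of range")
            noise = _sig.sosfiltfilt(sos, rng.standard_normal(rec.n_samples))
            noise *= art.muscle_rms / noise.std()
            out.data[ch] += noise
            events.append(("muscle", ch, 0.0, rec.duration_s))

    for ch in art.decorrelated_channels:
        if not (0 <= ch < rec.n_channels):
            raise ValidationError(f"decorrelated channel {ch} out of range")
        rms = rec.data[ch].std() or 10e-6
        out.data[ch] = _pink_noise(rng, 1, rec.n_samples, rec.fs, rms)[0]
        events.append(("decorrelated", ch, 0.0, rec.duration_s))

    return out, events


def study_spec(n_channels: int = 64, duration_s: float = 60.0, fs: float = 500.0,
               seed: int = 0) -> SynthSpec:
    """Default study-like scene: beta-dominant frontal activity on 1/f noise.

    Amplitudes are typical scalp-EEG values: 10 µV RMS 1/f background, an
    8 µV RMS alpha rhythm strongest posteriorly and a 6 µV RMS beta rhythm
    strongest frontally (beta is the dominant in-band rhythm by design, as
    during attentive 2D-content viewing).
    """
    beta = FrequencyBand("beta", 13.0, 30.0)
    alpha = FrequencyBand("alpha", 8.0, 13.0)
    if n_channels == 64:
        regions = builtin_montage("biosemi64").regions or []
        front = np.array([1.0 if r == "frontal" else 0.4 for r in regions])
        back = np.array([1.0 if r == "occipital" else 0.4 for r in regions])
    else:
        front = back = np.ones(n_channels)
    return SynthSpec(
        n_channels=n_channels, duration_s=duration_s, fs=fs,
        oscillations=[
            Oscillation(beta, 20.0, 6e-6, front),
            Oscillation(alpha, 10.0, 8e-6, back),
        ],
        noise_rms=10e-6, seed=seed,
    )
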
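"""Automated channel-quality screening.

Three rules, mirroring standard EEG bad-channel practice: (1) electrodes
that flatline for a sustained interval have lost contact; (2) electrodes
whose high-frequency residual is an outlier relative to the cap carry
muscle/line noise; (3) electrodes poorly correlated with their spatial
neighbors record something other than shared cortical activity.  A channel
is removed iff at least one rule flags it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .montages import builtin_montage
from .recording import EEGRecording, Montage, ValidationError


class NoChannelsRetainedError(ValidationError):
    """Every channel was flagged; the recording is unusable as given."""


@dataclass(frozen=True)
class QualityParams:
    """Screening thresholds.

    ``max_flat_duration_s``: a channel is bad if its range stays within
    ``flat_tolerance`` over a span longer than this.  ``hf_noise_z_max``:
    cap on the robust z-score (median/MAD across channels) of each channel's
    high-frequency noise SD, the residual above ``hf_cutoff_hz``.
    ``min_neighbor_corr``: minimum acceptable correlation with the best of
    the ``n_neighbors`` nearest electrodes, 1–45 Hz band, 5 s windows,
    median across windows.
    """

    max_flat_duration_s: float = 10.0
    flat_tolerance: float = 1e-6  # volts
    hf_noise_z_max: float = 4.0
    hf_cutoff_hz: float = 45.0
    min_neighbor_corr: float = 0.7
    n_neighbors: int = 4

    def __post_init__(self) -> None:
        if min(self.max_flat_duration_s, self.flat_tolerance,
               self.hf_noise_z_max, self.hf_cutoff_hz, self.n_neighbors) <= 0:
            raise ValidationError("all screening thresholds must be positive")
        if not (0 < self.min_neighbor_corr <= 1):
            raise ValidationError("min_neighbor_corr must be in (0, 1]")


@dataclass
class QualityReport:
    flags: list[set[str]]  # per channel, subset of {flat, hf_noise, low_corr}
    retained: list[int]
    n_removed: int

    @property
    def flagged(self) -> list[int]:
        return [i for i, f in enumerate(self.flags) if f]


def detect_flat_channels(rec: EEGRecording,
                         params: QualityParams | None = None) -> np.ndarray:
    """True where a channel's (max − min) stays ≤ flat_tolerance over any
    contiguous span longer than max_flat_duration_s.

    A recording shorter than the flat-duration threshold cannot flag any
    channel.  Invariant to constant offsets by construction.
    """
    params = params or QualityParams()
    # m samples span (m−1)/fs seconds; need strictly more than the threshold
    m = int(np.floor(params.max_flat_duration_s * rec.fs)) + 2
    flags = np.zeros(rec.n_channels, dtype=bool)
    n = rec.n_samples
    if n < m:
        return flags
    lo, hi = m // 2, n - 1 - (m - 1) // 2  # centers of fully-interior windows
    for i in range(rec.n_channels):
        rng = (maximum_filter1d(rec.data[i], size=m, mode="nearest")
               - minimum_filter1d(rec.data[i], size=m, mode="nearest"))
        flags[i] = bool(np.any(rng[lo:hi + 1] <= params.flat_tolerance))
    return flags


def _hf_residual_sd(rec: EEGRecording, cutoff_hz: float) -> np.ndarray:
    sos = signal.butter(8, cutoff_hz, btype="lowpass", fs=rec.fs, output="sos")
    low = signal.sosfiltfilt(sos, rec.data, axis=1)
    return (rec.data - low).std(axis=1)


def detect_hf_noise_channels(rec: EEGRecording,
                             params: QualityParams | None = None) -> np.ndarray:
    """Flag channels whose high-frequency noise SD is a robust outlier.

    The score is the SD of the residual after lowpass filtering at
    ``hf_cutoff_hz``; a channel is flagged iff its robust z-score — deviation
    from the cross-channel median in units of 1.4826·MAD — exceeds
    ``hf_noise_z_max``.  If the MAD is zero (all channels alike) nothing can
    be an outlier and no channel is flagged.
    """
    params = params or QualityParams()
    if rec.n_channels < 3:
        raise ValidationError(
            "robust z-scores need at least 3 channels to compare")
    if params.hf_cutoff_hz >= rec.fs / 2:
        raise ValidationError(
            f"hf_cutoff_hz {params.hf_cutoff_hz} must be below fs/2")
    score = _hf_residual_sd(rec, params.hf_cutoff_hz)
    med = np.median(score)
    mad = np.median(np.abs(score - med))
    if mad == 0:
        return np.zeros(rec.n_channels, dtype=bool)
    z = (score - med) / (1.4826 * mad)
    return z > params.hf_noise_z_max


def _resolve_montage(rec: EEGRecording, montage: Montage | None) -> Montage:
    if montage is None:
        if rec.montage_id is None:
            raise ValidationError("no montage given and recording names none")
        montage = builtin_montage(rec.montage_id)
    missing = [lab for lab in rec.channel_labels if lab not in montage.labels]
    if missing:
        raise ValidationError(f"montage lacks positions for channels {missing}")
    return montage.subset([montage.index_of(lab) for lab in rec.channel_labels])


def detect_low_correlation_channels(rec: EEGRecording,
                                    montage: Montage | None = None,
                                    params: QualityParams | None = None,
                                    ) -> np.ndarray:
    """Flag channels poorly correlated with all of their nearest neighbors.

    Data are bandpassed to 1–45 Hz, split into 5 s windows, and each
    channel's window score is the maximum absolute Pearson correlation over
    its ``n_neighbors`` nearest montage neighbors; the channel score is the
    median across windows.  Flagged iff score < ``min_neighbor_corr``.
    """
    params = params or QualityParams()
    mont = _resolve_montage(rec, montage)
    if rec.n_channels < 2:
        raise ValidationError("neighbor correlation needs ≥ 2 channels")
    hi = min(45.0, 0.95 * rec.fs / 2)
    sos = signal.butter(4, [1.0, hi], btype="bandpass", fs=rec.fs, output="sos")
    x = signal.sosfiltfilt(sos, rec.data, axis=1)

    win = int(round(5.0 * rec.fs))
    n_win = max(1, rec.n_samples // win)
    neighbors = mont.neighbors(params.n_neighbors)

    scores = np.empty((rec.n_channels, n_win))
    for w in range(n_win):
        seg = x[:, w * win:(w + 1) * win] if rec.n_samples >= win else x
        sd = seg.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(seg)
        c[~np.isfinite(c)] = 0.0  # zero-variance windows correlate with nothing
        c[sd == 0, :] = 0.0
        c[:, sd == 0] = 0.0
        for i in range(rec.n_channels):
            scores[i, w] = np.abs(c[i, neighbors[i]]).max()
    return np.median(scores, axis=1) < params.min_neighbor_corr


def screen_channels(rec: EEGRecording, montage: Montage | None = None,
                    params: QualityParams | None = None,
                    ) -> tuple[EEGRecording, QualityReport]:
    """Run all three rules and drop every flagged channel (order preserved)."""
    params = params or QualityParams()
    flat = detect_flat_channels(rec, params)
    hf = detect_hf_noise_channels(rec, params)
    corr = detect_low_correlation_channels(rec, montage, params)

    flags: list[set[str]] = []
    for i in range(rec.n_channels):
        f: set[str] = set()
        if flat[i]:
            f.add("flat")
        if hf[i]:
            f.add("hf_noise")
        if corr[i]:
            f.add("low_corr")
        flags.append(f)
    retained = [i for i, f in enumerate(flags) if not f]
    if not retained:
        raise NoChannelsRetainedError("every channel was flagged for removal")
    report = QualityReport(flags=flags, retained=retained,
                           n_removed=rec.n_channels - len(retained))
    return rec.subset(retained), report
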
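"""Core data model for multi-channel EEG recordings and scalp montages.

Amplitudes are stored in volts throughout; spectral results elsewhere in the
package are reported in µV² (1 V² = 1e12 µV²).  The on-disk interchange format
is a headerless CSV matrix (rows = channels, columns = samples) plus a JSON
sidecar carrying the sampling rate, channel labels and montage reference.
EDF/BDF files are read through MNE and written with a built-in minimal writer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np


class ValidationError(ValueError):
    """Raised when a recording, montage or parameter set violates its contract."""


class FormatError(ValueError):
    """Raised when an input file does not match the expected interchange layout."""


@dataclass(frozen=True)
class FrequencyBand:
    """A named frequency interval [f_low, f_high] in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0 < self.f_low < self.f_high):
            raise ValidationError(
                f"band {self.name!r}: need 0 < f_low < f_high, "
                f"got ({self.f_low}, {self.f_high})"
            )

    def validate_for_fs(self, fs: float) -> None:
        if self.f_high >= fs / 2:
            raise ValidationError(
                f"band {self.name!r} upper edge {self.f_high} Hz is not below "
                f"the Nyquist frequency {fs / 2} Hz"
            )


#: The beta band, the default optimization target: sustained-attention rhythms.
BETA = FrequencyBand("beta", 13.0, 30.0)


@dataclass
class Montage:
    """Labeled 2D scalp electrode layout.

    Coordinates are a unitless top-view projection with the nose toward +y and
    unit head radius; they only serve to define inter-electrode distances for
    neighbor-based channel screening.
    """

    labels: list[str]
    positions: np.ndarray  # (n, 2)
    regions: list[str] | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.labels) != len(set(self.labels)):
            raise ValidationError("montage labels must be unique")
        if self.positions.shape != (len(self.labels), 2):
            raise ValidationError("positions must be (n_labels, 2)")
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError("montage positions must be finite")
        if self.regions is not None and len(self.regions) != len(self.labels):
            raise ValidationError("regions length must match labels")

    def __len__(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"label {label!r} not in montage") from None

    def neighbors(self, n_neighbors: int) -> dict[int, list[int]]:
        """Indices of the ``n_neighbors`` nearest electrodes for each channel."""
        d = np.linalg.norm(
            self.positions[:, None, :] - self.positions[None, :, :], axis=-1
        )
        np.fill_diagonal(d, np.inf)
        k = min(n_neighbors, len(self.labels) - 1)
        order = np.argsort(d, axis=1)
        return {i: list(order[i, :k]) for i in range(len(self.labels))}

    def subset(self, indices: Sequence[int]) -> "Montage":
        idx = list(indices)
        return Montage(
            labels=[self.labels[i] for i in idx],
            positions=self.positions[idx],
            regions=None if self.regions is None else [self.regions[i] for i in idx],
        )


@dataclass
class EEGRecording:
    """A channels × samples EEG matrix in volts with acquisition metadata."""

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    montage_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise ValidationError("data must be a 2D channels × samples matrix")
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValidationError("need at least one channel and one sample")
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValidationError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValidationError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, key: int | str) -> np.ndarray:
        """One channel's signal by index or label."""
        if isinstance(key, str):
            try:
                key = self.channel_labels.index(key)
            except ValueError:
                raise KeyError(f"no channel labeled {key!r}") from None
        return self.data[key]

    def subset(self, indices: Sequence[int]) -> "EEGRecording":
        idx = list(indices)
        return EEGRecording(
            data=self.data[idx].copy(),
            fs=self.fs,
            channel_labels=[self.channel_labels[i] for i in idx],
            montage_id=self.montage_id,
        )

    def copy(self) -> "EEGRecording":
        return EEGRecording(
            data=self.data.copy(),
            fs=self.fs,
            channel_labels=list(self.channel_labels),
            montage_id=self.montage_id,
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FORMATS = ("csv_sidecar", "edf", "bdf")


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_recording(rec: EEGRecording, path: str | Path,
                    format: str = "csv_sidecar") -> None:
    """Write a recording so that :func:`read_recording` recovers it.

    ``csv_sidecar`` stores the full float precision; EDF/BDF quantize to the
    format's 16-/24-bit integer samples.
    """
    path = Path(path)
    if format == "csv_sidecar":
        np.savetxt(path, rec.data, delimiter=",")
        sidecar = {
            "fs_hz": rec.fs,
            "labels": rec.channel_labels,
            "units": "V",
            "montage": rec.montage_id,
        }
        _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    elif format in ("edf", "bdf"):
        from ._edf import write_edf
        write_edf(path, rec.data, rec.fs, rec.channel_labels,
                  bits=24 if format == "bdf" else 16)
    else:
        raise FormatError(f"unknown format {format!r}; expected one of {_FORMATS}")


def read_recording(path: str | Path, format: str | None = None) -> EEGRecording:
    """Read a recording from ``csv_sidecar``, ``edf`` or ``bdf`` storage.

    When ``format`` is omitted it is inferred from the file extension.
    """
    path = Path(path)
    if format is None:
        ext = path.suffix.lower().lstrip(".")
        format = {"csv": "csv_sidecar", "edf": "edf", "bdf": "bdf"}.get(ext)
        if format is None:
            raise FormatError(f"cannot infer format from extension {path.suffix!r}")
    if format == "csv_sidecar":
        return _read_csv_sidecar(path)
    if format in ("edf", "bdf"):
        return _read_edf_bdf(path, format)
    raise FormatError(f"unknown format {format!r}; expected one of {_FORMATS}")


def _read_csv_sidecar(path: Path) -> EEGRecording:
    sidecar_path = _sidecar_path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not sidecar_path.exists():
        raise FormatError(f"missing JSON sidecar {sidecar_path}")
    try:
        meta = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"sidecar {sidecar_path} is not valid JSON: {exc}") from exc
    if "fs_hz" not in meta or "labels" not in meta:
        raise FormatError("sidecar must contain fs_hz and labels")
    fs = float(meta["fs_hz"])
    if fs <= 0:
        raise ValidationError(f"sidecar fs_hz must be positive, got {fs}")
    try:
        data = np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError as exc:
        raise FormatError(f"could not parse matrix CSV {path}: {exc}") from exc
    labels = list(meta["labels"])
    if data.shape[0] != len(labels):
        raise FormatError(
            f"CSV has {data.shape[0]} rows but sidecar lists {len(labels)} labels"
        )
    return EEGRecording(data=data, fs=fs, channel_labels=labels,
                        montage_id=meta.get("montage"))


def _read_edf_bdf(path: Path, format: str) -> EEGRecording:
    import mne

    if not path.exists():
        raise FileNotFoundError(path)
    reader = mne.io.read_raw_bdf if format == "bdf" else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="error")
    # MNE returns volts for EEG-typed channels
    return EEGRecording(data=raw.get_data(), fs=float(raw.info["sfreq"]),
                        channel_labels=list(raw.ch_names))
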
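"""EEG containers, file I/O, and deterministic preprocessing.

Voltages are held in microvolts as a ``channels x samples`` float matrix.
Samples are 0-based; sample intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "ChannelMontage",
    "EEGRecording",
    "RatingTable",
    "TrialSet",
    "read_edf",
    "write_edf",
    "read_matrix",
    "write_matrix",
    "read_montage",
    "average_reference",
    "bandpass_filter",
    "downsample",
    "baseline_correct",
]


@dataclass(frozen=True)
class ChannelMontage:
    """Ordered electrode names, optionally with 2-D layout coordinates.

    The layout is unitless and used only for plotting; analyses depend only
    on the channel order.
    """

    channel_names: tuple[str, ...]
    layout: np.ndarray | None = None

    def __post_init__(self) -> None:
        names = tuple(str(n) for n in self.channel_names)
        object.__setattr__(self, "channel_names", names)
        if len(names) < 2:
            raise ValueError("a montage needs at least 2 channels")
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        if self.layout is not None:
            layout = np.asarray(self.layout, dtype=float)
            if layout.shape != (len(names), 2):
                raise ValueError("layout must be (n_channels, 2)")
            object.__setattr__(self, "layout", layout)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)


@dataclass
class EEGRecording:
    """A multichannel voltage recording (µV) at a fixed sampling rate.

    ``data`` is ``(n_channels, n_samples)``; row order matches the montage.
    """

    data: np.ndarray
    rate: float
    montage: ChannelMontage
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"data has {self.data.shape[0]} rows but montage has "
                f"{self.montage.n_channels} channels"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("voltages must be finite")
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.rate

    def with_data(self, data: np.ndarray, rate: float | None = None) -> "EEGRecording":
        return replace(self, data=data, rate=self.rate if rate is None else rate)


@dataclass
class RatingTable:
    """Per-trial affective ratings on the 1-9 self-assessment scales."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table)
        required = {"trial_id", "valence", "arousal"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"rating table missing columns: {sorted(missing)}")
        if df["trial_id"].duplicated().any():
            raise ValueError("trial ids must be unique")
        for col in ("valence", "arousal", "dominance"):
            if col in df.columns:
                vals = df[col].dropna()
                if ((vals < 1) | (vals > 9)).any():
                    raise ValueError(f"{col} ratings must lie in [1, 9]")
        self.table = df.reset_index(drop=True)

    def rating(self, trial_id, dimension: str) -> float:
        row = self.table[self.table["trial_id"] == trial_id]
        if row.empty:
            raise KeyError(f"no rating for trial {trial_id!r}")
        return float(row.iloc[0][dimension])


@dataclass
class TrialSet:
    """A collection of trial recordings with their ratings."""

    trials: list[EEGRecording]
    ratings: RatingTable

    def __post_init__(self) -> None:
        ids = [t.meta.get("trial_id") for t in self.trials]
        known = [i for i in ids if i is not None]
        if len(set(known)) != len(known):
            raise ValueError("duplicate trial ids among trials")


# ---------------------------------------------------------------------------
# EDF I/O
# ---------------------------------------------------------------------------

def read_edf(path) -> EEGRecording:
    """Read a European Data Format file into an :class:`EEGRecording`.

    All signals must share one sampling rate. Voltages are returned in µV
    regardless of the stored physical dimension (SI scaling is undone).
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "rb") as fh:
        magic = fh.read(8)
    if magic[:1] != b"0":
        raise ValueError(f"{path} does not look like an EDF file (bad version field)")
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    rates = {raw.info["sfreq"]}
    if len(rates) != 1:
        raise ValueError("mixed per-channel sampling rates are unsupported")
    data = raw.get_data() * 1e6  # mne returns volts
    montage = ChannelMontage(tuple(raw.ch_names))
    return EEGRecording(data=data, rate=float(raw.info["sfreq"]), montage=montage)


def write_edf(rec: EEGRecording, path) -> None:
    """Write a recording as a minimal EDF file (one data record per second).

    Physical dimension is µV; samples are quantized to the 16-bit EDF grid
    spanning the recording's value range.
    """
    path = Path(path)
    n_ch = rec.n_channels
    if rec.rate != int(rec.rate):
        raise ValueError("EDF writing requires an integer sampling rate")
    sps = int(rec.rate)  # samples per channel per 1-s record
    n_rec = int(np.ceil(rec.n_samples / sps))
    padded = np.zeros((n_ch, n_rec * sps))
    padded[:, : rec.n_samples] = rec.data

    phys_min = float(min(padded.min(), -1.0))
    phys_max = float(max(padded.max(), 1.0))
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((padded - phys_min) * scale + dig_min).astype("<i2")

    def fx(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    header = b"".join(
        [
            fx("0", 8),
            fx("X X X X", 80),  # patient id
            fx("Startdate X X X X", 80),  # recording id
            fx("01.01.00", 8),
            fx("00.00.00", 8),
            fx(str(256 * (1 + n_ch)), 8),
            fx("", 44),
            fx(str(n_rec), 8),
            fx("1", 8),  # record duration, seconds
            fx(str(n_ch), 4),
        ]
    )
    sig = b"".join(fx(name, 16) for name in rec.montage.channel_names)
    sig += fx("", 80) * n_ch  # transducer
    sig += fx("uV", 8) * n_ch
    sig += fx(f"{phys_min:.6g}", 8) * n_ch
    sig += fx(f"{phys_max:.6g}", 8) * n_ch
    sig += fx(str(dig_min), 8) * n_ch
    sig += fx(str(dig_max), 8) * n_ch
    sig += fx("", 80) * n_ch  # prefiltering
    sig += fx(str(sps), 8) * n_ch
    sig += fx("", 32) * n_ch  # reserved

    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_rec):
            block = digital[:, r * sps : (r + 1) * sps]
            fh.write(block.tobytes())


# ---------------------------------------------------------------------------
# Delimited-matrix I/O
# ---------------------------------------------------------------------------

def read_matrix(path, rate: float, orientation: str = "samples_rows") -> EEGRecording:
    """Read a delimited numeric matrix with a channel-name header row.

    ``orientation='samples_rows'`` (default) expects samples x channels after
    the header; ``'channels_rows'`` expects the transpose.
    """
    if not rate > 0:
        raise ValueError("rate must be positive")
    with open(path) as fh:
        raw_header = fh.readline().rstrip("\n").split("\t")
    if len(set(raw_header)) != len(raw_header):
        raise ValueError("duplicate channel names in header")
    df = pd.read_csv(path, sep="\t")
    names = tuple(raw_header)
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-numeric or non-finite cells in matrix")
    data = values.T if orientation == "samples_rows" else values
    return EEGRecording(data=data, rate=float(rate), montage=ChannelMontage(names))


def write_matrix(rec: EEGRecording, path) -> None:
    """Write a recording as TSV: header of channel names, rows of samples."""
    df = pd.DataFrame(rec.data.T, columns=list(rec.montage.channel_names))
    df.to_csv(path, sep="\t", index=False)


def read_montage(path) -> ChannelMontage:
    """Read a montage TSV: one channel name per row, optional "x,y" column."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    names = tuple(df.iloc[:, 0])
    layout = None
    if df.shape[1] > 1 and df.iloc[:, 1].notna().all():
        layout = np.array([[float(v) for v in cell.split(",")] for cell in df.iloc[:, 1]])
    return ChannelMontage(names, layout)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def average_reference(rec: EEGRecording) -> EEGRecording:
    """Re-reference to the common average: every sample gets zero channel mean.

    Idempotent linear projection; leaves global field power unchanged.
    """
    return rec.with_data(rec.data - rec.data.mean(axis=0, keepdims=True))


def bandpass_filter(rec: EEGRecording, low: float, high: float, order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass (forward-backward application).

    The pass band must lie strictly inside (0, Nyquist).
    """
    nyq = rec.rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"band ({low}, {high}) Hz must satisfy 0 < low < high < {nyq}")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.rate, output="sos")
    return rec.with_data(signal.sosfiltfilt(sos, rec.data, axis=1))


def downsample(rec: EEGRecording, target_rate: float) -> EEGRecording:
    """Anti-alias filter and decimate by an integer factor.

    Non-integer factors are refused so the sample-to-time mapping stays exact.
    """
    if target_rate >= rec.rate:
        raise ValueError("target rate must be below the current rate")
    factor = rec.rate / target_rate
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"target rate {target_rate} is not an integer divisor of {rec.rate}"
        )
    out = signal.decimate(rec.data, int(round(factor)), axis=1, ftype="fir", zero_phase=True)
    return rec.with_data(out, rate=float(target_rate))


def baseline_correct(
    rec: EEGRecording, baseline: tuple[int, int], crop: bool = True
) -> EEGRecording:
    """Subtract each channel's mean over ``baseline = [start, end)`` samples.

    With ``crop=True`` (the default for pre-stimulus baselines) the baseline
    samples are removed from the output.
    """
    start, end = baseline
    if not (0 <= start < end <= rec.n_samples):
        raise ValueError(f"baseline {baseline} out of bounds or empty")
    means = rec.data[:, start:end].mean(axis=1, keepdims=True)
    data = rec.data - means
    if crop:
        data = np.concatenate([data[:, :start], data[:, end:]], axis=1)
    return rec.with_data(data)
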
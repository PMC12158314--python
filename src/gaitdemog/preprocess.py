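"""Recording I/O, wavelet denoising, net acceleration and sliding-window segmentation.

A recording is a six-channel, uniformly sampled waist-IMU time series:
triaxial acceleration in g (x = lateral, y = vertical, z = forward) and
triaxial angular velocity in rad/s around the same axes.  Before feature
extraction each recording is denoised channel-by-channel with a wavelet
shrinkage filter, augmented with a seventh channel (net acceleration, the
per-sample Euclidean norm of the three acceleration axes, which is invariant
to sensor orientation), and cut into fixed-length windows with fractional
overlap.  Features are computed per window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pywt

from .errors import ConfigurationError, DataError, FormatError

#: sensed channels, in on-disk column order
CHANNELS = ("accl-x", "accl-y", "accl-z", "gyro-x", "gyro-y", "gyro-z")
#: channels seen by the feature extractor (sensed + derived net acceleration)
COMPONENTS = ("accl-x", "accl-y", "accl-z", "accl-net", "gyro-x", "gyro-y", "gyro-z")

_CSV_COLUMNS = ("t", "ax", "ay", "az", "gx", "gy", "gz")
_CSV_TO_CHANNEL = dict(zip(_CSV_COLUMNS[1:], CHANNELS))


@dataclass
class ImuRecording:
    """One subject x sensor-position recording with demographic labels.

    ``channels`` maps each name in :data:`CHANNELS` to an equal-length
    float array; ``rate`` is the sampling frequency in Hz.
    """

    channels: dict[str, np.ndarray]
    rate: float
    subject_id: str
    sex: str
    age: int
    sensor_position: str

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ConfigurationError(f"sampling rate must be > 0, got {self.rate}")
        missing = [c for c in CHANNELS if c not in self.channels]
        if missing:
            raise DataError(f"recording is missing channels: {missing}")
        lengths = {len(np.asarray(self.channels[c])) for c in CHANNELS}
        if len(lengths) != 1:
            raise DataError(f"channels have unequal lengths: {sorted(lengths)}")
        if lengths.pop() < 2:
            raise DataError("recording must contain at least 2 samples")
        self.channels = {c: np.asarray(self.channels[c], dtype=float) for c in CHANNELS}

    def __len__(self) -> int:
        return len(self.channels[CHANNELS[0]])


@dataclass
class Window:
    """One fixed-length segment carrying all seven components and its labels.

    ``residual_std`` optionally records, per sensed channel, the standard
    deviation of the denoising residual (raw minus denoised) inside this
    window; the feature extractor exposes it as ``<channel>-res-std``.
    """

    channels: dict[str, np.ndarray]
    start_time: float
    rate: float
    subject_id: str
    sex: str
    age: int
    sensor_position: str
    residual_std: dict[str, float] | None = None

    def __post_init__(self) -> None:
        lengths = {len(self.channels[c]) for c in self.channels}
        if len(lengths) != 1:
            raise DataError("window channels must have equal length")

    @property
    def duration(self) -> float:
        return len(self.channels[COMPONENTS[0]]) / self.rate


@dataclass(frozen=True)
class WaveletSettings:
    """Wavelet-shrinkage settings (Daubechies-4, level 3, soft universal threshold)."""

    family: str = "db4"
    level: int = 3
    threshold: str = "soft"  # pywt thresholding mode: "soft" or "hard"


@dataclass(frozen=True)
class PreprocessSettings:
    window_seconds: float = 3.0
    overlap: float = 0.5
    denoise: bool = True
    #: denoise the whole recording before segmenting (avoids window-edge
    #: artifacts); set False to window first and denoise each segment.
    denoise_first: bool = True
    wavelet: WaveletSettings = field(default_factory=WaveletSettings)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_recording(path, metadata: Mapping) -> ImuRecording:
    """Read a recording CSV (columns t, ax, ay, az, gx, gy, gz).

    ``metadata`` must provide subject_id, sex, age and sensor position
    (key ``position`` or ``sensor_position``).  Timestamps must be strictly
    increasing; they are used only to infer the sampling rate, the signal is
    assumed uniformly sampled.
    """
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    if len(df) < 2:
        raise DataError(f"{path}: need at least 2 rows, got {len(df)}")
    t = df["t"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise DataError(f"{path}: timestamps are not strictly increasing")
    rate = 1.0 / float(np.median(dt))
    position = metadata.get("position", metadata.get("sensor_position"))
    return ImuRecording(
        channels={ch: df[col].to_numpy(dtype=float) for col, ch in _CSV_TO_CHANNEL.items()},
        rate=rate,
        subject_id=str(metadata["subject_id"]),
        sex=str(metadata["sex"]),
        age=int(metadata["age"]),
        sensor_position=str(position),
    )


def write_recording(recording: ImuRecording, path) -> None:
    """Write a recording to CSV in the dialect accepted by :func:`read_recording`."""
    n = len(recording)
    data = {"t": np.arange(n) / recording.rate}
    for col, ch in _CSV_TO_CHANNEL.items():
        data[col] = recording.channels[ch]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def compute_net_acceleration(ax, ay, az) -> np.ndarray:
    """Element-wise Euclidean norm of the three acceleration axes."""
    ax, ay, az = (np.asarray(a, dtype=float) for a in (ax, ay, az))
    if not (len(ax) == len(ay) == len(az)):
        raise DataError(
            f"acceleration axes have unequal lengths: {len(ax)}, {len(ay)}, {len(az)}"
        )
    return np.sqrt(ax * ax + ay * ay + az * az)


def denoise(channel, settings: WaveletSettings = WaveletSettings()) -> np.ndarray:
    """Wavelet-shrinkage denoising of one channel.

    The channel is decomposed with a discrete wavelet transform, the detail
    coefficients are shrunk with the universal threshold
    sigma * sqrt(2 log n) — sigma estimated from the median absolute
    deviation of the finest-scale details — and the signal is reconstructed.
    Output length equals input length.  If the channel is too short for the
    requested level, a lower level is used with a warning.
    """
    x = np.asarray(channel, dtype=float)
    n = len(x)
    if n < 2:
        return x.copy()
    wavelet = pywt.Wavelet(settings.family)
    max_level = pywt.dwt_max_level(n, wavelet.dec_len)
    level = settings.level
    if max_level < 1:
        warnings.warn(f"channel of length {n} too short for wavelet denoising; returned as-is")
        return x.copy()
    if level > max_level:
        warnings.warn(
            f"wavelet level {level} too deep for length {n}; falling back to level {max_level}"
        )
        level = max_level
    coeffs = pywt.wavedec(x, wavelet, level=level)
    finest = coeffs[-1]
    sigma = float(np.median(np.abs(finest - np.median(finest)))) / 0.6745
    thr = sigma * np.sqrt(2.0 * np.log(n))
    if thr == 0.0:  # noiseless details: nothing to shrink
        return x.copy()
    shrunk = [coeffs[0]] + [
        pywt.threshold(c, thr, mode=settings.threshold) for c in coeffs[1:]
    ]
    out = pywt.waverec(shrunk, wavelet)
    return out[:n]


def segment(
    recording: ImuRecording,
    window_s: float = 3.0,
    overlap: float = 0.5,
    net: np.ndarray | None = None,
    residuals: dict[str, np.ndarray] | None = None,
) -> list[Window]:
    """Cut a recording into overlapping fixed-length windows.

    Window length W = round(window_s * rate) samples, stride
    S = round(W * (1 - overlap)); a trailing partial window is dropped so
    every window has identical length (and hence identical spectral
    resolution).  ``net`` supplies the precomputed accl-net channel (computed
    here from the stored axes if omitted); ``residuals`` optionally carries
    per-channel denoising residuals from which each window's residual spread
    is recorded.
    """
    if not 0.0 <= overlap < 1.0:
        raise ConfigurationError(f"overlap must be in [0, 1), got {overlap}")
    W = int(round(window_s * recording.rate))
    S = int(round(W * (1.0 - overlap)))
    if W < 2 or S < 1:
        raise ConfigurationError(f"degenerate window: W={W} samples, stride={S}")
    L = len(recording)
    if L < W:
        warnings.warn(
            f"recording {recording.subject_id}: {L} samples shorter than one "
            f"{W}-sample window; no windows produced"
        )
        return []
    if net is None:
        net = compute_net_acceleration(
            recording.channels["accl-x"],
            recording.channels["accl-y"],
            recording.channels["accl-z"],
        )
    count = (L - W) // S + 1
    windows: list[Window] = []
    for k in range(count):
        lo, hi = k * S, k * S + W
        chans = {c: recording.channels[c][lo:hi].copy() for c in CHANNELS}
        chans["accl-net"] = net[lo:hi].copy()
        res_std = None
        if residuals is not None:
            res_std = {c: float(np.std(residuals[c][lo:hi])) for c in residuals}
        windows.append(
            Window(
                channels=chans,
                start_time=lo / recording.rate,
                rate=recording.rate,
                subject_id=recording.subject_id,
                sex=recording.sex,
                age=recording.age,
                sensor_position=recording.sensor_position,
                residual_std=res_std,
            )
        )
    return windows


def preprocess_recording(
    recording: ImuRecording, settings: PreprocessSettings = PreprocessSettings()
) -> list[Window]:
    """Denoise, add net acceleration, and segment a recording into windows."""
    if not settings.denoise:
        return segment(recording, settings.window_seconds, settings.overlap)
    if settings.denoise_first:
        den = {c: denoise(recording.channels[c], settings.wavelet) for c in CHANNELS}
        residuals = {c: recording.channels[c] - den[c] for c in CHANNELS}
        clean = replace(recording, channels=den)
        net = compute_net_acceleration(den["accl-x"], den["accl-y"], den["accl-z"])
        return segment(clean, settings.window_seconds, settings.overlap, net=net,
                       residuals=residuals)
    # window-first variant: segment the raw recording, then denoise per window
    windows = segment(recording, settings.window_seconds, settings.overlap)
    out = []
    for w in windows:
        den = {c: denoise(w.channels[c], settings.wavelet) for c in CHANNELS}
        res_std = {c: float(np.std(w.channels[c] - den[c])) for c in CHANNELS}
        den["accl-net"] = compute_net_acceleration(den["accl-x"], den["accl-y"], den["accl-z"])
        out.append(replace(w, channels=den, residual_std=res_std))
    return out
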
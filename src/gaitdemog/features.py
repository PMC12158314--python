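"""Hand-crafted gait feature catalogue: time, jerk, frequency and correlation domains.

Every 3 s window yields one named feature vector over the seven components
(accl-x/y/z, accl-net, gyro-x/y/z).  Names follow the
``accl|gyro-axis-descriptor`` convention, e.g.
``accl-net-positive-peak-interval-mean`` (average step interval, ms) or
``gyro-y-bandwidth-psd-lower-bound`` (frequency at which cumulative spectral
power of the lateral-twist channel reaches 10% of the total, Hz).

Feature families
----------------
time domain
    mean, std, min, max, skewness, excess kurtosis, inter-quartile range,
    mean absolute deviation, energy per second, and peak statistics
    (count rate, value mean/std, interval mean/std in ms) for positive
    peaks, negative peaks and the unqualified "peak" alias (positive maxima).
jerk domain
    the same statistics on the first time-derivative of each channel.
frequency domain
    spectral moments of the FFT magnitude spectrum (``-freq`` suffix) and
    of the Welch power spectral density (``-psd`` suffix): mean/min/max
    frequency, peak frequency, skewness and kurtosis of frequency,
    normalized spectral entropy, and 10%/90% cumulative-power bandwidth
    bounds; plus per-band total power, percentage of total power and
    max-power frequency over six 3 Hz bands between 0 and 18 Hz
    (Delta, Theta, Alpha, Beta, Gamma, Zeta).
correlation
    Spearman rank correlation for all 21 unordered component pairs.

Missing values (too few peaks for an interval statistic, zero variance, zero
spectral power) are encoded as NaN and median-imputed from the training
split at modelling time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.signal
import scipy.stats

from .errors import DataError
from .preprocess import CHANNELS, COMPONENTS, Window

#: contiguous frequency bands (Hz), inclusive lower / exclusive upper edges
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.0, 3.0),
    "theta": (3.0, 6.0),
    "alpha": (6.0, 9.0),
    "beta": (9.0, 12.0),
    "gamma": (12.0, 15.0),
    "zeta": (15.0, 18.0),
}


@dataclass(frozen=True)
class PeakSet:
    """Detected peaks of one channel: times (s, strictly increasing), values,
    and the requested polarity."""

    times: np.ndarray
    values: np.ndarray
    polarity: str

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class Spectrum:
    """One-sided spectrum on a uniform grid from 0 to the Nyquist frequency."""

    freqs: np.ndarray
    power: np.ndarray
    method: str  # "fft-magnitude" or "welch-psd"

    @property
    def resolution(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass(frozen=True)
class FeatureSettings:
    """Knobs of the extractor; defaults follow standard practice at 100 Hz.

    A peak is a local extremum beyond the channel mean with at least
    ``peak_min_separation_s`` between consecutive peaks — one peak per step
    at human cadences.  Welch uses ``welch_nperseg``-sample Hann segments
    with 50% overlap.
    """

    peak_min_separation_s: float = 0.2
    welch_nperseg: int = 128
    welch_overlap: float = 0.5
    bands: Mapping[str, tuple[float, float]] = field(default_factory=lambda: dict(BANDS))


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

def detect_peaks(
    channel,
    rate: float,
    polarity: str = "positive",
    settings: FeatureSettings = FeatureSettings(),
) -> PeakSet:
    """Find local maxima above the channel mean (positive) or local minima
    below it (negative), at least ``peak_min_separation_s`` apart."""
    x = np.asarray(channel, dtype=float)
    if len(x) < 3:
        return PeakSet(np.array([]), np.array([]), polarity)
    base = float(np.mean(x))
    distance = max(1, int(round(settings.peak_min_separation_s * rate)))
    if polarity == "positive":
        idx, _ = scipy.signal.find_peaks(x, height=base, distance=distance)
    elif polarity == "negative":
        idx, _ = scipy.signal.find_peaks(-x, height=-base, distance=distance)
    else:
        raise ValueError(f"polarity must be 'positive' or 'negative', got {polarity!r}")
    return PeakSet(times=idx / rate, values=x[idx], polarity=polarity)


def peak_features(peaks: PeakSet, window_s: float, prefix: str) -> dict[str, float]:
    """Peak statistics named ``<prefix>val-mean``, ``<prefix>val-std``,
    ``<prefix>interval-mean`` and ``<prefix>interval-std``.

    Intervals are reported in milliseconds; interval std uses the population
    (n-denominator) form.  The interval mean needs >= 2 peaks and the
    interval std >= 3 peaks; otherwise NaN.
    """
    n = len(peaks)
    out: dict[str, float] = {}
    out[f"{prefix}val-mean"] = float(np.mean(peaks.values)) if n >= 1 else np.nan
    out[f"{prefix}val-std"] = float(np.std(peaks.values)) if n >= 1 else np.nan
    if n >= 2:
        intervals_ms = np.diff(peaks.times) * 1000.0
        out[f"{prefix}interval-mean"] = float(np.mean(intervals_ms))
        out[f"{prefix}interval-std"] = (
            float(np.std(intervals_ms)) if n >= 3 else np.nan
        )
    else:
        out[f"{prefix}interval-mean"] = np.nan
        out[f"{prefix}interval-std"] = np.nan
    return out


# ---------------------------------------------------------------------------
# time / jerk domain
# ---------------------------------------------------------------------------

def time_domain_features(channel, rate: float, prefix: str) -> dict[str, float]:
    """Distributional statistics of one channel.

    MAD is the mean absolute deviation from the mean; IQR uses
    linear-interpolation quantiles; energy per second is sum(x^2) divided by
    the window duration; skewness/kurtosis are the standardized third moment
    and excess fourth moment (NaN for zero-variance channels).
    """
    x = np.asarray(channel, dtype=float)
    if len(x) < 2:
        raise DataError("time-domain features need at least 2 samples")
    mu = float(np.mean(x))
    sd = float(np.std(x))
    q1, q3 = np.percentile(x, [25, 75])
    duration = len(x) / rate
    out = {
        f"{prefix}mean": mu,
        f"{prefix}std": sd,
        f"{prefix}min": float(np.min(x)),
        f"{prefix}max": float(np.max(x)),
        f"{prefix}iqr": float(q3 - q1),
        f"{prefix}mad": float(np.mean(np.abs(x - mu))),
        f"{prefix}energy-per-second": float(np.sum(x * x) / duration),
    }
    if sd > 0:
        out[f"{prefix}skewness"] = float(scipy.stats.skew(x, bias=True))
        out[f"{prefix}kurtosis"] = float(scipy.stats.kurtosis(x, fisher=True, bias=True))
    else:
        out[f"{prefix}skewness"] = np.nan
        out[f"{prefix}kurtosis"] = np.nan
    return out


def jerk(channel, rate: float) -> np.ndarray:
    """First time-derivative of a channel (first difference times rate);
    output is one sample shorter than the input."""
    x = np.asarray(channel, dtype=float)
    if len(x) < 2:
        raise DataError("jerk needs at least 2 samples")
    return np.diff(x) * rate


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def fft_spectrum(channel, rate: float) -> Spectrum:
    """One-sided FFT power spectrum normalized so total power equals the
    signal energy sum(x^2) (Parseval)."""
    x = np.asarray(channel, dtype=float)
    n = len(x)
    if n < 2:
        raise DataError("fft_spectrum needs at least 2 samples")
    X = np.fft.rfft(x)
    P = np.abs(X) ** 2 / n
    if n % 2 == 0:
        P[1:-1] *= 2.0
    else:
        P[1:] *= 2.0
    return Spectrum(freqs=np.fft.rfftfreq(n, d=1.0 / rate), power=P, method="fft-magnitude")


def welch_psd(
    channel, rate: float, settings: FeatureSettings = FeatureSettings()
) -> Spectrum:
    """Welch power spectral density (Hann window, 50% overlapping segments)."""
    x = np.asarray(channel, dtype=float)
    nperseg = settings.welch_nperseg
    if len(x) < nperseg:
        raise DataError(
            f"welch_psd needs at least {nperseg} samples, got {len(x)}"
        )
    noverlap = int(round(nperseg * settings.welch_overlap))
    freqs, power = scipy.signal.welch(
        x, fs=rate, window="hann", nperseg=nperseg, noverlap=noverlap, detrend=False
    )
    return Spectrum(freqs=freqs, power=power, method="welch-psd")


def spectral_features(spec: Spectrum, prefix: str) -> dict[str, float]:
    """Moments of the power-normalized spectrum treated as a distribution
    over frequency, plus 10%/90% cumulative-power bandwidth bounds.

    Names depend on the spectrum type: the FFT spectrum yields
    ``<c>-mean-freq`` ... ``<c>-skewness-freq`` / ``<c>-kurtosis-freq`` /
    ``<c>-spectral-entropy-freq`` / ``<c>-bandwidth-fft-*-bound``; the Welch
    PSD yields ``<c>-mean-freq-psd`` ... ``<c>-skew-freq-psd`` /
    ``<c>-kurt-freq-psd`` / ``<c>-spectral-entropy-psd`` /
    ``<c>-bandwidth-psd-*-bound``.  Min/max frequency are the extreme
    frequencies carrying nonzero power; spectral entropy is normalized to
    [0, 1] by log(number of bins).  All NaN when total power is zero.
    """
    if spec.method == "welch-psd":
        names = dict(mean="mean-freq-psd", mn="min-freq-psd", mx="max-freq-psd",
                     peak="peak-freq-psd", skew="skew-freq-psd", kurt="kurt-freq-psd",
                     ent="spectral-entropy-psd", lo="bandwidth-psd-lower-bound",
                     hi="bandwidth-psd-upper-bound")
    else:
        names = dict(mean="mean-freq", mn="min-freq", mx="max-freq",
                     peak="peak-freq", skew="skewness-freq", kurt="kurtosis-freq",
                     ent="spectral-entropy-freq", lo="bandwidth-fft-lower-bound",
                     hi="bandwidth-fft-upper-bound")
    f, P = spec.freqs, np.asarray(spec.power, dtype=float)
    total = float(P.sum())
    if total <= 0 or not np.isfinite(total):
        return {f"{prefix}{v}": np.nan for v in names.values()}
    p = P / total
    mean = float(np.sum(p * f))
    var = float(np.sum(p * (f - mean) ** 2))
    sd = np.sqrt(var)
    nz = P > 0
    cum = np.cumsum(p)
    out = {
        f"{prefix}{names['mean']}": mean,
        f"{prefix}{names['mn']}": float(f[nz][0]),
        f"{prefix}{names['mx']}": float(f[nz][-1]),
        f"{prefix}{names['peak']}": float(f[np.argmax(P)]),
        f"{prefix}{names['lo']}": float(f[np.searchsorted(cum, 0.1)]),
        f"{prefix}{names['hi']}": float(f[np.searchsorted(cum, 0.9)]),
    }
    if sd > 0:
        out[f"{prefix}{names['skew']}"] = float(np.sum(p * (f - mean) ** 3) / sd**3)
        out[f"{prefix}{names['kurt']}"] = float(np.sum(p * (f - mean) ** 4) / var**2 - 3.0)
    else:
        out[f"{prefix}{names['skew']}"] = np.nan
        out[f"{prefix}{names['kurt']}"] = np.nan
    pn = p[nz]
    out[f"{prefix}{names['ent']}"] = (
        float(-np.sum(pn * np.log(pn)) / np.log(len(P))) if len(P) > 1 else 0.0
    )
    return out


def band_features(
    spec: Spectrum, bands: Mapping[str, tuple[float, float]], prefix: str
) -> dict[str, float]:
    """Per-band total power, percentage of total spectrum power (0-100), and
    the frequency of maximum power within the band."""
    f, P = spec.freqs, np.asarray(spec.power, dtype=float)
    total = float(P.sum())
    out: dict[str, float] = {}
    for name, (lo, hi) in bands.items():
        mask = (f >= lo) & (f < hi)
        band_power = float(P[mask].sum()) if mask.any() else np.nan
        out[f"{prefix}total-power-{name}-band-psd"] = band_power
        out[f"{prefix}percentage-power-{name}-band-psd"] = (
            100.0 * band_power / total if total > 0 else np.nan
        )
        if mask.any() and band_power > 0:
            out[f"{prefix}max-freq-{name}-band-psd"] = float(f[mask][np.argmax(P[mask])])
        else:
            out[f"{prefix}max-freq-{name}-band-psd"] = np.nan
    return out


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks,
    equivalent to 1 - 6*sum(d_i^2)/(n(n^2-1)) when there are no ties.
    NaN if either input is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise DataError(f"spearman inputs have unequal lengths {len(x)} and {len(y)}")
    if len(x) < 2:
        raise DataError("spearman needs at least 2 observations")
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return np.nan
    return float(np.corrcoef(rx, ry)[0, 1])


# ---------------------------------------------------------------------------
# full catalogue
# ---------------------------------------------------------------------------

def _peak_block(x, rate: float, window_s: float, comp_prefix: str,
                settings: FeatureSettings) -> dict[str, float]:
    pos = detect_peaks(x, rate, "positive", settings)
    neg = detect_peaks(x, rate, "negative", settings)
    out = peak_features(pos, window_s, f"{comp_prefix}positive-peak-")
    out.update(peak_features(neg, window_s, f"{comp_prefix}negative-peak-"))
    # unqualified "peak" features alias the positive maxima
    out.update(peak_features(pos, window_s, f"{comp_prefix}peak-"))
    out[f"{comp_prefix}peaks-per-second"] = len(pos) / window_s
    return out


def extract_all(
    window: Window, settings: FeatureSettings = FeatureSettings()
) -> dict[str, float]:
    """Compute the full feature vector for one window (deterministic;
    insertion order is fixed by the component list)."""
    out: dict[str, float] = {}
    rate = window.rate
    window_s = window.duration
    for comp in COMPONENTS:
        x = window.channels[comp]
        pfx = f"{comp}-"
        out.update(time_domain_features(x, rate, pfx))
        out.update(_peak_block(x, rate, window_s, pfx, settings))
        j = jerk(x, rate)
        jfx = f"{comp}-jerk-"
        out.update(time_domain_features(j, rate, jfx))
        out.update(_peak_block(j, rate, window_s, jfx, settings))
        out.update(spectral_features(fft_spectrum(x, rate), pfx))
        psd = welch_psd(x, rate, settings)
        out.update(spectral_features(psd, pfx))
        out.update(band_features(psd, settings.bands, pfx))
    if window.residual_std is not None:
        for comp in CHANNELS:
            out[f"{comp}-res-std"] = window.residual_std.get(comp, np.nan)
    for i, a in enumerate(COMPONENTS):
        for b in COMPONENTS[i + 1:]:
            out[f"{a}-{b}-spearman"] = spearman(window.channels[a], window.channels[b])
    return out


LABEL_COLUMNS = ("subject_id", "sex", "age", "position", "start_time")


def extract_table(
    windows: Iterable[Window], settings: FeatureSettings = FeatureSettings()
) -> pd.DataFrame:
    """Tidy feature table: one row per window, feature columns followed by
    the label columns subject_id, sex, age, position, start_time."""
    rows = []
    for w in windows:
        row = extract_all(w, settings)
        row.update(
            subject_id=w.subject_id, sex=w.sex, age=w.age,
            position=w.sensor_position, start_time=w.start_time,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def feature_names(df: pd.DataFrame) -> list[str]:
    """Feature columns of a table produced by :func:`extract_table`."""
    return [c for c in df.columns if c not in LABEL_COLUMNS]


def feature_unit(name: str) -> str:
    """Unit of a feature by naming convention.

    Peak-interval statistics are in ms; frequency-valued features in Hz;
    percentages in percent; entropy, correlations and shape statistics are
    dimensionless; everything else carries the channel's own unit
    (g for accelerometer-derived values, rad/s for gyroscope-derived).
    """
    if name.endswith("-spearman") or "entropy" in name:
        return "dimensionless"
    if "interval-mean" in name or "interval-std" in name:
        return "ms"
    if name.endswith("-bound") or "peaks-per-second" in name:
        return "Hz"
    if ("-freq" in name and "percentage" not in name and "total-power" not in name) or \
            "max-freq" in name:
        return "Hz"
    if "percentage-power" in name:
        return "percent"
    if "skew" in name or "kurt" in name:
        return "dimensionless"
    return "g" if name.startswith("accl") else "rad/s"
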
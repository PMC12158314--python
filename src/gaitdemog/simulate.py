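"""Demographic-conditioned synthetic waist-IMU gait generator.

The restricted corpora this package targets (large waist-IMU gait databases
with sex and age labels) cannot be redistributed, so the package ships a
seeded generator that emulates their structure: quasi-periodic walking
signals whose per-subject parameters are drawn from sex- and age-conditioned
maps.  The generator is a study fixture — it plants known parameters so the
downstream feature extractor and models can be validated against ground
truth — not a biomechanical simulation.

Waveform model (per recording):

* vertical acceleration (accl-y) = gravity offset + one Gaussian-windowed
  pulse per step, pulse onsets ``step_interval_mean`` apart with i.i.d.
  Gaussian timing jitter — so a peak detector finds exactly one peak per
  step;
* forward acceleration (accl-z) = a sinusoid at the step frequency plus a
  10.5 Hz sinusoid carrying a controllable fraction ``hf_power_frac`` of the
  channel's signal power (the "beta band" 9-12 Hz dial);
* lateral acceleration (accl-x) and the three gyroscope channels (forward
  tilt gx, lateral twist gy, vertical swing gz) are sinusoids at the step or
  stride (= half step) frequency;
* independent white Gaussian noise on every channel.

The default sex/age parameter maps place the male/female gaps of the
population the package emulates: mean step interval 466.81 vs 433.44 ms,
step-interval jitter 92.47 vs 81.71 ms, and 9-12 Hz power fraction 6.5% vs
4.54% of the forward-acceleration signal, with piecewise-linear age trends
(short erratic strides in children, stable adult gait, slower and weaker
steps in the elderly).  Amplitude means are sex-conditioned as well (larger
step force in males, stronger lateral twist in females); see
docs/methods.md for the calibration rationale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigurationError
from .preprocess import CHANNELS, ImuRecording

SEXES = ("male", "female")
POSITIONS = ("center", "left", "right")

#: width (s) of the Gaussian step pulse on the vertical channel
_PULSE_SIGMA_S = 0.05
#: frequency (Hz) at which the high-frequency power fraction is injected
_HF_TONE_HZ = 10.5


@dataclass(frozen=True)
class GaitParams:
    """Per-subject gait parameters planted into a synthetic recording.

    Units: step interval quantities in ms; acceleration amplitudes in g;
    angular-velocity amplitudes in rad/s; ``hf_power_frac`` is the fraction
    in [0, 1) of forward-acceleration signal power injected at 10.5 Hz;
    ``noise_sd`` applies in g to accelerometer channels and rad/s to
    gyroscope channels.
    """

    step_interval_mean: float
    step_interval_jitter_sd: float = 0.0
    vertical_amp: float = 0.5
    forward_amp: float = 0.3
    lateral_amp: float = 0.18
    twist_amp: float = 0.8
    tilt_amp: float = 0.6
    swing_amp: float = 0.7
    hf_power_frac: float = 0.05
    noise_sd: float = 0.03
    gravity_offset: float = 1.0

    def __post_init__(self) -> None:
        if self.step_interval_mean <= 0:
            raise ConfigurationError(
                f"step_interval_mean must be > 0 ms, got {self.step_interval_mean}"
            )
        for name in ("step_interval_jitter_sd", "vertical_amp", "forward_amp",
                     "lateral_amp", "twist_amp", "tilt_amp", "swing_amp", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.hf_power_frac < 1.0:
            raise ConfigurationError(
                f"hf_power_frac must be in [0, 1), got {self.hf_power_frac}"
            )


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    sex: str
    age: int
    sensor_position: str
    params: GaitParams

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ConfigurationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.sensor_position not in POSITIONS:
            raise ConfigurationError(
                f"sensor_position must be one of {POSITIONS}, got {self.sensor_position!r}"
            )
        if not 2 <= self.age <= 78:
            raise ConfigurationError(f"age must be within [2, 78], got {self.age}")


# ---------------------------------------------------------------------------
# default sex/age parameter map
# ---------------------------------------------------------------------------

# Sex-conditional means and between-subject spreads.  Step interval, jitter
# and high-frequency fraction use the group means of the emulated
# population; amplitudes are free calibration choices (see docs/methods.md).
_SEX_MAP = {
    "male": dict(
        step_mu=466.81, step_sd=60.0,
        jitter_mu=92.47, jitter_sd=22.8,
        hf_mu=0.065, hf_sd=0.0366,
        vert_mu=0.55, fwd_mu=0.34, twist_mu=0.75,
    ),
    "female": dict(
        step_mu=433.44, step_sd=60.0,
        jitter_mu=81.71, jitter_sd=22.94,
        hf_mu=0.0454, hf_sd=0.0332,
        vert_mu=0.42, fwd_mu=0.27, twist_mu=0.95,
    ),
}
_VERT_SD = 0.08
_FWD_SD = 0.05
_TWIST_SD = 0.10


def _trend(age: float, knots: Sequence[tuple[float, float]]) -> float:
    xs, ys = zip(*knots)
    return float(np.interp(age, xs, ys))


def default_parameter_map(sex: str, age: int, rng: np.random.Generator) -> GaitParams:
    """Draw one subject's :class:`GaitParams` from the default (sex, age) map.

    Age trends are piecewise linear: children take shorter, jerkier, noisier
    steps with more body swing; adult gait is stable; elderly gait slows,
    weakens and becomes slightly noisier again.
    """
    if sex not in _SEX_MAP:
        raise ConfigurationError(f"unknown sex {sex!r}")
    m = _SEX_MAP[sex]
    if sex == "male":
        step_off = _trend(age, [(2, -90), (20, 0), (50, 0), (60, 10), (78, 40)])
    else:
        step_off = _trend(age, [(2, -80), (15, 0), (30, 0), (78, -40)])
    jitter_mult = _trend(age, [(2, 1.6), (15, 1.0), (60, 1.0), (78, 1.25)])
    tilt_mult = _trend(age, [(2, 1.5), (15, 1.0), (78, 0.9)])
    swing_mult = _trend(age, [(2, 1.6), (10, 1.3), (20, 1.0), (78, 0.85)])
    amp_mult = _trend(age, [(2, 0.9), (20, 1.0), (50, 1.0), (78, 0.8)])
    noise_mult = _trend(age, [(2, 1.5), (12, 1.0), (30, 1.0), (78, 1.2)])

    step = max(250.0, m["step_mu"] + step_off + rng.normal(0.0, m["step_sd"]))
    jitter = max(0.0, jitter_mult * rng.normal(m["jitter_mu"], m["jitter_sd"]))
    hf = float(np.clip(rng.normal(m["hf_mu"], m["hf_sd"]), 0.0, 0.45))
    return GaitParams(
        step_interval_mean=step,
        step_interval_jitter_sd=jitter,
        vertical_amp=max(0.05, amp_mult * rng.normal(m["vert_mu"], _VERT_SD)),
        forward_amp=max(0.03, amp_mult * rng.normal(m["fwd_mu"], _FWD_SD)),
        lateral_amp=max(0.02, rng.normal(0.18, 0.04)),
        twist_amp=max(0.05, rng.normal(m["twist_mu"], _TWIST_SD)),
        tilt_amp=max(0.05, tilt_mult * rng.normal(0.6, 0.10)),
        swing_amp=max(0.05, swing_mult * rng.normal(0.7, 0.12)),
        hf_power_frac=hf,
        noise_sd=max(0.005, noise_mult * rng.normal(0.03, 0.006)),
    )


#: default age-bin weights, skewed young with few elderly subjects, matching
#: the imbalanced age pyramid typical of inertial gait databases
DEFAULT_AGE_DISTRIBUTION: tuple[tuple[tuple[int, int], float], ...] = (
    ((2, 10), 0.25),
    ((11, 20), 0.30),
    ((21, 30), 0.20),
    ((31, 40), 0.10),
    ((41, 50), 0.07),
    ((51, 60), 0.05),
    ((61, 78), 0.03),
)


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a simulated cohort.

    ``sex_ratio`` is the probability of drawing a male subject (default
    389/744, the sex balance of the emulated population);
    ``age_distribution`` is a list of ((low, high) age bin, weight) pairs;
    ``sexage_parameter_map`` maps (sex, age, rng) to a :class:`GaitParams`.
    """

    n_subjects: int = 200
    sex_ratio: float = 389 / 744
    age_distribution: tuple = DEFAULT_AGE_DISTRIBUTION
    recording_duration: float = 30.0
    sampling_rate: float = 100.0
    seed: int = 0
    position_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    sexage_parameter_map: Callable[[str, int, np.random.Generator], GaitParams] = (
        default_parameter_map
    )

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ConfigurationError(f"sex_ratio must be in [0, 1], got {self.sex_ratio}")
        if len(self.age_distribution) == 0:
            raise ConfigurationError("age_distribution must not be empty")
        weights = np.array([w for _, w in self.age_distribution], dtype=float)
        if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0):
            raise ConfigurationError("age_distribution weights must be >= 0 and sum to 1")
        if self.recording_duration < 6.0:
            raise ConfigurationError("recording_duration must be >= 6 s (>= 2 windows)")
        if self.sampling_rate <= 2 * 18.0:
            raise ConfigurationError("sampling_rate must exceed twice the highest modelled frequency")


# ---------------------------------------------------------------------------
# sampling and synthesis
# ---------------------------------------------------------------------------

def sample_subject_profile(
    config: CohortConfig, rng: np.random.Generator, subject_id: str = "S0000"
) -> SubjectProfile:
    """Draw one subject: sex per ``sex_ratio``, age per ``age_distribution``,
    sensor position per ``position_weights``, parameters from the (sex, age)
    map.  Center-worn sensors attenuate the motion amplitudes slightly (the
    back of the waist sits farther from the legs than the sides)."""
    sex = "male" if rng.random() < config.sex_ratio else "female"
    weights = np.array([w for _, w in config.age_distribution], dtype=float)
    bin_idx = int(rng.choice(len(weights), p=weights / weights.sum()))
    lo, hi = config.age_distribution[bin_idx][0]
    age = int(rng.integers(lo, hi + 1))
    pos = POSITIONS[int(rng.choice(3, p=np.asarray(config.position_weights) /
                                   np.sum(config.position_weights)))]
    params = config.sexage_parameter_map(sex, age, rng)
    if pos == "center":
        params = replace(
            params,
            vertical_amp=0.85 * params.vertical_amp,
            forward_amp=0.85 * params.forward_amp,
            lateral_amp=0.85 * params.lateral_amp,
            twist_amp=0.85 * params.twist_amp,
            tilt_amp=0.85 * params.tilt_amp,
            swing_amp=0.85 * params.swing_amp,
        )
    return SubjectProfile(subject_id=subject_id, sex=sex, age=age,
                          sensor_position=pos, params=params)


def synthesize_recording(
    profile: SubjectProfile,
    duration: float,
    rate: float,
    rng: np.random.Generator,
) -> ImuRecording:
    """Render one synthetic recording from a subject profile.

    Deterministic given (profile, duration, rate, rng state); the stream is
    consumed in a fixed order (phases, step jitter, then noise), so two
    parameter sets differing only in a deterministic dial (e.g.
    ``hf_power_frac``) see identical noise realizations under the same seed.
    """
    if rate <= 0:
        raise ConfigurationError(f"rate must be > 0, got {rate}")
    n = int(round(duration * rate))
    if n < 2:
        raise ConfigurationError("duration * rate must be >= 2 samples")
    p = profile.params
    t = np.arange(n) / rate
    T = p.step_interval_mean / 1000.0  # step period, s
    f_step = 1.0 / T
    f_stride = f_step / 2.0

    # fixed draw order: 6 phases, pulse onsets, then 6 noise channels
    phases = rng.uniform(0.0, 2.0 * np.pi, size=6)
    n_steps = int(np.ceil(duration / T)) + 3
    jitter = rng.normal(0.0, p.step_interval_jitter_sd / 1000.0, size=n_steps)
    intervals = np.maximum(0.25 * T, T + jitter)
    onsets = 0.35 * T + np.concatenate(([0.0], np.cumsum(intervals)))
    onsets = onsets[onsets < duration + 2 * _PULSE_SIGMA_S]

    ay = np.full(n, p.gravity_offset)
    for tk in onsets:
        ay += p.vertical_amp * np.exp(-0.5 * ((t - tk) / _PULSE_SIGMA_S) ** 2)

    az = p.forward_amp * np.sin(2 * np.pi * f_step * t + phases[0])
    if p.hf_power_frac > 0 and p.forward_amp > 0:
        # amplitude such that the 10.5 Hz tone carries hf_power_frac of the
        # channel's (noise-free) signal power
        a_hf = p.forward_amp * np.sqrt(p.hf_power_frac / (1.0 - p.hf_power_frac))
        az = az + a_hf * np.sin(2 * np.pi * _HF_TONE_HZ * t + phases[1])
    ax = p.lateral_amp * np.sin(2 * np.pi * f_stride * t + phases[2])
    gx = p.tilt_amp * np.sin(2 * np.pi * f_step * t + phases[3])
    gy = p.twist_amp * np.sin(2 * np.pi * f_stride * t + phases[4])
    gz = p.swing_amp * np.sin(2 * np.pi * f_stride * t + phases[5])

    signals = dict(zip(CHANNELS, (ax, ay, az, gx, gy, gz)))
    if p.noise_sd > 0:
        for c in CHANNELS:
            signals[c] = signals[c] + rng.normal(0.0, p.noise_sd, size=n)
    return ImuRecording(
        channels=signals,
        rate=rate,
        subject_id=profile.subject_id,
        sex=profile.sex,
        age=profile.age,
        sensor_position=profile.sensor_position,
    )


def generate_cohort(config: CohortConfig) -> list[tuple[ImuRecording, SubjectProfile]]:
    """Generate the full cohort; per-subject RNG streams are derived from
    (seed, subject index) so the output is order-independent and reproducible."""
    out = []
    for i in range(config.n_subjects):
        rng = np.random.default_rng([config.seed, i])
        profile = sample_subject_profile(config, rng, subject_id=f"S{i:04d}")
        rec = synthesize_recording(
            profile, config.recording_duration, config.sampling_rate, rng
        )
        out.append((rec, profile))
    return out


def cohort_metadata(items: list[tuple[ImuRecording, SubjectProfile]]):
    """Cohort label table as a DataFrame (subject_id, sex, age, position)."""
    import pandas as pd

    return pd.DataFrame(
        [
            dict(subject_id=p.subject_id, sex=p.sex, age=p.age,
                 position=p.sensor_position)
            for _, p in items
        ]
    )


def write_cohort(items, out_dir) -> None:
    """Write one CSV per recording plus a cohort metadata CSV."""
    from pathlib import Path

    from .preprocess import write_recording

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = cohort_metadata(items)
    files = []
    for rec, prof in items:
        fname = f"{prof.subject_id}.csv"
        write_recording(rec, out / fname)
        files.append(fname)
    meta["file"] = files
    meta.to_csv(out / "metadata.csv", index=False)
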
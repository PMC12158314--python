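import numpy as np
import pandas as pd
import pytest

from gaitdemog import (GaitParams, SubjectProfile, preprocess_recording,
                       synthesize_recording)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_window():
    """One denoised window from a noiseless 450 ms pulse-train recording."""
    params = GaitParams(step_interval_mean=450.0, step_interval_jitter_sd=0.0,
                        noise_sd=0.0)
    profile = SubjectProfile("S0001", "male", 30, "center", params)
    rec = synthesize_recording(profile, 30.0, 100.0, np.random.default_rng(7))
    return preprocess_recording(rec)[3]


def make_feature_frame(n_subjects=40, windows_per_subject=5, n_features=10,
                       seed=0, sex_effect=1.5):
    """Synthetic window-level feature table: feature 0 carries a sex effect,
    the rest are noise; ages are uniform in [5, 70]."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        sex = "male" if i % 2 == 0 else "female"
        age = int(rng.integers(5, 71))
        centre = rng.normal(0.0, 1.0, n_features)
        centre[0] += sex_effect if sex == "male" else 0.0
        for w in range(windows_per_subject):
            feats = centre + rng.normal(0.0, 0.3, n_features)
            row = {f"f{j:02d}": feats[j] for j in range(n_features)}
            row.update(subject_id=f"S{i:04d}", sex=sex, age=age,
                       position="center", start_time=float(w))
            rows.append(row)
    return pd.DataFrame(rows)
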
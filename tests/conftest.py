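import numpy as np
import pandas as pd
import pytest

from pupilddm.preprocess import PupilSamples


@pytest.fixture
def flat_stream():
    """20 s of constant 3 mm pupil at 250 Hz, gaze on fixation."""
    n = 5000
    t = np.arange(n) / 250.0
    return PupilSamples(time=t, diameter=np.full(n, 3.0),
                        gaze_x=np.zeros(n), gaze_y=np.zeros(n),
                        valid=np.ones(n, dtype=bool))


@pytest.fixture
def rng():
    return np.random.default_rng(20140918)


def make_trials(n_subjects=3, n_trials=80, seed=0, coupled=False):
    """Cheap behavioral fixture with pupil-independent (or coupled) RTs."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        pupil = rng.normal(4.5, 0.4, n_trials)
        pz = (pupil - pupil.mean()) / pupil.std()
        p_err = 0.18 + (0.08 * pz if coupled else 0.0)
        acc = (rng.random(n_trials) > np.clip(p_err, 0.02, 0.6)).astype(int)
        rt = np.exp(rng.normal(-0.35, 0.2, n_trials))
        if coupled:
            rt *= np.exp(0.12 * (1 - acc) * pz)
        rows.append(pd.DataFrame({
            "subject": s, "trial": np.arange(n_trials),
            "rt": np.clip(rt, 0.15, 1.45), "accuracy": acc,
            "baseline_pupil": pupil,
            "gaze_x": rng.normal(0, 0.5, n_trials),
            "gaze_y": rng.normal(0, 0.5, n_trials)}))
    return pd.concat(rows, ignore_index=True)
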
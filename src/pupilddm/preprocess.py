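"""Pupillometry preprocessing: scaling, blink interpolation, artifact
rejection, per-trial baselines, trial exclusion and pupil binning.

The chain mirrors standard tonic-arousal pupillometry practice: convert the
eyetracker's pixel units to mm with a subject-specific scale, linearly
interpolate blink dropouts shorter than 1 s, flag artifactual samples by
amplitude (< 1 mm), sample-to-sample gradient (> 0.02 mm) and gaze
eccentricity (> 5 degrees), average the 1 s preceding motion onset into a
per-trial baseline, and split each subject's retained trials into the
lowest and highest two-fifths of baseline values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "PupilSamples",
    "px_to_mm",
    "interpolate_blinks",
    "flag_artifacts",
    "baseline_per_trial",
    "exclude_trials",
    "bin_by_pupil",
]


@dataclass
class PupilSamples:
    """Uniformly sampled eyetracker stream.

    time is a strictly increasing uniform grid (s); diameter in mm or px
    (tracked by ``units``); gaze in degrees from fixation; ``valid`` marks
    recorded samples, ``interpolated`` marks gap-filled ones.
    """

    time: np.ndarray
    diameter: np.ndarray
    gaze_x: np.ndarray
    gaze_y: np.ndarray
    valid: np.ndarray
    units: str = "mm"
    interpolated: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.time)
        for name in ("diameter", "gaze_x", "gaze_y", "valid"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name} length mismatch")
        dt = np.diff(self.time)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6)):
            raise ValueError("time must be a strictly increasing uniform grid")
        if self.interpolated is None:
            self.interpolated = np.zeros(n, dtype=bool)

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(self.time[1] - self.time[0])


def px_to_mm(samples: PupilSamples, scale: float) -> PupilSamples:
    """Multiply diameter by the mm-per-pixel scale; idempotent once in mm."""
    if scale <= 0:
        raise ValueError(f"scale must be > 0, got {scale}")
    if samples.units == "mm":
        return samples
    return replace(samples, diameter=samples.diameter * scale, units="mm")


def interpolate_blinks(samples: PupilSamples, max_gap: float = 1.0) -> PupilSamples:
    """Linearly interpolate runs of invalid samples strictly shorter than
    ``max_gap`` seconds.

    Interpolated samples are marked in ``interpolated`` (and ``valid``);
    runs at least max_gap long, or touching either stream boundary (no
    flanking anchor), are left invalid.  Valid samples are never changed.
    """
    v = samples.valid
    n = len(v)
    diam = samples.diameter.copy()
    newvalid = v.copy()
    interp = samples.interpolated.copy()
    dt = 1.0 / samples.sampling_rate
    i = 0
    while i < n:
        if v[i]:
            i += 1
            continue
        j = i
        while j < n and not v[j]:
            j += 1
        run = j - i  # invalid run [i, j)
        if i > 0 and j < n and run * dt < max_gap:
            x0, x1 = diam[i - 1], diam[j]
            w = np.arange(1, run + 1) / (run + 1)
            diam[i:j] = x0 + w * (x1 - x0)
            newvalid[i:j] = True
            interp[i:j] = True
        i = j
    return replace(samples, diameter=diam, valid=newvalid, interpolated=interp)


def flag_artifacts(samples: PupilSamples, amp_min: float = 1.0,
                   grad_max: float = 0.02, gaze_max: float = 5.0) -> np.ndarray:
    """Boolean artifact mask over samples (True = artifactual).

    A sample is artifactual if its diameter is below ``amp_min`` mm, its
    absolute difference from the previous sample exceeds ``grad_max`` mm,
    its Euclidean gaze eccentricity exceeds ``gaze_max`` degrees, or it is
    still invalid after interpolation.  Applied to the interpolated stream,
    so gap-filled samples are themselves eligible for flagging.
    """
    if samples.units != "mm":
        raise ValueError("samples must be in mm before artifact flagging")
    d = samples.diameter
    bad = ~samples.valid
    bad = bad | (d < amp_min)
    grad = np.abs(np.diff(d, prepend=d[0]))
    bad = bad | (grad > grad_max)
    ecc = np.hypot(samples.gaze_x, samples.gaze_y)
    bad = bad | (ecc > gaze_max)
    return bad


def baseline_per_trial(samples: PupilSamples, onsets, window: float = 1.0,
                       artifact_mask=None) -> pd.DataFrame:
    """Mean pupil diameter over [onset - window, onset) per trial.

    Returns a frame with ``baseline_pupil`` and ``artifact_flag`` (True if
    any sample in the window is artifactual, in which case the trial is
    excluded downstream and the baseline set to NaN).
    """
    if artifact_mask is None:
        artifact_mask = flag_artifacts(samples)
    fs = samples.sampling_rate
    t0 = samples.time[0]
    n = len(samples.time)
    out_b = np.empty(len(onsets))
    out_f = np.zeros(len(onsets), dtype=bool)
    for j, onset in enumerate(np.asarray(onsets, dtype=float)):
        i1 = int(round((onset - t0) * fs))
        i0 = i1 - int(round(window * fs))
        if i0 < 0 or i1 > n:
            raise ValueError(f"trial {j}: baseline window [{onset - window}, "
                             f"{onset}) falls outside the sample stream")
        if artifact_mask[i0:i1].any():
            out_f[j] = True
            out_b[j] = np.nan
        else:
            out_b[j] = samples.diameter[i0:i1].mean()
    return pd.DataFrame({"baseline_pupil": out_b, "artifact_flag": out_f})


def exclude_trials(trials: pd.DataFrame, rt_floor: float = 0.1,
                   rt_deadline: float = 1.5) -> pd.DataFrame:
    """Drop fast-guess, missed-deadline and artifact trials.

    Per-reason counts land in ``df.attrs['exclusions']``.  Raises if
    nothing survives.
    """
    t = trials.copy()
    fast = t["rt"] <= rt_floor
    slow = t["rt"] > rt_deadline
    art = t["artifact_flag"].astype(bool) if "artifact_flag" in t else \
        pd.Series(False, index=t.index)
    keep = ~(fast | slow | art)
    out = t[keep].copy()
    if out.empty:
        raise ValueError("no trials remain after exclusion")
    out.attrs["exclusions"] = {"fast": int(fast.sum()),
                               "slow": int((slow & ~fast).sum()),
                               "artifact": int((art & ~fast & ~slow).sum()),
                               "retained": int(keep.sum())}
    return out


def bin_by_pupil(trials: pd.DataFrame, low_frac: float = 0.4,
                 high_frac: float = 0.4) -> pd.DataFrame:
    """Assign within-subject pupil bins: lowest/highest fractions of
    baseline values go to 'low'/'high', the remainder to 'middle'.

    Bin sizes are floor(frac * n) per subject; ties break by stable sort on
    (baseline, trial order).  Requires >= 5 retained trials per subject.
    """
    if low_frac + high_frac > 1:
        raise ValueError("bin fractions must sum to <= 1")
    t = trials.copy()
    if t["baseline_pupil"].isna().any():
        raise ValueError("baseline_pupil missing on some retained trials")
    labels = pd.Series("middle", index=t.index, dtype=object)
    for _, idx in t.groupby("subject").groups.items():
        sub = t.loc[idx]
        n = len(sub)
        if n < 5:
            raise ValueError(f"subject {sub['subject'].iloc[0]} has only {n} "
                             "retained trials (< 5)")
        order = np.argsort(sub["baseline_pupil"].to_numpy(), kind="stable")
        n_low = int(np.floor(low_frac * n))
        n_high = int(np.floor(high_frac * n))
        lab = np.full(n, "middle", dtype=object)
        lab[order[:n_low]] = "low"
        if n_high:
            lab[order[-n_high:]] = "high"
        labels.loc[sub.index] = lab
    t["pupil_bin"] = labels
    return t
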
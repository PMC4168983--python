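"""Synthetic pupil streams and DDM-coupled behavior.

The generator emulates the statistical structure the analysis pipeline
assumes: 26 subjects x 500 trials of a speeded motion-discrimination task,
RTs and choices from a two-boundary diffusion with z = a/2, baseline pupil
diameter carrying slow task-independent fluctuations, and a linear coupling
from (z-scored) baseline pupil to the between-trial SD of drift rate.  The
response-to-stimulus interval is uniform on 5-6.5 s so that the
decision-locked pupil dilation returns to baseline before the next
baseline-measurement window.

Defaults follow the study's fitted group-level values: v = 0.204,
a = 0.108, t = 0.523 (mean of the two bins), st = 0.077, drift-SD intercept
0.123 with a slope calibrated to a low-to-high-bin eta difference of about
0.04.  Between-subject dispersion of the generating parameters is a fixture
convention (15% of each mean) because population SDs are not part of the
reported group-level estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.stats import gamma as gamma_dist

from . import _wfpt
from .ddm import DDMParams, sample_exact, simulate_trials
from .preprocess import PupilSamples

__all__ = [
    "StudyDesign",
    "CouplingSpec",
    "TABLE1_BIN_MEANS",
    "default_base_params",
    "gen_pupil_timeseries",
    "gen_coupled_behavior",
    "gen_binned_dataset",
    "gen_psychometric_dataset",
    "generate_study",
]

# group-level posterior-mean (EAP) estimates, per pupil bin, used as the
# canonical generating truth for recovery experiments
TABLE1_BIN_MEANS = {
    "low": {"v": 0.204, "a": 0.108, "t": 0.526, "eta": 0.123},
    "high": {"v": 0.201, "a": 0.109, "t": 0.520, "eta": 0.164},
    "st": 0.077,
}


def default_base_params() -> DDMParams:
    """Pooled generating parameter set (bin-averaged group means)."""
    lo, hi = TABLE1_BIN_MEANS["low"], TABLE1_BIN_MEANS["high"]
    return DDMParams(v=(lo["v"] + hi["v"]) / 2, a=(lo["a"] + hi["a"]) / 2,
                     t=(lo["t"] + hi["t"]) / 2, eta=(lo["eta"] + hi["eta"]) / 2,
                     st=TABLE1_BIN_MEANS["st"])


@dataclass(frozen=True)
class StudyDesign:
    n_subjects: int = 26
    n_trials: int = 500
    sampling_rate: float = 250.0
    rsi_range: tuple = (5.0, 6.5)
    baseline_window: float = 1.0
    rt_deadline: float = 1.5
    rt_floor: float = 0.1

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if not self.rsi_range[0] < self.rsi_range[1]:
            raise ValueError("rsi_range must satisfy low < high")
        if not self.rt_floor < self.rt_deadline:
            raise ValueError("rt_floor must be < rt_deadline")


@dataclass(frozen=True)
class CouplingSpec:
    """Pupil process and pupil-to-drift-SD coupling.

    eta0/eta_slope define per-trial drift SD
    eta_j = max(0, eta0 + eta_slope * z(pupil_j)).  The pupil baseline is a
    sum of slow sinusoids (periods spanning 1-5 min) plus AR(1) measurement
    noise; a gamma-shaped decision-locked dilation (peak ~1 s post-response,
    back to baseline within ~5 s) rides on top of it in the sample stream.
    """

    eta0: float = 0.123
    eta_slope: float = 0.021
    pupil_mean_mm: float = 4.5
    slow_amp_mm: float = 0.35
    slow_periods_s: tuple = (60.0, 300.0)
    n_slow_components: int = 3
    noise_sd_mm: float = 0.02
    noise_tau_s: float = 2.0
    evoked_amp_mm: float = 0.4
    evoked_decay_s: float = 5.0
    blink_rate_per_min: float = 4.0
    blink_duration_s: tuple = (0.1, 0.4)
    gaze_sd_deg: float = 0.5
    excursion_rate_per_min: float = 0.2

    def __post_init__(self):
        if self.eta0 < 0:
            raise ValueError("eta0 must be >= 0")
        if self.blink_rate_per_min < 0:
            raise ValueError("blink_rate_per_min must be >= 0")


class _SlowProcess:
    """Sum of slow sinusoids; the tonic-arousal analogue."""

    def __init__(self, coupling: CouplingSpec, rng):
        k = coupling.n_slow_components
        lo, hi = coupling.slow_periods_s
        self.periods = rng.uniform(lo, hi, k)
        amps = rng.uniform(0.5, 1.0, k)
        if amps.sum() > 0:
            amps *= coupling.slow_amp_mm / amps.sum()
        self.amps = amps
        self.phases = rng.uniform(0, 2 * np.pi, k)
        self.mean = coupling.pupil_mean_mm
        # SD of a sinusoid sum with independent phases: sqrt(sum A^2 / 2)
        self.sd = float(np.sqrt(np.sum(amps ** 2) / 2)) or 1.0

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.mean)
        for A, T, ph in zip(self.amps, self.periods, self.phases):
            out = out + A * np.sin(2 * np.pi * t / T + ph)
        return out

    def zscore(self, x):
        return (np.asarray(x) - self.mean) / self.sd


def _simulate_subject_behavior(design, coupling, base: DDMParams, slow, rng,
                               dt=0.001):
    """Sequential per-trial simulation with onset times coupled to RTs."""
    n = design.n_trials
    onsets = np.empty(n)
    rts = np.empty(n)
    choices = np.empty(n, dtype=int)
    etas = np.empty(n)
    vs = np.empty(n)
    base_true = np.empty(n)
    _wfpt.set_seed(int(rng.integers(2 ** 31)))
    t_clock = 10.0 + rng.uniform(*design.rsi_range)
    n_resampled = 0
    for j in range(n):
        onsets[j] = t_clock
        # slow-process value at the midpoint of the baseline window
        b = float(slow(t_clock - design.baseline_window / 2))
        base_true[j] = b
        eta_j = max(0.0, coupling.eta0 + coupling.eta_slope * slow.zscore(b))
        etas[j] = eta_j
        for _ in range(200):
            u = rng.normal(base.v, eta_j)
            tnd = base.t + base.st * (rng.random() - 0.5)
            dtime, c = _wfpt._euler_single(u, base.a, base.z, base.s, dt,
                                           design.rt_deadline + 1.0)
            rt = dtime + tnd
            if c >= 0 and rt <= design.rt_deadline:
                break
            n_resampled += 1
        else:
            raise RuntimeError(f"trial {j}: could not draw an RT under the "
                               "deadline; generator misconfigured")
        vs[j] = u
        rts[j] = rt
        choices[j] = c
        t_clock += rt + rng.uniform(*design.rsi_range)
    if n_resampled > 0.2 * n:
        raise ValueError(f"{n_resampled} deadline misses resampled for "
                         f"{n} trials (> 20%); generator misconfigured")
    return onsets, rts, choices, vs, etas, base_true, n_resampled


def _build_stream(design, coupling, slow, onsets, rts, rng):
    fs = design.sampling_rate
    dur = onsets[-1] + rts[-1] + 3.0
    n = int(np.ceil(dur * fs))
    t = np.arange(n) / fs
    pupil = slow(t)
    # AR(1) measurement noise with time constant noise_tau_s
    if coupling.noise_sd_mm > 0:
        rho = np.exp(-1.0 / (fs * coupling.noise_tau_s))
        innov = rng.normal(0, coupling.noise_sd_mm * np.sqrt(1 - rho ** 2), n)
        pupil = pupil + lfilter([1.0], [1.0, -rho], innov)
    # decision-locked dilation: gamma kernel (shape 3, scale decay/10),
    # peak ~1 s after the response, ~0 by evoked_decay_s
    if coupling.evoked_amp_mm > 0:
        scale = coupling.evoked_decay_s / 10.0
        kt = np.arange(0, coupling.evoked_decay_s, 1 / fs)
        kern = gamma_dist.pdf(kt, a=3, scale=scale)
        kern = coupling.evoked_amp_mm * kern / kern.max()
        for onset, rt in zip(onsets, rts):
            i0 = int(round((onset + rt) * fs))
            i1 = min(i0 + len(kern), n)
            if i0 < n:
                pupil[i0:i1] += kern[: i1 - i0]
    # gaze jitter around fixation with occasional large excursions
    rho_g = np.exp(-1.0 / (fs * 0.2))
    gx = lfilter([1.0], [1.0, -rho_g],
                 rng.normal(0, coupling.gaze_sd_deg * np.sqrt(1 - rho_g ** 2), n))
    gy = lfilter([1.0], [1.0, -rho_g],
                 rng.normal(0, coupling.gaze_sd_deg * np.sqrt(1 - rho_g ** 2), n))
    n_exc = rng.poisson(coupling.excursion_rate_per_min * dur / 60)
    for _ in range(n_exc):
        i0 = rng.integers(0, n)
        length = int(rng.uniform(0.3, 1.0) * fs)
        ang = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(5.5, 8.0)
        gx[i0:i0 + length] += amp * np.cos(ang)
        gy[i0:i0 + length] += amp * np.sin(ang)
    # blinks: Poisson events, dropout (invalid samples)
    valid = np.ones(n, dtype=bool)
    n_blinks = rng.poisson(coupling.blink_rate_per_min * dur / 60)
    for _ in range(n_blinks):
        i0 = rng.integers(0, n)
        length = max(1, int(rng.uniform(*coupling.blink_duration_s) * fs))
        valid[i0:i0 + length] = False
    clean = pupil.copy()
    pupil[~valid] = 0.0
    samples = PupilSamples(time=t, diameter=pupil, gaze_x=gx, gaze_y=gy,
                           valid=valid, units="mm")
    return samples, clean


def gen_pupil_timeseries(design: StudyDesign, coupling: CouplingSpec,
                         seed: int, rts=None, strict_baseline_return=False):
    """Generate a continuous pupil sample stream plus trial onset times.

    If per-trial response times ``rts`` are not supplied, placeholder RTs
    are drawn from a lognormal near the study's mean RT.  Returns
    (PupilSamples, onsets, rts, true_baselines) where ``true_baselines``
    are the clean-stream means over the baseline window of each trial.
    """
    if design.sampling_rate <= 0:
        raise ValueError("sampling_rate must be > 0")
    if strict_baseline_return and design.rsi_range[1] < coupling.evoked_decay_s:
        raise ValueError(
            f"rsi upper bound {design.rsi_range[1]} s is shorter than the "
            f"evoked-response decay {coupling.evoked_decay_s} s; the baseline "
            "window would be contaminated by the preceding dilation")
    rng = np.random.default_rng(seed)
    slow = _SlowProcess(coupling, rng)
    n = design.n_trials
    if rts is None:
        rts = np.clip(rng.lognormal(np.log(0.72), 0.18, n), design.rt_floor,
                      design.rt_deadline)
    rts = np.asarray(rts, dtype=float)
    rsis = rng.uniform(*design.rsi_range, n)
    onsets = np.empty(n)
    t_clock = 10.0 + rsis[0]
    for j in range(n):
        onsets[j] = t_clock
        t_clock += rts[j] + rng.uniform(*design.rsi_range)
    samples, clean = _build_stream(design, coupling, slow, onsets, rts, rng)
    base_true = _window_means(clean, design, onsets)
    return samples, onsets, rts, base_true


def _window_means(clean, design, onsets):
    fs = design.sampling_rate
    w = design.baseline_window
    out = np.empty(len(onsets))
    for j, onset in enumerate(onsets):
        i1 = int(round(onset * fs))
        i0 = int(round((onset - w) * fs))
        out[j] = clean[i0:i1].mean()
    return out


def gen_coupled_behavior(design: StudyDesign, coupling: CouplingSpec,
                         base_params: DDMParams, seed: int,
                         baselines=None) -> pd.DataFrame:
    """Trial table with drift-SD coupled to baseline pupil.

    For trial j, eta_j = max(0, eta0 + eta_slope * z(pupil_j)); the
    single-trial drift is Normal(v, eta_j) and RT/choice come from the
    two-boundary process.  Deadline misses are resampled (counts in
    ``df.attrs['n_deadline_resampled']``) so trial counts match the design.
    If per-trial ``baselines`` (dict subject -> array, z-scored or raw) are
    supplied they replace the internal slow-process draw.
    """
    if coupling.eta0 < 0:
        raise ValueError("eta0 must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    n_resampled_total = 0
    for p in range(design.n_subjects):
        srng = np.random.default_rng(rng.integers(2 ** 31))
        slow = _SlowProcess(coupling, srng)
        if baselines is not None:
            raw = np.asarray(baselines[p], dtype=float)
            zb = (raw - raw.mean()) / raw.std()
            etas = np.maximum(0.0, coupling.eta0 + coupling.eta_slope * zb)
            _wfpt.set_seed(int(srng.integers(2 ** 31)))
            us = srng.normal(base_params.v, etas)
            rts = np.empty(design.n_trials)
            chs = np.empty(design.n_trials, dtype=int)
            n_res = 0
            for j in range(design.n_trials):
                for _ in range(200):
                    tnd = base_params.t + base_params.st * (srng.random() - 0.5)
                    dtime, ch = _wfpt._euler_single(
                        us[j], base_params.a, base_params.z, base_params.s,
                        0.001, design.rt_deadline + 1.0)
                    if ch >= 0 and dtime + tnd <= design.rt_deadline:
                        break
                    n_res += 1
                    us[j] = srng.normal(base_params.v, etas[j])
                rts[j] = dtime + tnd
                chs[j] = ch
            onsets = 10.0 + np.cumsum(rts + srng.uniform(*design.rsi_range,
                                                         design.n_trials))
            b_true = raw
        else:
            onsets, rts, chs, us, etas, b_true, n_res = \
                _simulate_subject_behavior(design, coupling, base_params,
                                           slow, srng)
        n_resampled_total += n_res
        rows.append(pd.DataFrame({
            "subject": p, "trial": np.arange(design.n_trials),
            "onset_s": onsets, "rt": rts, "accuracy": (chs == 1).astype(int),
            "choice": np.where(chs == 1, "R", "L"),
            "baseline_pupil": b_true, "generating_v": us,
            "generating_eta": etas}))
    df = pd.concat(rows, ignore_index=True)
    df.attrs["n_deadline_resampled"] = n_resampled_total
    return df


def gen_binned_dataset(bin_means: dict | None = None, sd_frac: float = 0.15,
                       n_subjects: int = 26, n_trials_per_bin: int = 196,
                       seed: int = 0, antithetic: bool = True) -> pd.DataFrame:
    """Binned trial table generated directly from per-bin group means.

    The canonical recovery fixture: subject-level parameters are
    Normal(group mean, sd_frac * group mean) with a shared per-subject
    deviate across bins, z = a/2, s = 0.1.  With ``antithetic`` (default)
    subject deviates come in mirrored pairs, so each subject's parameters
    are still Normal-dispersed at sd_frac but the realized group mean
    equals the nominal one exactly — recovery error then measures the
    estimator, not the luck of the 26-subject draw.  Trials are drawn by
    exact inverse-CDF sampling (no Euler discretization error).
    Ground-truth parameters are attached in ``df.attrs['true_params']``.
    """
    bm = TABLE1_BIN_MEANS if bin_means is None else bin_means
    rng = np.random.default_rng(seed)

    def draw_devs():
        if antithetic and n_subjects % 2 == 0:
            half = rng.standard_normal(n_subjects // 2)
            z = np.concatenate([half, -half])
        else:
            z = rng.standard_normal(n_subjects)
        return z

    devs = {p: draw_devs() for p in ("v", "a", "t", "eta")}
    dev_st = draw_devs()
    mu_st = bm["st"]
    rows = []
    true = {"bin_means": bm, "subject": {}}
    for p_i in range(n_subjects):
        st_p = max(1e-3, mu_st * (1 + sd_frac * dev_st[p_i]))
        for bname in ("low", "high"):
            m = bm[bname]
            par = {k: m[k] * (1 + sd_frac * devs[k][p_i]) for k in m}
            par["eta"] = max(0.0, par["eta"])
            par["a"] = max(1e-3, par["a"])
            par["t"] = max(st_p / 2, par["t"])
            dp = DDMParams(v=par["v"], a=par["a"], t=par["t"],
                           eta=par["eta"], st=st_p)
            true["subject"][(bname, p_i)] = dp
            rt, ch = sample_exact(dp, n_trials_per_bin,
                                  seed=int(rng.integers(2 ** 31)))
            rows.append(pd.DataFrame({
                "subject": p_i, "pupil_bin": bname, "rt": rt,
                "accuracy": ch.astype(int)}))
    df = pd.concat(rows, ignore_index=True)
    df.attrs["true_params"] = true
    return df


def gen_psychometric_dataset(coherences, n_per: int, k: float, a: float,
                             t_r: float, seed: int, dt: float = 0.001) -> pd.DataFrame:
    """Accuracy and mean RT per coherence under the proportional-rate model.

    Drift is k * C (C in percent coherence), symmetric bounds at distance
    ``a`` from the start, unit within-trial noise; the observed accuracy and
    mean RT per level are what the calibration step consumes.
    """
    coherences = np.asarray(coherences, dtype=float)
    if np.any((coherences < 0) | (coherences > 100)):
        raise ValueError("coherences must be in [0, 100]")
    if n_per < 1:
        raise ValueError("n_per must be >= 1")
    if k < 0 or a <= 0:
        raise ValueError("need k >= 0 and a > 0")
    rng = np.random.default_rng(seed)
    recs = []
    for C in coherences:
        p = DDMParams(v=k * C, a=2 * a, t=t_r, z=a, s=1.0)
        rt, ch = simulate_trials(p, n_per, seed=int(rng.integers(2 ** 31)),
                                 dt=dt, t_max=30.0)
        keep = ch >= 0
        rt = rt[keep]
        correct = ch[keep] == 1
        if C == 0:  # no signal: either bound counts as a coin flip
            correct = rng.random(len(rt)) < 0.5
        recs.append({"coherence": C, "n": len(rt),
                     "accuracy": float(np.mean(correct)),
                     "mean_rt": float(np.mean(rt)),
                     "sem_rt": float(np.std(rt, ddof=1) / np.sqrt(len(rt)))})
    return pd.DataFrame.from_records(recs)


def generate_study(design: StudyDesign, coupling: CouplingSpec,
                   base_params: DDMParams | None = None, seed: int = 0):
    """Full self-consistent study: streams plus coupled behavior.

    Per subject, trial onsets follow the simulated RTs plus uniform RSIs,
    drift SD follows the slow pupil process, and the returned clean-stream
    window means are recorded as the ground-truth baselines.  Returns
    (streams, onsets_by_subject, trial_table); streams is a dict
    subject -> PupilSamples.
    """
    if base_params is None:
        base_params = default_base_params().with_(eta=0.0)
    rng = np.random.default_rng(seed)
    streams = {}
    onsets_by_subj = {}
    rows = []
    for p in range(design.n_subjects):
        srng = np.random.default_rng(rng.integers(2 ** 31))
        slow = _SlowProcess(coupling, srng)
        onsets, rts, chs, us, etas, _, n_res = _simulate_subject_behavior(
            design, coupling, base_params, slow, srng)
        samples, clean = _build_stream(design, coupling, slow, onsets, rts, srng)
        base_rec = _window_means(clean, design, onsets)
        streams[p] = samples
        onsets_by_subj[p] = onsets
        rows.append(pd.DataFrame({
            "subject": p, "trial": np.arange(design.n_trials),
            "onset_s": onsets, "rt": rts, "accuracy": (chs == 1).astype(int),
            "choice": np.where(chs == 1, "R", "L"),
            "baseline_pupil": base_rec, "generating_v": us,
            "generating_eta": etas}))
    table = pd.concat(rows, ignore_index=True)
    return streams, onsets_by_subj, table
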
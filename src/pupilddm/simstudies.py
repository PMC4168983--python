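"""Simulation experiments on how accumulation-rate variability shapes
observable behavior.

Three experiments: (i) a two-choice grid varying the drift-SD eta
independently in two conditions and comparing correct- and error-trial RT
variability per (eta1, eta2) pixel; (ii) the same design under a one-choice
(single boundary, high-drift) model, where increased eta robustly increases
RT variability; and (iii) an eta-vs-s grid comparing each (eta, s) pixel to
a fixed reference condition on accuracy and the error-minus-correct RT gap,
dissociating between- from within-trial variability in accumulation rate.

Each pixel is compared across simulated subjects with an uncorrected paired
t-test.  Conditions share random numbers within a subject (the same seed
drives every grid value), so identity pixels differ by exactly zero and the
paired comparisons are sharpened without biasing means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import _wfpt
from .ddm import DDMParams, draw_subject_params

__all__ = [
    "GridResult",
    "RATCLIFF_ONE_CHOICE",
    "eta_grid_two_choice",
    "eta_grid_one_choice",
    "eta_s_dissociation",
]

# one-choice group parameters (mean, SD) from a fitted easy-detection task
RATCLIFF_ONE_CHOICE = {
    "means": {"v": 0.777, "a": 0.136, "t": 0.253, "st": 0.136},
    "sds": {"v": 0.191, "a": 0.017, "t": 0.034, "st": 0.037},
}


@dataclass
class GridResult:
    axis1: np.ndarray           # condition-1 parameter values (rows)
    axis2: np.ndarray           # condition-2 parameter values (columns)
    mean_diff: np.ndarray       # across-subject mean condition difference
    p_value: np.ndarray         # per-pixel paired t-test (uncorrected)
    alpha: float = 0.05

    @property
    def sig_mask(self):
        return self.p_value < self.alpha


def _pairwise_grids(per_subject_stat):
    """Turn a (subjects, n_values) statistic into pairwise-difference grids.

    diff[i, j] = mean over subjects of stat[:, i] - stat[:, j]; the paired
    t-test runs across subjects per pixel (NaN subjects drop pairwise).
    """
    S = np.asarray(per_subject_stat, dtype=float)
    d = S[:, :, None] - S[:, None, :]          # (subjects, i, j)
    mean_diff = np.nanmean(d, axis=0)
    nn = np.sum(np.isfinite(d), axis=0)
    sd = np.nanstd(d, axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_diff / (sd / np.sqrt(nn))
    p = 2 * stats.t.sf(np.abs(t), np.maximum(nn - 1, 1))
    p[~np.isfinite(t)] = 1.0                    # identity pixels: zero variance
    return mean_diff, p


def default_two_choice_subjects(seed: int = 0, n_subjects: int = 26,
                                sd_frac: float = 0.15):
    """Mock subjects from the fitted low-bin group-level distributions."""
    means = {"v": 0.204, "a": 0.108, "t": 0.526, "st": 0.077}
    sds = {k: sd_frac * v for k, v in means.items()}
    return draw_subject_params(means, sds, n_subjects, seed)


def eta_grid_two_choice(subjects=None, eta_values=None, n_trials: int = 5000,
                        seed: int = 0, dt: float = 0.001):
    """RT-variability differences over a 2-D grid of eta pairs (two-choice).

    Returns {"correct": GridResult, "error": GridResult}.  Each subject is
    simulated once per eta value and grid pixels are pairwise differences
    of the per-subject RT SDs, so the diagonal is exactly zero.
    """
    if subjects is None:
        subjects = default_two_choice_subjects(seed)
    if eta_values is None:
        eta_values = np.linspace(0.05, 0.2, 31)
    eta_values = np.asarray(eta_values, dtype=float)
    if n_trials < 100:
        import warnings
        warnings.warn("n_trials < 100 gives noisy grid pixels")
    rng = np.random.default_rng(seed)
    subj_seeds = rng.integers(2 ** 31, size=len(subjects))
    sd_cor = np.empty((len(subjects), len(eta_values)))
    sd_err = np.empty_like(sd_cor)
    for pi, p in enumerate(subjects):
        for ki, eta in enumerate(eta_values):
            rt, ch = _wfpt.simulate_paths(
                n_trials, p.v, p.a, p.z, p.t, eta, p.st, p.s, dt, 10.0,
                int(subj_seeds[pi]))  # common random numbers across eta
            cor = rt[ch == 1]
            err = rt[ch == 0]
            sd_cor[pi, ki] = cor.std(ddof=1) if len(cor) > 1 else np.nan
            sd_err[pi, ki] = err.std(ddof=1) if len(err) > 1 else np.nan
    out = {}
    for name, S in (("correct", sd_cor), ("error", sd_err)):
        md, pv = _pairwise_grids(S)
        out[name] = GridResult(eta_values, eta_values, md, pv)
    return out


def eta_grid_one_choice(eta_values=None, group_params=None,
                        n_subjects: int = 26, n_trials: int = 5000,
                        seed: int = 0, t_max: float = 30.0) -> GridResult:
    """RT-variability differences over eta pairs for the one-choice model.

    Subjects are drawn from the easy-detection group parameters; per-trial
    drifts that never reach the boundary (or exceed t_max) are censored and
    excluded from the SDs.
    """
    if eta_values is None:
        eta_values = np.linspace(0.1, 0.4, 31)
    eta_values = np.asarray(eta_values, dtype=float)
    gp = RATCLIFF_ONE_CHOICE if group_params is None else group_params
    subjects = draw_subject_params(gp["means"], gp["sds"], n_subjects, seed)
    rng = np.random.default_rng(seed + 1)
    subj_seeds = rng.integers(2 ** 31, size=len(subjects))
    sd = np.empty((len(subjects), len(eta_values)))
    for pi, p in enumerate(subjects):
        cnt, _, sds = _wfpt.one_choice_sd_over_etas(
            n_trials, p.v, p.a, p.t, p.st, p.s, eta_values, t_max,
            int(subj_seeds[pi]))
        sd[pi] = np.where(cnt > 1, sds, np.nan)
    md, pv = _pairwise_grids(sd)
    return GridResult(eta_values, eta_values, md, pv)


def eta_s_dissociation(subjects=None, eta_ref: float = 0.125,
                       s_ref: float = 0.1, eta_values=None, s_values=None,
                       n_trials: int = 5000, seed: int = 0, dt: float = 0.001):
    """Accuracy and error-correct RT-gap differences of (eta, s) pixels
    versus a fixed reference condition.

    Returns {"accuracy": GridResult-like, "err_minus_corr_rt": ...} with
    axis1 = eta values (rows) and axis2 = s values (columns); each entry is
    the varying-condition minus reference mean across subjects.
    """
    if subjects is None:
        subjects = default_two_choice_subjects(seed)
    if eta_values is None:
        eta_values = np.round(np.arange(0.06, 0.19 + 1e-9, 0.005), 4)
    if s_values is None:
        s_values = np.round(np.arange(0.07, 0.13 + 1e-9, 0.005), 4)
    eta_values = np.asarray(eta_values, dtype=float)
    s_values = np.asarray(s_values, dtype=float)
    rng = np.random.default_rng(seed)
    subj_seeds = rng.integers(2 ** 31, size=len(subjects))
    P = len(subjects)
    ne, ns = len(eta_values), len(s_values)
    acc = np.empty((P, ne, ns))
    gap = np.empty((P, ne, ns))
    acc_ref = np.empty(P)
    gap_ref = np.empty(P)

    def run(p, eta, s_val, sd):
        rt, ch = _wfpt.simulate_paths(n_trials, p.v, p.a, p.z, p.t, eta,
                                      p.st, s_val, dt, 10.0, sd)
        ok = ch >= 0
        rt, ch = rt[ok], ch[ok]
        a = (ch == 1).mean()
        cor, err = rt[ch == 1], rt[ch == 0]
        g = (err.mean() - cor.mean()) if len(err) and len(cor) else np.nan
        return a, g

    for pi, p in enumerate(subjects):
        sd0 = int(subj_seeds[pi])
        acc_ref[pi], gap_ref[pi] = run(p, eta_ref, s_ref, sd0)
        for ei, eta in enumerate(eta_values):
            for si, s_val in enumerate(s_values):
                acc[pi, ei, si], gap[pi, ei, si] = run(p, eta, s_val, sd0)

    out = {}
    for name, M, ref in (("accuracy", acc, acc_ref),
                         ("err_minus_corr_rt", gap, gap_ref)):
        d = M - ref[:, None, None]
        md = np.nanmean(d, axis=0)
        nn = np.sum(np.isfinite(d), axis=0)
        sdv = np.nanstd(d, axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = md / (sdv / np.sqrt(nn))
        pv = 2 * stats.t.sf(np.abs(t), np.maximum(nn - 1, 1))
        pv[~np.isfinite(t)] = 1.0
        out[name] = GridResult(eta_values, s_values, md, pv)
    return out
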
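"""Proportional-rate diffusion calibration of stimulus difficulty.

A reduced diffusion model in which drift rate is proportional to motion
coherence: with sensitivity k, bound +/-a around the start and unit
within-trial noise,

    P(correct | C)  = 1 / (1 + exp(-2 a k C))
    E[RT | C]       = (a / (k C)) * tanh(a k C) + t_r      (C -> 0: a^2 + t_r)

Fitting maximizes the binomial likelihood of per-level accuracies jointly
with a Gaussian likelihood of per-level mean RTs (weighted by their
standard errors).  Inverting the fitted psychometric function at a target
accuracy (0.85 by convention here) yields the coherence used for the main
task, matching difficulty across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ProportionalRateParams",
    "psychometric",
    "chronometric",
    "fit_proportional_rate",
    "interpolate_target_coherence",
]


@dataclass(frozen=True)
class ProportionalRateParams:
    k: float      # drift per unit coherence (%^-1, unit-noise scale)
    a: float      # bound distance from the neutral start
    t_r: float    # residual (non-decision) time, s

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.a <= 0:
            raise ValueError("a must be > 0")
        if self.t_r < 0:
            raise ValueError("t_r must be >= 0")


def psychometric(C, k, a):
    """P(correct) at coherence C (percent)."""
    return 1.0 / (1.0 + np.exp(-2.0 * a * k * np.asarray(C, dtype=float)))


def chronometric(C, k, a, t_r):
    """Mean RT at coherence C, with the analytic driftless limit a^2."""
    C = np.asarray(C, dtype=float)
    x = a * k * C
    with np.errstate(divide="ignore", invalid="ignore"):
        dt = np.where(x < 1e-8, a * a, (a / np.maximum(k * C, 1e-300)) * np.tanh(x))
    return dt + t_r


def fit_proportional_rate(table: pd.DataFrame) -> ProportionalRateParams:
    """Maximum-likelihood fit to per-coherence accuracy and mean RT.

    ``table`` needs columns coherence, n, accuracy, mean_rt and sem_rt
    (standard error of the mean RT; rows with sem_rt = 0 fall back to an
    unweighted Gaussian term).  At least 3 coherence levels are required.
    """
    req = {"coherence", "n", "accuracy", "mean_rt"}
    missing = req - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if len(table) < 3:
        raise ValueError("need >= 3 coherence levels")
    C = table["coherence"].to_numpy(float)
    n = table["n"].to_numpy(float)
    k_obs = np.round(table["accuracy"].to_numpy(float) * n)
    mrt = table["mean_rt"].to_numpy(float)
    sem = table["sem_rt"].to_numpy(float) if "sem_rt" in table else np.full(len(C), 0.01)
    sem = np.where(sem > 0, sem, np.nanmax([sem.max(), 0.01]))

    def negll(theta):
        lk, la, tr = theta
        k, a = np.exp(lk), np.exp(la)
        p = np.clip(psychometric(C, k, a), 1e-9, 1 - 1e-9)
        ll_acc = np.sum(k_obs * np.log(p) + (n - k_obs) * np.log1p(-p))
        pred = chronometric(C, k, a, tr)
        ll_rt = -0.5 * np.sum(((mrt - pred) / sem) ** 2)
        return -(ll_acc + ll_rt)

    best = None
    for k0, a0 in [(0.03, 1.0), (0.01, 0.7), (0.1, 1.5), (0.05, 0.5)]:
        x0 = np.array([np.log(k0), np.log(a0), max(min(mrt) * 0.5, 0.05)])
        res = optimize.minimize(negll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-8,
                                         "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("proportional-rate fit failed to converge; "
                           "check that accuracy rises with coherence")
    lk, la, tr = best.x
    return ProportionalRateParams(k=float(np.exp(lk)), a=float(np.exp(la)),
                                  t_r=float(max(tr, 0.0)))


def interpolate_target_coherence(params: ProportionalRateParams,
                                 target_accuracy: float = 0.85) -> float:
    """Invert the fitted psychometric function at the target accuracy.

    C* = logit(target) / (2 a k); target must lie in (0.5, 1) except for
    the degenerate chance level, which maps to C* = 0.
    """
    if not 0.5 <= target_accuracy < 1:
        raise ValueError("target accuracy must be in [0.5, 1)")
    if target_accuracy == 0.5:
        return 0.0
    if params.k == 0:
        raise ValueError("flat psychometric function (k = 0): no coherence "
                         "attains the target accuracy")
    logit = np.log(target_accuracy / (1 - target_accuracy))
    return float(logit / (2.0 * params.a * params.k))
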
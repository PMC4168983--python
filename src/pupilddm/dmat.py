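"""Non-hierarchical per-subject DDM fitting from RT quantiles.

The classic quantile-likelihood recipe: summarize each (pupil bin x
accuracy) cell by its RT quantiles at probabilities (.1, .3, .5, .7, .9),
convert a candidate parameter set into predicted probability masses of the
inter-quantile bins via the defective CDFs, and minimize the multinomial
negative log-likelihood by Nelder-Mead simplex from several jittered
starts.  a, t, v and eta are free per pupil bin; st is shared; z = a/2.

Error cells with fewer than 5 trials collapse to a median-only summary
(two bins), the standard fallback when errors are scarce.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .ddm import DDMParams, choice_probability, fpt_density

__all__ = [
    "QuantileData",
    "rt_quantiles",
    "quantile_data_from_trials",
    "defective_interval_masses",
    "quantile_negloglik",
    "fit_subject",
]

PROBS = (0.1, 0.3, 0.5, 0.7, 0.9)
_MASS_FLOOR = 1e-10
# Gauss-Legendre rule used to integrate the defective density over each
# inter-quantile interval
_QX, _QW = np.polynomial.legendre.leggauss(8)


def rt_quantiles(rts, probs=PROBS):
    """Linear-interpolation sample quantiles (Hyndman-Fan type 7).

    Fewer than 5 observations collapse to the median only, with a warning.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size == 0:
        raise ValueError("empty RT list")
    if rts.size < 5:
        warnings.warn(f"only {rts.size} observations; collapsing to median")
        probs = (0.5,)
    return np.quantile(rts, probs)


@dataclass
class QuantileData:
    """Per (bin, correctness): quantiles, trial count; plus bin accuracy."""

    quantiles: dict      # (bin, bool correct) -> quantile vector
    counts: dict         # (bin, bool correct) -> trial count
    bins: tuple = ("low", "high")

    def accuracy(self, bname):
        nc = self.counts.get((bname, True), 0)
        ne = self.counts.get((bname, False), 0)
        return nc / max(nc + ne, 1)


def quantile_data_from_trials(trials: pd.DataFrame,
                              min_error_trials: int = 5) -> QuantileData:
    """Summarize one subject's binned trials into quantile form."""
    q, n = {}, {}
    for bname in ("low", "high"):
        sub = trials[trials["pupil_bin"] == bname]
        for correct in (True, False):
            cell = sub[(sub["accuracy"] > 0.5) == correct]["rt"].to_numpy()
            n[(bname, correct)] = len(cell)
            if len(cell) == 0:
                q[(bname, correct)] = None
            elif not correct and len(cell) < min_error_trials:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    q[(bname, correct)] = rt_quantiles(cell, (0.5,))
            else:
                q[(bname, correct)] = rt_quantiles(cell)
    return QuantileData(q, n)


def defective_interval_masses(p: DDMParams, edges, bound: str):
    """Probability masses of (-inf, e1], (e1, e2], ..., (em, inf) at one
    boundary, via fixed-order quadrature of the defective density."""
    edges = np.asarray(edges, dtype=float)
    lo = p.t - p.st / 2
    pts = np.concatenate([[lo], edges])
    nodes = []
    for i in range(len(pts) - 1):
        a0, b0 = pts[i], max(pts[i + 1], pts[i])
        nodes.append(0.5 * (b0 - a0) * _QX + 0.5 * (a0 + b0))
    nodes = np.concatenate(nodes)
    dens = fpt_density(nodes, bound, p)
    masses = np.empty(len(edges) + 1)
    for i in range(len(pts) - 1):
        h = 0.5 * (max(pts[i + 1], pts[i]) - pts[i])
        masses[i] = h * np.sum(_QW * dens[8 * i: 8 * (i + 1)])
    total = choice_probability(p) if bound == "upper" else 1 - choice_probability(p)
    masses[-1] = max(total - masses[:-1].sum(), 0.0)
    return np.maximum(masses, 0.0)


def _cell_negll(p, quants, count, correct):
    if count == 0 or quants is None:
        return 0.0
    bound = "upper" if correct else "lower"
    masses = defective_interval_masses(p, quants, bound)
    if len(quants) == len(PROBS):
        props = np.diff([0.0, *PROBS, 1.0])
    else:  # median-only summary
        props = np.array([0.5, 0.5])
    counts = count * props
    return -np.sum(counts * np.log(np.maximum(masses, _MASS_FLOOR)))


def quantile_negloglik(params_by_bin: dict, q: QuantileData) -> float:
    """Multinomial negative log-likelihood of the quantile summaries.

    ``params_by_bin`` maps bin name to a DDMParams (z = a/2 enforced by the
    caller).  Depends on the data only through quantiles and counts, so it
    is invariant to trial order.
    """
    total = 0.0
    for bname, p in params_by_bin.items():
        for correct in (True, False):
            total += _cell_negll(p, q.quantiles.get((bname, correct)),
                                 q.counts.get((bname, correct), 0), correct)
    return float(total)


def _unpack(x, bins, s):
    out = {}
    st = min(abs(x[8]), 2 * min(x[4], x[5]) - 1e-4) if min(x[4], x[5]) > 0 else 0.0
    st = max(st, 0.0)
    for i, bname in enumerate(bins):
        a = np.exp(x[2 + i])
        t = x[4 + i]
        if t <= st / 2:
            return None
        out[bname] = DDMParams(v=x[0 + i], a=a, t=t, eta=abs(x[6 + i]),
                               st=st, s=s)
    return out


def fit_subject(q: QuantileData, s: float = 0.1, n_starts: int = 5,
                seed: int = 0, x0=None):
    """Fit per-bin (v, a, t, eta) plus shared st by simplex minimization.

    Runs ``n_starts`` Nelder-Mead searches with 10% multiplicative jitter
    around the start and keeps the best.  Returns (params_by_bin, negll,
    report).
    """
    for bname in q.bins:
        if q.counts.get((bname, True), 0) + q.counts.get((bname, False), 0) == 0:
            raise ValueError(f"bin {bname!r} has no trials")
    rng = np.random.default_rng(seed)
    if x0 is None:
        med = np.nanmedian([qq[len(qq) // 2] for qq in q.quantiles.values()
                            if qq is not None])
        x0 = np.array([0.2, 0.2, np.log(0.11), np.log(0.11),
                       max(med - 0.2, 0.1), max(med - 0.2, 0.1), 0.1, 0.1,
                       0.05])

    def obj(x):
        pb = _unpack(x, q.bins, s)
        if pb is None:
            return 1e8
        try:
            return quantile_negloglik(pb, q)
        except (ValueError, FloatingPointError):
            return 1e8

    best = None
    n_fail = 0
    for i in range(n_starts):
        xs = x0 * (1 + 0.1 * rng.standard_normal(len(x0))) if i else x0.copy()
        res = optimize.minimize(obj, xs, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-6,
                                         "maxiter": 3000})
        if not np.isfinite(res.fun) or res.fun >= 1e8:
            n_fail += 1
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(f"all {n_starts} simplex starts failed")
    report = {"negll": float(best.fun), "n_failed_starts": n_fail,
              "converged": bool(best.success)}
    return _unpack(best.x, q.bins, s), float(best.fun), report
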
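"""Two-boundary drift-diffusion and one-choice diffusion numerics.

The two-boundary model: noisy evidence accumulates from a starting point
``z`` between absorbing boundaries at 0 and ``a`` with mean drift ``v`` and
within-trial Gaussian noise of SD ``s`` (conventionally fixed at 0.1).
Between-trial variability enters through a Normal(v, eta^2) drift
distribution and a Uniform(t - st/2, t + st/2) non-decision time.  The
defective first-passage-time densities at each boundary are the trial
likelihood of every model fit in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _wfpt

__all__ = [
    "DDMParams",
    "fpt_density",
    "choice_probability",
    "mean_decision_time",
    "simulate_trials",
    "simulate_one_choice",
    "draw_subject_params",
]

# Gauss-Legendre nodes/weights on [-1, 1] for the uniform st integral
_GL_ORDER = 11
_GL_X, _GL_W = np.polynomial.legendre.leggauss(_GL_ORDER)
# Gauss-Hermite rule for marginalizing choice probability over the drift
# distribution (probabilist transform applied at call time)
_GH_ORDER = 15
_GH_X, _GH_W = np.polynomial.hermite.hermgauss(_GH_ORDER)

LIKELIHOOD_FLOOR = 1e-10


@dataclass(frozen=True)
class DDMParams:
    """One parameter set of the diffusion process.

    v : mean drift rate (evidence/s)
    a : boundary separation (evidence units)
    t : mean non-decision time (s)
    z : starting point (evidence units); None means a/2
    eta : between-trial SD of drift rate
    st : range of uniform between-trial non-decision-time variability (s)
    s : within-trial noise SD (evidence/sqrt(s)), fixed scaling constant
    """

    v: float
    a: float
    t: float
    z: float | None = None
    eta: float = 0.0
    st: float = 0.0
    s: float = 0.1

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError(f"boundary separation a must be > 0, got {self.a}")
        z = self.a / 2 if self.z is None else self.z
        if not 0 < z < self.a:
            raise ValueError(f"starting point z must lie in (0, a), got {z}")
        if self.eta < 0:
            raise ValueError(f"eta must be >= 0, got {self.eta}")
        if self.st < 0:
            raise ValueError(f"st must be >= 0, got {self.st}")
        if self.t < self.st / 2:
            raise ValueError(f"need t >= st/2 (t={self.t}, st={self.st})")
        if self.s <= 0:
            raise ValueError(f"s must be > 0, got {self.s}")
        object.__setattr__(self, "z", z)

    def with_(self, **kw) -> "DDMParams":
        return replace(self, **kw)


def fpt_density(rt, bound: str, p: DDMParams):
    """Defective first-passage density at one boundary.

    ``bound`` is "upper" or "lower".  Scalar or array ``rt``; values at or
    below t - st/2 return 0.  The density over both bounds integrates to 1.
    """
    if bound not in ("upper", "lower"):
        raise ValueError(f"bound must be 'upper' or 'lower', got {bound!r}")
    up = bound == "upper"
    rt_arr = np.atleast_1d(np.asarray(rt, dtype=float))
    out = np.empty_like(rt_arr)
    upper = np.full(rt_arr.shape, up)
    _wfpt.wfpt_pdf_arr(rt_arr, upper, p.v, p.a, p.t, p.z, p.eta, p.st, p.s,
                       _GL_X, _GL_W, out)
    return out if np.ndim(rt) else float(out[0])


def _p_upper_fixed_drift(v, a, z, s):
    """Closed-form upper-boundary absorption probability at fixed drift."""
    x = 2.0 * v / (s * s)
    if abs(x * a) < 1e-9:
        return z / a
    # stable evaluation of (1 - e^{-xz}) / (1 - e^{-xa})
    num = -np.expm1(-x * z)
    den = -np.expm1(-x * a)
    return num / den


def choice_probability(p: DDMParams) -> float:
    """Probability of upper-boundary absorption, drift variability included.

    Closed form for eta = 0; Gauss-Hermite quadrature over the Normal drift
    distribution otherwise.
    """
    if p.eta == 0:
        return float(_p_upper_fixed_drift(p.v, p.a, p.z, p.s))
    drifts = p.v + np.sqrt(2.0) * p.eta * _GH_X
    probs = np.array([_p_upper_fixed_drift(u, p.a, p.z, p.s) for u in drifts])
    return float(np.sum(_GH_W * probs) / np.sqrt(np.pi))


def mean_decision_time(p: DDMParams) -> float:
    """Closed-form mean first-passage time for eta = 0 (both bounds pooled).

    Wald's identity gives E[T] = (a * P_upper - z) / v for v != 0; the
    driftless limit is z * (a - z) / s^2.  For z = a/2 this reduces to the
    familiar (a / 2v) * tanh(v * a / (2 s^2)).
    """
    if p.eta != 0:
        raise ValueError("closed form requires eta = 0")
    v, a, z, s = p.v, p.a, p.z, p.s
    if abs(v) < 1e-12:
        return float(z * (a - z) / (s * s))
    pu = _p_upper_fixed_drift(v, a, z, s)
    return float((a * pu - z) / v)


def simulate_trials(p: DDMParams, n: int, seed: int, dt: float = 0.001,
                    t_max: float = 10.0):
    """Euler-Maruyama simulation of ``n`` trials.

    Returns arrays (rt, choice) with choice 1 = upper, 0 = lower,
    -1 = censored at ``t_max``.  A censored fraction above 1% triggers a
    warning.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rt, choice = _wfpt.simulate_paths(n, p.v, p.a, p.z, p.t, p.eta, p.st,
                                      p.s, dt, t_max, seed)
    n_cens = int(np.sum(choice == -1))
    if n_cens > 0.01 * n:
        import warnings
        warnings.warn(f"{n_cens}/{n} paths not absorbed by t_max={t_max}")
    return rt, choice


def simulate_one_choice(v, a, t, eta=0.0, st=0.0, s=0.1, n=1000, seed=0,
                        t_max=30.0):
    """First-passage times of the single-boundary (one-choice) model.

    Sampling is exact: Wald draws for positive per-trial drift, and for
    non-positive drift the absorption event (probability exp(2*u*a/s^2)) is
    drawn first, then a Wald/Levy time conditional on absorption.
    Non-terminating or > t_max trials are returned as NaN; the caller drops
    them from RT summaries.
    """
    if a <= 0:
        raise ValueError("a must be > 0")
    rt = _wfpt.simulate_one_choice_core(n, v, a, t, eta, st, s, t_max, seed)
    n_cens = int(np.sum(np.isnan(rt)))
    if n_cens > 0.05 * n:
        import warnings
        warnings.warn(f"{n_cens}/{n} one-choice trials censored")
    return rt


def sample_exact(p: DDMParams, n: int, seed: int, grid_points: int = 8192,
                 t_max: float | None = None):
    """Draw (rt, choice) by inverse-CDF sampling of the defective
    first-passage distributions.

    Exact up to the density-grid resolution (no time-discretization bias,
    unlike the Euler path simulator); drift and non-decision-time
    variability are already marginalized inside the density.  The extreme
    upper tail beyond ``t_max`` (default: survival mass ~1e-8) is truncated.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo = p.t - p.st / 2
    if t_max is None:
        # decision-time tail decays like exp(-lambda tau); generous cap
        lam = (np.pi ** 2 * p.s ** 2 / (2 * p.a ** 2)) + p.v ** 2 / (2 * p.s ** 2)
        t_max = lo + min(max(20.0 / lam * 0.25, 5.0), 60.0)
    grid = np.linspace(lo, t_max, grid_points)
    fu = np.clip(fpt_density(grid, "upper", p), 0, None)
    fl = np.clip(fpt_density(grid, "lower", p), 0, None)
    dt = grid[1] - grid[0]
    Fu = np.concatenate([[0.0], np.cumsum(0.5 * (fu[1:] + fu[:-1])) * dt])
    Fl = np.concatenate([[0.0], np.cumsum(0.5 * (fl[1:] + fl[:-1])) * dt])
    total = Fu[-1] + Fl[-1]
    u = rng.uniform(0.0, total, n)
    upper = u < Fu[-1]
    rt = np.empty(n)
    rt[upper] = np.interp(u[upper], Fu, grid)
    rt[~upper] = np.interp(u[~upper] - Fu[-1], Fl, grid)
    return rt, upper.astype(np.int64)


# bounds of the valid domain used when drawing mock subjects
_DOMAIN_LOW = {"v": -np.inf, "a": 1e-6, "t": 1e-6, "eta": 0.0, "st": 0.0}


def draw_subject_params(group_means: dict, group_sds: dict, n_subjects: int,
                        seed: int) -> list[DDMParams]:
    """Draw per-subject parameter sets from Normal(group mean, group SD).

    Draws are rejected-and-redrawn until inside each parameter's valid
    domain; a rejection rate above 50% raises (misconfigured SDs).  The
    constraint t >= st/2 is enforced jointly.
    """
    rng = np.random.default_rng(seed)
    for k, sd in group_sds.items():
        if sd < 0:
            raise ValueError(f"group SD for {k} must be >= 0")
    out = []
    n_draws = 0
    n_rej = 0
    for _ in range(n_subjects):
        while True:
            n_draws += 1
            if n_rej > 50 + 0.5 * n_draws and n_draws > 100:
                raise ValueError("truncation rejection rate > 50%; "
                                 "check group SDs against parameter domains")
            vals = {}
            ok = True
            for k, mu in group_means.items():
                x = rng.normal(mu, group_sds.get(k, 0.0))
                if x < _DOMAIN_LOW.get(k, -np.inf):
                    ok = False
                    break
                vals[k] = x
            if ok and vals.get("t", 1.0) < vals.get("st", 0.0) / 2:
                ok = False
            if ok:
                out.append(DDMParams(
                    v=vals.get("v", 0.0), a=vals["a"], t=vals.get("t", 0.0),
                    eta=vals.get("eta", 0.0), st=vals.get("st", 0.0),
                    s=vals.get("s", 0.1)))
                break
            n_rej += 1
    return out
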
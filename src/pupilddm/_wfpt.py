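"""Numba kernels for Wiener first-passage-time numerics and path simulation.

All kernels work in noise-normalized units internally (divide evidence-space
quantities by the within-trial noise SD ``s``); first-passage *times* are
invariant under that rescaling, so no Jacobian is needed.

The defective density at one boundary factorizes as

    f_bound(tau | u) = exp(-u*w - u^2*tau/2) * g(tau; a, w)

where ``u`` is the (normalized) drift, ``w`` the distance from the starting
point to the absorbing boundary being hit, and ``g`` the drift-free series
(small-time or large-time expansion, selected by the usual accuracy
criterion).  Because the drift enters only through that Gaussian factor, the
between-trial drift distribution Normal(v, eta^2) integrates in closed form;
uniform non-decision-time variability is handled by fixed-order
Gauss-Legendre quadrature.
"""

import math

import numpy as np
from numba import njit

# series truncation tolerance for the drift-free expansions
_SERIES_EPS = 1e-8
# hard cap on series terms (never reached for sane inputs)
_KMAX = 64


@njit(cache=True, fastmath=True)
def _fnorm(tt, w):
    """Drift-free FPT density for unit boundary separation, normalized time.

    ``tt`` = tau / a^2, ``w`` = (distance to hit boundary) / a, both in (0, 1)
    for w.  Chooses the cheaper of the small-time and large-time expansions.
    """
    if tt <= 0.0:
        return 0.0
    eps = _SERIES_EPS
    # number of terms needed by each expansion (Navarro-Fuss style bounds)
    if math.pi * tt * eps < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * tt * math.log(2.0 * eps * math.sqrt(2.0 * math.pi * tt)))
        ks = max(ks, math.sqrt(tt) + 1.0)
    else:
        ks = 2.0
    if math.pi * tt * eps < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * tt * eps) / (math.pi * math.pi * tt))
        kl = max(kl, 1.0 / (math.pi * math.sqrt(tt)))
    else:
        kl = 1.0 / (math.pi * math.sqrt(tt))

    if ks < kl:
        K = int(math.ceil((ks - 1.0) / 2.0))
        if K > _KMAX:
            K = _KMAX
        acc = 0.0
        for k in range(-K, K + 1):
            x = w + 2.0 * k
            acc += x * math.exp(-x * x / (2.0 * tt))
        return acc / math.sqrt(2.0 * math.pi * tt ** 3)
    else:
        K = int(math.ceil(kl))
        if K > _KMAX:
            K = _KMAX
        acc = 0.0
        for k in range(1, K + 1):
            acc += k * math.exp(-k * k * math.pi * math.pi * tt / 2.0) * math.sin(k * math.pi * w)
        return acc * math.pi


@njit(cache=True, fastmath=True)
def _density_tau(tau, upper, v, a, z, eta):
    """Defective FPT density at decision time tau, normalized units (s = 1).

    Drift variability eta >= 0 is marginalized in closed form:
    with alpha = 1 + eta^2 * tau,

        M = alpha^{-1/2} exp((eta^2 w^2 - 2 b w - (b w / |b w|)... )

    concretely, for exponent exp(-u*w_signed - u^2 tau/2) with
    u ~ N(v, eta^2):  M = alpha^{-1/2} *
        exp((eta^2 w_s^2 - 2 v w_s - v^2 tau) / (2 alpha)).
    Lower bound: w_s = z.  Upper bound: w_s = -(a - z).
    """
    if tau <= 0.0 or a <= 0.0 or z <= 0.0 or z >= a:
        return 0.0
    if upper:
        w = a - z
        ws = -w
    else:
        w = z
        ws = w
    alpha = 1.0 + eta * eta * tau
    expo = (eta * eta * w * w - 2.0 * v * ws - v * v * tau) / (2.0 * alpha)
    if expo > 50.0:
        expo = 50.0
    m = math.exp(expo) / math.sqrt(alpha)
    return m * _fnorm(tau / (a * a), w / a) / (a * a)


@njit(cache=True, fastmath=True)
def _series_counts(tt_lo, tt_hi):
    """Conservative term counts for both expansions over a tau range.

    The small-time expansion needs more terms at large normalized time, the
    large-time expansion at small normalized time, so each count is taken
    at its worst end of the interval.
    """
    eps = _SERIES_EPS
    if math.pi * tt_hi * eps < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * tt_hi * math.log(2.0 * eps * math.sqrt(2.0 * math.pi * tt_hi)))
        ks = max(ks, math.sqrt(tt_hi) + 1.0)
    else:
        ks = 2.0
    if math.pi * tt_lo * eps < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * tt_lo * eps) / (math.pi * math.pi * tt_lo))
        kl = max(kl, 1.0 / (math.pi * math.sqrt(tt_lo)))
    else:
        kl = 1.0 / (math.pi * math.sqrt(tt_lo))
    Ks = int(math.ceil((ks - 1.0) / 2.0))
    Kl = int(math.ceil(kl))
    return min(max(Ks, 1), _KMAX), min(max(Kl, 1), _KMAX)


@njit(cache=True, fastmath=True)
def _fnorm_small(tt, w, K):
    acc = 0.0
    for k in range(-K, K + 1):
        x = w + 2.0 * k
        acc += x * math.exp(-x * x / (2.0 * tt))
    return acc / math.sqrt(2.0 * math.pi * tt ** 3)


@njit(cache=True, fastmath=True)
def _fnorm_large(tt, w, K):
    acc = 0.0
    for k in range(1, K + 1):
        acc += k * math.exp(-k * k * math.pi * math.pi * tt / 2.0) * math.sin(k * math.pi * w)
    return acc * math.pi


@njit(cache=True, fastmath=True)
def wfpt_pdf(rt, upper, v, a, t0, z, eta, st, s, gl_x, gl_w):
    """Defective density of the full DDM at observed time ``rt``.

    Parameters are in natural units; ``gl_x``/``gl_w`` are Gauss-Legendre
    nodes/weights on [-1, 1] for the uniform non-decision-time integral.
    The series expansion and its truncation order are selected once per
    call (conservatively over the whole non-decision-time interval) and
    reused at every quadrature node.
    """
    vn = v / s
    an = a / s
    zn = z / s
    en = eta / s
    if st <= 0.0:
        return _density_tau(rt - t0, upper, vn, an, zn, en)
    tau_hi = rt - (t0 - 0.5 * st)
    if tau_hi <= 0.0 or an <= 0.0 or zn <= 0.0 or zn >= an:
        return 0.0
    tau_lo = rt - (t0 + 0.5 * st)
    if upper:
        w = an - zn
        ws = -w
    else:
        w = zn
        ws = w
    a2 = an * an
    wn = w / an
    tt_lo = max(tau_lo, 1e-4) / a2
    tt_hi = tau_hi / a2
    Ks, Kl = _series_counts(tt_lo, tt_hi)
    use_small = (2 * Ks + 1) < Kl
    e2 = en * en
    eww = e2 * w * w
    acc = 0.0
    for i in range(gl_x.shape[0]):
        tau = rt - (t0 + 0.5 * st * gl_x[i])
        if tau <= 0.0:
            continue
        alpha = 1.0 + e2 * tau
        expo = (eww - 2.0 * vn * ws - vn * vn * tau) / (2.0 * alpha)
        if expo > 50.0:
            expo = 50.0
        m = math.exp(expo) / math.sqrt(alpha)
        tt = tau / a2
        if use_small:
            g = _fnorm_small(tt, wn, Ks)
        else:
            g = _fnorm_large(tt, wn, Kl)
        acc += 0.5 * gl_w[i] * m * g / a2
    return acc


@njit(cache=True, fastmath=True)
def wfpt_pdf_arr(rt, upper, v, a, t0, z, eta, st, s, gl_x, gl_w, out):
    for i in range(rt.shape[0]):
        out[i] = wfpt_pdf(rt[i], upper[i], v, a, t0, z, eta, st, s, gl_x, gl_w)


@njit(cache=True, fastmath=True)
def loglik_by_subject(rt, upper, subj, v, a, t0, eta, st, s, gl_x, gl_w,
                      floor, out):
    """Accumulate per-subject log-likelihoods for one pupil bin.

    ``subj`` indexes into the per-subject parameter arrays; ``z`` is fixed at
    a/2.  Densities are floored at ``floor`` so that proposals rendering an
    observed RT impossible stay finite (and are effectively rejected).
    """
    out[:] = 0.0
    for i in range(rt.shape[0]):
        p = subj[i]
        f = wfpt_pdf(rt[i], upper[i], v[p], a[p], t0[p], 0.5 * a[p],
                     eta[p], st[p], s, gl_x, gl_w)
        if f < floor:
            f = floor
        out[p] += math.log(f)


@njit(cache=True)
def set_seed(seed):
    """Seed numba's global RNG (for sequential single-trial simulation)."""
    np.random.seed(seed)


@njit(cache=True)
def _euler_single(u, a, z, s, dt, t_max):
    """One Euler-Maruyama path with diffusion-bridge boundary corrections.

    Plain Euler overshoots absorbing boundaries (an O(sqrt(dt)) bias in both
    RT and choice probability); between consecutive interior points the
    Brownian bridge crosses a boundary at distance d0, d1 with probability
    exp(-2 d0 d1 / (s^2 dt)), which is applied at every step.
    Returns (decision_time, choice); choice -1 means censored.
    """
    sq = s * math.sqrt(dt)
    inv = 2.0 / (s * s * dt)
    x = z
    t = 0.0
    while t < t_max:
        xn = x + u * dt + sq * np.random.randn()
        t += dt
        # absorption times are recorded at the step midpoint, removing the
        # O(dt/2) positive bias of end-of-step bookkeeping
        if xn >= a:
            return t - 0.5 * dt, 1
        if xn <= 0.0:
            return t - 0.5 * dt, 0
        # bridge crossing of the upper boundary
        if np.random.rand() < math.exp(-(a - x) * (a - xn) * inv):
            return t - 0.5 * dt, 1
        if np.random.rand() < math.exp(-x * xn * inv):
            return t - 0.5 * dt, 0
        x = xn
    return t, -1


@njit(cache=True)
def simulate_paths(n, v, a, z, t0, eta, st, s, dt, t_max, seed):
    """Simulate n two-boundary trials.

    Returns (rt, choice) with choice 1 = upper, 0 = lower, -1 = censored at
    t_max (rt then equals t_max + non-decision time).
    """
    np.random.seed(seed)
    rt = np.empty(n)
    choice = np.empty(n, dtype=np.int64)
    for i in range(n):
        u = v + eta * np.random.randn() if eta > 0.0 else v
        tnd = t0 + st * (np.random.rand() - 0.5) if st > 0.0 else t0
        dtime, c = _euler_single(u, a, z, s, dt, t_max)
        rt[i] = dtime + tnd
        choice[i] = c
    return rt, choice


@njit(cache=True)
def simulate_paths_driftarray(u_arr, a, z, t0, st, s, dt, t_max, seed):
    """Path simulation with an externally supplied per-trial drift array."""
    np.random.seed(seed)
    n = u_arr.shape[0]
    rt = np.empty(n)
    choice = np.empty(n, dtype=np.int64)
    for i in range(n):
        tnd = t0 + st * (np.random.rand() - 0.5) if st > 0.0 else t0
        dtime, c = _euler_single(u_arr[i], a, z, s, dt, t_max)
        rt[i] = dtime + tnd
        choice[i] = c
    return rt, choice


@njit(cache=True)
def _wald_sample(mu, lam):
    """Inverse-Gaussian draw, Michael-Schucany-Haas transformation."""
    nu = np.random.randn()
    y = nu * nu
    x = mu + mu * mu * y / (2.0 * lam) - mu / (2.0 * lam) * math.sqrt(
        4.0 * mu * lam * y + mu * mu * y * y)
    if np.random.rand() <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=True)
def _wald_from(nu, u, mu, lam):
    """Inverse-Gaussian draw from supplied standard variates."""
    y = nu * nu
    x = mu + mu * mu * y / (2.0 * lam) - mu / (2.0 * lam) * math.sqrt(
        4.0 * mu * lam * y + mu * mu * y * y)
    if u <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=True)
def one_choice_sd_over_etas(n, v, a, t0, st, s, etas, t_max, seed):
    """Per-eta RT mean/SD with common random numbers across eta values.

    Each trial consumes a fixed block of variates (drift z-score, Wald
    normal, two uniforms, non-decision uniform) reused for every eta, so
    differences between eta conditions reflect the parameter change rather
    than sampling noise.  Censored trials (no absorption, or beyond t_max)
    are excluded from the running moments.
    """
    np.random.seed(seed)
    K = etas.shape[0]
    cnt = np.zeros(K)
    s1 = np.zeros(K)
    s2 = np.zeros(K)
    lam = (a / s) * (a / s)
    for _ in range(n):
        zdrift = np.random.randn()
        nu = np.random.randn()
        u1 = np.random.rand()
        u2 = np.random.rand()
        utnd = np.random.rand()
        for k in range(K):
            u = v + etas[k] * zdrift
            if u > 0.0:
                fpt = _wald_from(nu, u2, a / u, lam)
            elif u == 0.0:
                fpt = lam / (nu * nu)
            else:
                if u1 >= math.exp(2.0 * u * a / (s * s)):
                    continue
                fpt = _wald_from(nu, u2, a / (-u), lam)
            if fpt > t_max:
                continue
            rt = fpt + t0 + st * (utnd - 0.5)
            cnt[k] += 1.0
            s1[k] += rt
            s2[k] += rt * rt
    mean = s1 / cnt
    var = (s2 - s1 * s1 / cnt) / (cnt - 1.0)
    return cnt, mean, np.sqrt(var)


@njit(cache=True)
def simulate_one_choice_core(n, v, a, t0, eta, st, s, t_max, seed):
    """Single-boundary FPT sampling, exact for every drift sign.

    Positive per-trial drift: Wald(a/u, (a/s)^2).  Non-positive drift: the
    process reaches the boundary with probability exp(2*u*a/s^2) (1 for
    u = 0); conditional on absorption the FPT is Wald with drift |u| (Levy
    for u = 0).  Trials that never terminate, or terminate after t_max, are
    censored (rt = nan).
    """
    np.random.seed(seed)
    rt = np.full(n, np.nan)
    for i in range(n):
        u = v + eta * np.random.randn() if eta > 0.0 else v
        tnd = t0 + st * (np.random.rand() - 0.5) if st > 0.0 else t0
        lam = (a / s) * (a / s)
        if u > 0.0:
            fpt = _wald_sample(a / u, lam)
        elif u == 0.0:
            nu = np.random.randn()
            fpt = lam / (nu * nu)
        else:
            p_hit = math.exp(2.0 * u * a / (s * s))
            if np.random.rand() >= p_hit:
                continue
            fpt = _wald_sample(a / (-u), lam)
        if fpt <= t_max:
            rt[i] = fpt + tnd
    return rt
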
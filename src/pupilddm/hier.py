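"""Hierarchical Bayesian estimation of the pupil-binned drift-diffusion model.

Model (primary variant): for pupil bin i (low/high), subject p, trial j,

    (rt, accuracy)_{ipj} ~ Wiener FPT(v_{ip}, a_{ip}, t_{ip}, eta_{ip},
                                      st_p, z = a/2, s = 0.1)
    theta_{ip} ~ Normal(mu_theta_i, sigma_theta_i)   for theta in {v,a,t,eta}
    st_p       ~ Normal(mu_st, sigma_st)             (bin-invariant)

with weakly informative truncated-Normal hyperpriors on the group means and
half-Normal priors on the group SDs.  Two alternative variants constrain the
structure: ``group_eta`` estimates eta only at the group level (one value
per bin shared by all subjects), and ``eta_only`` lets only eta vary across
bins while a, t and v are bin-invariant.

Sampling is adaptive Gaussian random-walk Metropolis within Gibbs.  Subject
parameters of one type are updated simultaneously across subjects through a
single vectorized likelihood kernel; group means have conjugate
(truncated-Normal) Gibbs updates and group SDs log-scale Metropolis steps.
Step sizes adapt only during burn-in, preserving detailed balance for the
retained draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri

from . import _wfpt
from .ddm import LIKELIHOOD_FLOOR, _GL_X, _GL_W, DDMParams

__all__ = [
    "HierarchicalModelSpec",
    "PosteriorSamples",
    "EffectDistribution",
    "build_model",
    "sample_posterior",
    "rhat",
    "effect_distribution",
    "posterior_predict",
    "subject_delta_eta",
]

BINS = ("low", "high")
_PARAMS = ("a", "t", "v", "eta")

# hyperpriors: (prior mean, prior SD, lower truncation bound)
_MU_PRIOR = {
    "v": (0.2, 0.5, -np.inf),
    "a": (0.12, 0.1, 1e-4),
    "t": (0.4, 0.3, 1e-4),
    "eta": (0.15, 0.2, 0.0),
    "st": (0.1, 0.2, 0.0),
}
_SIGMA_SCALE = 0.1  # half-Normal scale for all group SDs
_DOMAIN_LOW = {"v": -np.inf, "a": 1e-4, "t": 1e-3, "eta": 0.0, "st": 0.0}


@dataclass(frozen=True)
class HierarchicalModelSpec:
    variant: str
    bin_varying: frozenset
    eta_level: str  # "subject" or "group_only"
    s: float = 0.1

    def __post_init__(self):
        unknown = self.bin_varying - {"a", "t", "v", "eta"}
        if unknown:
            raise ValueError(f"unknown bin-varying parameters: {unknown}")


def build_model(variant: str = "primary") -> HierarchicalModelSpec:
    """Return the model specification for one of the three fitted variants.

    ``primary``: a, t, v and eta all vary across pupil bins, eta estimated
    per subject.  ``group_eta``: same bin structure but eta estimated only
    at the group level.  ``eta_only``: only eta varies across bins.
    Starting-point variability (sz) is omitted in every variant and z is
    fixed at a/2.
    """
    if variant == "primary":
        return HierarchicalModelSpec(variant, frozenset(_PARAMS), "subject")
    if variant == "group_eta":
        return HierarchicalModelSpec(variant, frozenset(_PARAMS), "group_only")
    if variant == "eta_only":
        return HierarchicalModelSpec(variant, frozenset({"eta"}), "subject")
    raise ValueError(f"unknown model variant {variant!r}")


@dataclass
class PosteriorSamples:
    """MCMC draws: chains x kept iterations, post burn-in.

    ``group`` maps names like ``mu_v_low`` or ``sigma_eta_high`` (and
    ``eta_low`` for the group-only variant) to (chains, kept) arrays;
    ``subject`` maps parameter names to (chains, kept, n_bins, n_subjects)
    arrays (n_bins = 1 for bin-invariant parameters).
    """

    spec: HierarchicalModelSpec
    group: dict
    subject: dict
    subjects: list
    trial_counts: dict = field(default_factory=dict)  # (bin, subject) -> n
    acceptance: dict = field(default_factory=dict)

    @property
    def n_chains(self):
        return next(iter(self.group.values())).shape[0]

    @property
    def n_kept(self):
        return next(iter(self.group.values())).shape[1]

    def pooled(self, name):
        return self.group[name].reshape(-1)


@dataclass
class EffectDistribution:
    parameter: str
    draws: np.ndarray  # pooled (high - low) group-mean draws
    p_above_zero: float
    mode: float


def _truncnorm_draw(rng, m, sd, lo):
    """One draw from Normal(m, sd) truncated below at lo (inverse CDF)."""
    if not np.isfinite(lo):
        return rng.normal(m, sd)
    alo = ndtr((lo - m) / sd)
    u = rng.uniform(alo, 1.0)
    u = min(max(u, 1e-15), 1 - 1e-15)
    return m + sd * ndtri(u)


def _ez_init(rt, correct, s):
    """EZ-style method-of-moments starting values (v, a, t0)."""
    n = len(rt)
    pc = np.clip(np.mean(correct), 0.55, 1 - 1 / (2 * max(n, 2)))
    vrt = max(np.var(rt[correct.astype(bool)]) if correct.sum() > 2
              else np.var(rt), 1e-4)
    L = np.log(pc / (1 - pc))
    x = L * (L * pc ** 2 - L * pc + pc - 0.5) / vrt
    v = s * x ** 0.25
    a = s * s * L / v
    mdt = (a / (2 * v)) * (1 - np.exp(-v * a / s ** 2)) / (1 + np.exp(-v * a / s ** 2))
    t0 = np.mean(rt) - mdt
    t0 = min(max(t0, 0.05), np.min(rt) * 0.95)
    return v, a, t0


class _State:
    """Mutable sampler state for one chain."""

    def __init__(self, spec, data, rng):
        self.spec = spec
        P = data["n_subjects"]
        nb = {p: (2 if p in spec.bin_varying else 1) for p in _PARAMS}
        self.nb = nb
        self.val = {}
        for p in _PARAMS:
            self.val[p] = np.empty((nb[p], P))
        self.st = np.empty(P)
        init = data["init"]
        for p in _PARAMS:
            for b in range(nb[p]):
                self.val[p][b] = init[p] * np.exp(rng.normal(0, 0.05, P)) \
                    if p in ("a", "t", "eta") else init[p] + rng.normal(0, 0.02, P)
        # keep t0 below each subject's fastest RT
        for b in range(nb["t"]):
            self.val["t"][b] = np.minimum(self.val["t"][b], data["min_rt"] * 0.9)
        self.st[:] = np.clip(rng.normal(0.05, 0.01, P), 0.005, None)
        self.eta_g = np.array([0.1, 0.1])  # group-only eta, per bin
        self.mu = {}
        self.sig = {}
        for p in _PARAMS + ("st",):
            k = 1 if p == "st" else nb[p]
            if p == "eta" and spec.eta_level == "group_only":
                continue
            src = self.st if p == "st" else self.val[p]
            self.mu[p] = np.array([np.mean(src[b] if p != "st" else src)
                                   for b in range(k)])
            self.sig[p] = np.full(k, 0.05)


def _loglik_bin(state, data, b, s, val_override=None):
    """Per-subject log-likelihood of bin ``b`` under current (or overridden)
    subject-level values."""
    spec = state.spec
    arrs = {}
    for p in _PARAMS:
        v = state.val[p]
        if val_override and p in val_override:
            v = val_override[p]
        arrs[p] = v[b if v.shape[0] == 2 else 0]
    if spec.eta_level == "group_only":
        eg = val_override["eta_g"] if val_override and "eta_g" in val_override \
            else state.eta_g
        arrs["eta"] = np.full(data["n_subjects"], eg[b])
    st = val_override["st"] if val_override and "st" in val_override else state.st
    out = np.empty(data["n_subjects"])
    _wfpt.loglik_by_subject(
        data["rt"][b], data["upper"][b], data["subj"][b],
        arrs["v"], arrs["a"], arrs["t"], arrs["eta"], st, s,
        _GL_X, _GL_W, LIKELIHOOD_FLOOR, out)
    return out


def sample_posterior(spec: HierarchicalModelSpec, data, chains: int = 6,
                     iterations: int = 15000, burnin: int = 10000,
                     seed: int = 0, progress: bool = False) -> PosteriorSamples:
    """Draw from the joint posterior by Metropolis-within-Gibbs.

    ``data`` is a binned trial table (pandas DataFrame with columns
    ``subject``, ``rt``, ``accuracy``, ``pupil_bin`` where pupil_bin is
    'low' or 'high'; 'middle'/'unassigned' rows are ignored).  Per-chain
    seeds are derived from the master seed, so runs are reproducible.
    """
    if burnin >= iterations:
        raise ValueError("burnin must be < iterations")
    d = _prepare_data(data, spec)
    kept = iterations - burnin
    P = d["n_subjects"]
    nb = {p: (2 if p in spec.bin_varying else 1) for p in _PARAMS}

    group_names = []
    for p in _PARAMS:
        if p == "eta" and spec.eta_level == "group_only":
            for b in range(nb[p]):
                group_names.append(f"eta_{BINS[b] if nb[p] == 2 else 'all'}")
            continue
        for b in range(nb[p]):
            tag = BINS[b] if nb[p] == 2 else "all"
            group_names.append(f"mu_{p}_{tag}")
            group_names.append(f"sigma_{p}_{tag}")
    group_names += ["mu_st", "sigma_st"]
    group_store = {k: np.empty((chains, kept)) for k in group_names}
    subj_store = {p: np.empty((chains, kept, nb[p], P), dtype=np.float32)
                  for p in _PARAMS if not (p == "eta" and spec.eta_level == "group_only")}
    subj_store["st"] = np.empty((chains, kept, 1, P), dtype=np.float32)
    acc_report = {}

    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(chains)
    for c in range(chains):
        rng = np.random.default_rng(chain_seeds[c])
        state = _State(spec, d, rng)
        _run_chain(state, d, spec, iterations, burnin, rng,
                   group_store, subj_store, c, acc_report, progress)
    return PosteriorSamples(spec=spec, group=group_store, subject=subj_store,
                            subjects=d["subject_ids"],
                            trial_counts=d["trial_counts"],
                            acceptance=acc_report)


def _prepare_data(trials, spec):
    import pandas as pd
    t = trials[trials["pupil_bin"].isin(BINS)].copy()
    subject_ids = sorted(t["subject"].unique())
    smap = {s: i for i, s in enumerate(subject_ids)}
    P = len(subject_ids)
    d = {"n_subjects": P, "subject_ids": subject_ids, "rt": {}, "upper": {},
         "subj": {}, "trial_counts": {}}
    min_rt = np.full(P, np.inf)
    for b, bname in enumerate(BINS):
        tb = t[t["pupil_bin"] == bname]
        d["rt"][b] = tb["rt"].to_numpy(float)
        d["upper"][b] = tb["accuracy"].to_numpy() > 0.5
        d["subj"][b] = tb["subject"].map(smap).to_numpy(np.int64)
        for s_id in subject_ids:
            sub = tb[tb["subject"] == s_id]
            d["trial_counts"][(bname, s_id)] = len(sub)
            ncor = int((sub["accuracy"] > 0.5).sum())
            if len(sub) and (ncor == 0 or ncor == len(sub)):
                warnings.warn(f"subject {s_id} bin {bname} lacks both correct "
                              "and error trials; its defective-likelihood "
                              "contribution is degenerate")
        np.minimum.at(min_rt, d["subj"][b], d["rt"][b])
    d["min_rt"] = min_rt
    # EZ-style initial values pooled over bins, per subject
    init = {p: np.empty(P) for p in _PARAMS}
    rt_all = np.concatenate([d["rt"][0], d["rt"][1]])
    up_all = np.concatenate([d["upper"][0], d["upper"][1]])
    sj_all = np.concatenate([d["subj"][0], d["subj"][1]])
    for p_i in range(P):
        m = sj_all == p_i
        v, a, t0 = _ez_init(rt_all[m], up_all[m].astype(float), spec.s)
        init["v"][p_i], init["a"][p_i], init["t"][p_i] = v, a, t0
        init["eta"][p_i] = 0.1
    d["init"] = init
    return d


def _run_chain(state, d, spec, iterations, burnin, rng, group_store,
               subj_store, c, acc_report, progress):
    P = d["n_subjects"]
    s = spec.s
    nb = state.nb
    ll = np.vstack([_loglik_bin(state, d, b, s) for b in range(2)])  # (2, P)

    # one adaptive step size per (parameter, bin)
    steps = {(p, b): 0.03 if p != "t" else 0.02
             for p in _PARAMS for b in range(nb[p])}
    steps[("st", 0)] = 0.02
    steps[("eta_g", 0)] = 0.01
    steps[("eta_g", 1)] = 0.01
    steps[("joint", 0)] = 0.02
    steps[("joint", 1)] = 0.02
    acc = {k: 0 for k in steps}
    tot = {k: 0 for k in steps}

    subject_params = [p for p in _PARAMS
                      if not (p == "eta" and spec.eta_level == "group_only")]
    kept_i = 0
    for it in range(iterations):
        # --- subject-level updates, vectorized across subjects ---
        for p in subject_params:
            for b in range(nb[p]):
                cur = state.val[p][b]
                prop = cur + steps[(p, b)] * rng.standard_normal(P)
                ok = prop > _DOMAIN_LOW[p]
                if p == "t":
                    ok &= prop >= state.st / 2
                newv = state.val[p].copy()
                newv[b] = np.where(ok, prop, cur)
                bins_aff = [b] if nb[p] == 2 else [0, 1]
                ll_prop = np.vstack([
                    _loglik_bin(state, d, bb, s, {p: newv})
                    for bb in bins_aff])
                ll_cur = ll[bins_aff, :]
                lp = (_norm_logpdf(prop, state.mu[p][b], state.sig[p][b])
                      - _norm_logpdf(cur, state.mu[p][b], state.sig[p][b]))
                delta = ll_prop.sum(axis=0) - ll_cur.sum(axis=0) + lp
                accept = ok & (np.log(rng.random(P)) < delta)
                state.val[p][b] = np.where(accept, prop, cur)
                for k, bb in enumerate(bins_aff):
                    ll[bb] = np.where(accept, ll_prop[k], ll[bb])
                acc[(p, b)] += int(accept.sum())
                tot[(p, b)] += P
        # --- joint (v, eta) ridge updates ---
        # v and eta trade off (more drift variability needs more drift to
        # hold accuracy), so componentwise walks crawl along a ridge;
        # a correlated 2-D proposal traverses it.
        if spec.eta_level == "subject":
            for b in range(nb["eta"]):
                bv = b if nb["v"] == 2 else 0
                cur_v = state.val["v"][bv]
                cur_e = state.val["eta"][b]
                n1 = rng.standard_normal(P)
                n2 = rng.standard_normal(P)
                sc = steps[("joint", b)]
                prop_v = cur_v + sc * n1
                prop_e = cur_e + sc * (0.7 * n1 + 0.714 * n2)
                ok = prop_e > 0
                newv = state.val["v"].copy()
                newe = state.val["eta"].copy()
                newv[bv] = np.where(ok, prop_v, cur_v)
                newe[b] = np.where(ok, prop_e, cur_e)
                bins_aff = [b] if (nb["eta"] == 2 and nb["v"] == 2) else [0, 1]
                ll_prop = np.vstack([
                    _loglik_bin(state, d, bb, s, {"v": newv, "eta": newe})
                    for bb in bins_aff])
                lp = (_norm_logpdf(prop_v, state.mu["v"][bv], state.sig["v"][bv])
                      - _norm_logpdf(cur_v, state.mu["v"][bv], state.sig["v"][bv])
                      + _norm_logpdf(prop_e, state.mu["eta"][b], state.sig["eta"][b])
                      - _norm_logpdf(cur_e, state.mu["eta"][b], state.sig["eta"][b]))
                delta = ll_prop.sum(axis=0) - ll[bins_aff, :].sum(axis=0) + lp
                accept = ok & (np.log(rng.random(P)) < delta)
                state.val["v"][bv] = np.where(accept, prop_v, cur_v)
                state.val["eta"][b] = np.where(accept, prop_e, cur_e)
                for k2, bb in enumerate(bins_aff):
                    ll[bb] = np.where(accept, ll_prop[k2], ll[bb])
                acc[("joint", b)] += int(accept.sum())
                tot[("joint", b)] += P
        # --- st (shared across bins) ---
        cur = state.st
        prop = cur + steps[("st", 0)] * rng.standard_normal(P)
        tmin = state.val["t"].min(axis=0)
        ok = (prop >= 0) & (prop / 2 <= tmin)
        propc = np.where(ok, prop, cur)
        ll_prop = np.vstack([_loglik_bin(state, d, bb, s, {"st": propc})
                             for bb in range(2)])
        lp = (_norm_logpdf(prop, state.mu["st"][0], state.sig["st"][0])
              - _norm_logpdf(cur, state.mu["st"][0], state.sig["st"][0]))
        delta = ll_prop.sum(axis=0) - ll.sum(axis=0) + lp
        accept = ok & (np.log(rng.random(P)) < delta)
        state.st = np.where(accept, prop, cur)
        for bb in range(2):
            ll[bb] = np.where(accept, ll_prop[bb], ll[bb])
        acc[("st", 0)] += int(accept.sum())
        tot[("st", 0)] += P
        # --- group-level eta for the group_only variant ---
        if spec.eta_level == "group_only":
            for b in range(nb["eta"]):
                cur_e = state.eta_g[b]
                prop_e = cur_e + steps[("eta_g", b)] * rng.standard_normal()
                if prop_e >= 0:
                    eg = state.eta_g.copy()
                    eg[b] = prop_e
                    bins_aff = [b] if nb["eta"] == 2 else [0, 1]
                    llp = np.vstack([_loglik_bin(state, d, bb, s, {"eta_g": eg})
                                     for bb in bins_aff])
                    m0, s0, lo = _MU_PRIOR["eta"]
                    dlt = (llp.sum() - ll[bins_aff, :].sum()
                           + _norm_logpdf(prop_e, m0, s0)
                           - _norm_logpdf(cur_e, m0, s0))
                    if np.log(rng.random()) < dlt:
                        state.eta_g[b] = prop_e
                        for k, bb in enumerate(bins_aff):
                            ll[bb] = llp[k]
                        acc[("eta_g", b)] += 1
                tot[("eta_g", b)] += 1
        # --- group means: conjugate truncated-Normal Gibbs ---
        for p in subject_params + ["st"]:
            m0, s0, lo = _MU_PRIOR[p]
            k = 1 if p == "st" else nb[p]
            for b in range(k):
                vals = state.st if p == "st" else state.val[p][b]
                sg = state.sig[p][b]
                prec = len(vals) / sg ** 2 + 1 / s0 ** 2
                mpost = (vals.sum() / sg ** 2 + m0 / s0 ** 2) / prec
                state.mu[p][b] = _truncnorm_draw(rng, mpost, prec ** -0.5, lo)
        # --- group SDs: log-scale Metropolis with half-Normal prior ---
        for p in subject_params + ["st"]:
            k = 1 if p == "st" else nb[p]
            for b in range(k):
                vals = state.st if p == "st" else state.val[p][b]
                cur_s = state.sig[p][b]
                prop_s = cur_s * np.exp(0.1 * rng.standard_normal())
                dlt = (_norm_logpdf(vals, state.mu[p][b], prop_s).sum()
                       - _norm_logpdf(vals, state.mu[p][b], cur_s).sum()
                       - 0.5 * (prop_s ** 2 - cur_s ** 2) / _SIGMA_SCALE ** 2
                       + np.log(prop_s) - np.log(cur_s))  # log-scale Jacobian
                if np.log(rng.random()) < dlt:
                    state.sig[p][b] = prop_s
        # --- step-size adaptation (burn-in only) ---
        if it < burnin and (it + 1) % 50 == 0:
            for key in steps:
                if tot[key] == 0:
                    continue
                rate = acc[key] / tot[key]
                steps[key] *= float(np.exp(0.8 * (rate - 0.35)))
                acc[key] = 0
                tot[key] = 0
        # --- record ---
        if it >= burnin:
            for p in subject_params:
                for b in range(nb[p]):
                    tag = BINS[b] if nb[p] == 2 else "all"
                    group_store[f"mu_{p}_{tag}"][c, kept_i] = state.mu[p][b]
                    group_store[f"sigma_{p}_{tag}"][c, kept_i] = state.sig[p][b]
                subj_store[p][c, kept_i] = state.val[p]
            if spec.eta_level == "group_only":
                for b in range(nb["eta"]):
                    tag = BINS[b] if nb["eta"] == 2 else "all"
                    group_store[f"eta_{tag}"][c, kept_i] = state.eta_g[b]
            group_store["mu_st"][c, kept_i] = state.mu["st"][0]
            group_store["sigma_st"][c, kept_i] = state.sig["st"][0]
            subj_store["st"][c, kept_i, 0] = state.st
            kept_i += 1
    for key in steps:
        acc_report[(c,) + key] = acc[key] / max(tot[key], 1)


def _norm_logpdf(x, m, sd):
    return -0.5 * ((x - m) / sd) ** 2 - np.log(sd) - 0.5 * np.log(2 * np.pi)


def rhat(samples: PosteriorSamples) -> dict:
    """Gelman-Rubin potential scale reduction for every group-level quantity.

    Compares between-chain to within-chain variance; values below 1.05 are
    conventionally taken as converged.
    """
    if samples.n_chains < 2:
        raise ValueError("R-hat requires at least 2 chains")
    out = {}
    for name, draws in samples.group.items():
        out[name] = _rhat_array(draws)
    return out


def _rhat_array(draws):
    m, n = draws.shape
    chain_means = draws.mean(axis=1)
    w = draws.var(axis=1, ddof=1).mean()
    b = n * chain_means.var(ddof=1)
    if w <= 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def effect_distribution(samples: PosteriorSamples, parameter: str) -> EffectDistribution:
    """Posterior distribution of the (high - low) group-mean difference.

    ``p_above_zero`` counts draws above zero, with exact zeros contributing
    half (so an all-zero distribution reports 0.5).
    """
    if parameter not in samples.spec.bin_varying:
        raise ValueError(f"parameter {parameter!r} does not vary by bin in "
                         f"variant {samples.spec.variant!r}")
    if parameter == "eta" and samples.spec.eta_level == "group_only":
        hi, lo = samples.pooled("eta_high"), samples.pooled("eta_low")
    else:
        hi = samples.pooled(f"mu_{parameter}_high")
        lo = samples.pooled(f"mu_{parameter}_low")
    diff = hi - lo
    n = diff.size
    p_above = (np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / n
    hist, edges = np.histogram(diff, bins=64)
    mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
    return EffectDistribution(parameter, diff, float(p_above), float(mode))


def subject_delta_eta(samples: PosteriorSamples) -> np.ndarray:
    """Per-subject posterior-mean change in eta from low to high bin."""
    if samples.spec.eta_level == "group_only":
        raise ValueError("subject-level eta not estimated in this variant")
    if "eta" not in samples.spec.bin_varying:
        raise ValueError("eta does not vary by bin in this variant")
    e = samples.subject["eta"].astype(float)  # (chains, kept, 2, P)
    return (e[:, :, 1, :] - e[:, :, 0, :]).mean(axis=(0, 1))


def posterior_predict(samples: PosteriorSamples, n_datasets: int = 1000,
                      seed: int = 0, dt: float = 0.001):
    """Simulate new datasets from evenly thinned posterior draws.

    Each dataset regenerates every subject's per-bin trial counts from that
    draw's subject-level parameters, pools across subjects, and returns
    per-bin accuracy plus pooled correct/error RT quantiles per dataset.
    """
    total = samples.n_chains * samples.n_kept
    if n_datasets > total:
        raise ValueError(f"n_datasets={n_datasets} exceeds pooled draw count {total}")
    idx = np.linspace(0, total - 1, n_datasets).astype(int)
    chain_idx, it_idx = np.unravel_index(idx, (samples.n_chains, samples.n_kept))
    spec = samples.spec
    probs = (0.1, 0.3, 0.5, 0.7, 0.9)
    acc_out = np.empty((n_datasets, 2))
    q_cor = np.empty((n_datasets, 2, len(probs)))
    q_err = np.full((n_datasets, 2, len(probs)), np.nan)
    rng = np.random.default_rng(seed)
    for k in range(n_datasets):
        c, i = chain_idx[k], it_idx[k]
        for b, bname in enumerate(BINS):
            rts, cors = [], []
            for p_i, s_id in enumerate(samples.subjects):
                n = samples.trial_counts.get((bname, s_id), 0)
                if n == 0:
                    continue
                par = _draw_params(samples, spec, c, i, b, p_i)
                rt, ch = _wfpt.simulate_paths(
                    n, par.v, par.a, par.z, par.t, par.eta, par.st, par.s,
                    dt, 10.0, int(rng.integers(2 ** 31)))
                keep = ch >= 0
                rts.append(rt[keep])
                cors.append(ch[keep] == 1)
            rt = np.concatenate(rts)
            cor = np.concatenate(cors)
            acc_out[k, b] = cor.mean()
            q_cor[k, b] = np.quantile(rt[cor], probs)
            if (~cor).sum() >= len(probs):
                q_err[k, b] = np.quantile(rt[~cor], probs)
    return {"accuracy": acc_out, "rt_quantiles_correct": q_cor,
            "rt_quantiles_error": q_err, "probs": probs, "bins": BINS}


def _draw_params(samples, spec, c, i, b, p_i):
    def get(p):
        arr = samples.subject.get(p)
        if arr is None:  # group-only eta
            tag = BINS[b] if "eta" in spec.bin_varying else "all"
            return float(samples.group[f"eta_{tag}"][c, i])
        bi = b if arr.shape[2] == 2 else 0
        return float(arr[c, i, bi, p_i])
    a = max(get("a"), 1e-3)
    return DDMParams(v=get("v"), a=a, t=max(get("t"), 1e-3),
                     eta=max(get("eta"), 0.0),
                     st=min(max(float(samples.subject["st"][c, i, 0, p_i]), 0.0),
                            2 * max(get("t"), 1e-3)),
                     s=spec.s)
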
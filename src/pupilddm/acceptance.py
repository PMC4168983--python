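"""End-to-end recovery and consistency experiments.

Three self-contained computations, used by the ``recover`` CLI subcommand
and the repository's acceptance script:

* Table-recovery: simulate 26 subjects x 2 pupil bins x 196 trials from the
  published group-level means (between-subject SD 15% of each mean,
  z = a/2, s = 0.1), fit the primary hierarchical model at reduced MCMC
  scale (3 chains x 4,000 iterations, 2,000 burn-in) and report the
  posterior means of the group-level parameters.
* Behavioral consistency: simulate a large trial sample at the pooled
  (bin-averaged) group means and report percent correct and mean correct
  RT in ms.
* Calibration round-trip: generate psychometric data from known
  proportional-rate parameters, fit, invert at the 85% criterion, and
  simulate at the returned coherence.
"""

from __future__ import annotations

import numpy as np

from .calibration import fit_proportional_rate, interpolate_target_coherence
from .ddm import DDMParams, sample_exact, simulate_trials
from .hier import build_model, sample_posterior
from .synthetic import (TABLE1_BIN_MEANS, default_base_params,
                        gen_binned_dataset, gen_psychometric_dataset)

__all__ = ["table_recovery", "behavioral_consistency", "calibration_roundtrip",
           "run_all"]


def table_recovery(seed: int, chains: int = 3, iterations: int = 4000,
                   burnin: int = 2000, n_subjects: int = 26,
                   n_trials_per_bin: int = 196):
    """Posterior means of the group-level parameters after refitting data
    generated from the published group means."""
    ss = np.random.SeedSequence(seed)
    gen_seed, fit_seed = [int(s.generate_state(1)[0] % 2 ** 31)
                          for s in ss.spawn(2)]
    df = gen_binned_dataset(seed=gen_seed, n_subjects=n_subjects,
                            n_trials_per_bin=n_trials_per_bin)
    post = sample_posterior(build_model("primary"), df, chains=chains,
                            iterations=iterations, burnin=burnin,
                            seed=fit_seed)
    est = {k: float(post.pooled(k).mean())
           for k in ("mu_v_low", "mu_a_low", "mu_t_low", "mu_eta_low",
                     "mu_eta_high", "mu_st")}
    est["n_trials_total"] = n_subjects * 2 * n_trials_per_bin
    return est, post, df


def behavioral_consistency(seed: int, n_trials: int = 200_000):
    """Percent correct and mean correct RT (ms) at the pooled group means."""
    p = default_base_params()
    rt, ch = sample_exact(p, n_trials, seed=int(seed % 2 ** 31))
    acc_pct = 100.0 * float((ch == 1).mean())
    mean_rt_ms = 1000.0 * float(rt[ch == 1].mean())
    return {"accuracy_pct": acc_pct, "mean_correct_rt_ms": mean_rt_ms,
            "n": int(len(rt))}


def calibration_roundtrip(seed: int, n_per: int = 2000, n_check: int = 100_000,
                          k: float = 0.04, a: float = 0.8, t_r: float = 0.3,
                          target: float = 0.85):
    """Simulated accuracy at the coherence the fitted model recommends."""
    ss = np.random.SeedSequence(seed)
    s1, s2 = [int(s.generate_state(1)[0] % 2 ** 31) for s in ss.spawn(2)]
    table = gen_psychometric_dataset([0, 10, 20, 40, 80], n_per, k=k, a=a,
                                     t_r=t_r, seed=s1)
    params = fit_proportional_rate(table)
    cstar = interpolate_target_coherence(params, target)
    p = DDMParams(v=params.k * cstar, a=2 * params.a, t=params.t_r,
                  z=params.a, s=1.0)
    rt, ch = simulate_trials(p, n_check, seed=s2, t_max=30.0)
    acc = 100.0 * float((ch[ch >= 0] == 1).mean())
    return {"coherence_pct": float(cstar), "accuracy_pct": acc,
            "fitted": {"k": params.k, "a": params.a, "t_r": params.t_r},
            "n": int((ch >= 0).sum())}


def run_all(seed: int = 1) -> dict:
    """All three experiments; keyed results with problem sizes."""
    rec, _, _ = table_recovery(seed)
    beh = behavioral_consistency(seed + 1)
    cal = calibration_roundtrip(seed + 2)
    truth = TABLE1_BIN_MEANS
    return {
        "table_recovery": {
            **rec,
            "generating": {"low": truth["low"], "high": truth["high"],
                           "st": truth["st"]},
        },
        "behavioral_consistency": beh,
        "calibration_roundtrip": cal,
    }
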
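"""Trial-level regressions of behavior on baseline pupil, and group tests.

The within-subject models:

    logit P(correct) = b0 + b1 * Pupil                          (accuracy)
    RT = b0 + b1 * Acc + b2 * Pupil + b3 * Acc x Pupil          (RT)

plus expanded variants adding previous-trial accuracy and baseline-window
gaze position as nuisance covariates.  Pupil is the z-scored (within
subject) single-trial baseline diameter; RT is z-scored log RT; Acc is
1 = correct, 0 = error.  b1 of the accuracy model is reported as beta_acc
and b3 of the RT model as beta_rt_x (the pupil-by-accuracy interaction:
does the error/correct RT gap widen with pupil size?).  Group-level
inference is a one-sample t-test of the per-subject coefficients against
zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegressionResult",
    "prepare_predictors",
    "fit_eq_accuracy",
    "fit_eq_rt",
    "fit_expanded",
    "group_beta_test",
    "behavioral_summary",
    "rt_variability_by_bin",
    "between_subject_correlations",
]


@dataclass
class RegressionResult:
    terms: list
    betas: pd.DataFrame        # subjects x terms
    converged: pd.Series       # per subject
    group_t: pd.Series
    group_p: pd.Series

    def group_test(self, term, tail="two"):
        b = self.betas.loc[self.converged, term]
        return group_beta_test(b.to_numpy(), tail=tail)


def _zscore(x):
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("zero variance")
    return (x - x.mean()) / sd


def prepare_predictors(trials: pd.DataFrame) -> pd.DataFrame:
    """Within-subject design columns for the trial-level regressions.

    Adds pupil_z (z-scored baseline), log_rt_z, acc (1 = correct),
    prev_acc (previous-trial accuracy; NaN on each subject's first trial)
    and, when gaze means are present, gaze_x_z / gaze_y_z.
    """
    out = []
    for sid, sub in trials.groupby("subject", sort=False):
        sub = sub.sort_values("trial") if "trial" in sub else sub.copy()
        d = sub.copy()
        try:
            d["pupil_z"] = _zscore(sub["baseline_pupil"])
        except ValueError:
            raise ValueError(f"subject {sid}: baseline_pupil has zero variance")
        try:
            d["log_rt_z"] = _zscore(np.log(sub["rt"]))
        except ValueError:
            raise ValueError(f"subject {sid}: rt has zero variance")
        d["acc"] = (sub["accuracy"] > 0.5).astype(float)
        d["prev_acc"] = d["acc"].shift(1)
        for g in ("gaze_x", "gaze_y"):
            if g in sub:
                try:
                    d[f"{g}_z"] = _zscore(sub[g])
                except ValueError:
                    raise ValueError(f"subject {sid}: {g} has zero variance")
        out.append(d)
    return pd.concat(out, ignore_index=True)


def _fit_logistic(y, X):
    """IRLS logistic fit; returns (betas, converged)."""
    import statsmodels.api as sm
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        beta = np.asarray(res.params)
        # separation shows up as non-convergence or exploding coefficients
        ok = bool(res.mle_retvals.get("converged", True)) and np.all(np.abs(beta) < 25)
        return beta, ok
    except Exception:
        return np.full(X.shape[1], np.nan), False


def _per_subject(trials, terms, fitter, outcome):
    rows = {}
    conv = {}
    for sid, sub in trials.groupby("subject", sort=False):
        X = np.column_stack([np.ones(len(sub))] +
                            [sub[t].to_numpy(float) for t in terms])
        y = sub[outcome].to_numpy(float)
        beta, ok = fitter(y, X)
        rows[sid] = beta[1:]
        conv[sid] = ok
    betas = pd.DataFrame(rows, index=terms).T
    converged = pd.Series(conv)
    tvals, pvals = {}, {}
    for t in terms:
        b = betas.loc[converged, t].to_numpy()
        if len(b) >= 2 and np.std(b) > 0:
            tt, pp = stats.ttest_1samp(b, 0.0)
        else:
            tt, pp = np.nan, np.nan
        tvals[t], pvals[t] = tt, pp
    return RegressionResult(terms, betas, converged,
                            pd.Series(tvals), pd.Series(pvals))


def fit_eq_accuracy(trials: pd.DataFrame) -> RegressionResult:
    """Per-subject logistic regression of accuracy on z-scored pupil.

    Subjects with separation (non-converged IRLS) are flagged and excluded
    from the group test.  The pupil coefficient is beta_acc.
    """
    d = trials if "pupil_z" in trials else prepare_predictors(trials)
    for sid, sub in d.groupby("subject"):
        if sub["acc"].nunique() < 2:
            raise ValueError(f"subject {sid}: only one outcome class present")
    return _per_subject(d, ["pupil_z"], _fit_logistic, "acc")


def _fit_ols(y, X):
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    return beta, True


def fit_eq_rt(trials: pd.DataFrame) -> RegressionResult:
    """Per-subject OLS of z-scored log RT on Acc, Pupil and Acc x Pupil.

    The interaction coefficient is beta_rt_x.
    """
    d = trials.copy() if "pupil_z" in trials else prepare_predictors(trials)
    d["acc_x_pupil"] = d["acc"] * d["pupil_z"]
    return _per_subject(d, ["acc", "pupil_z", "acc_x_pupil"], _fit_ols,
                        "log_rt_z")


def fit_expanded(trials: pd.DataFrame):
    """Expanded accuracy and RT models with previous-trial accuracy and
    baseline-window gaze position as covariates.

    First trials (undefined previous accuracy) are dropped here only.
    Returns (accuracy_result, rt_result).
    """
    d = trials.copy() if "pupil_z" in trials else prepare_predictors(trials)
    if "prev_acc" not in d:
        raise ValueError("previous-trial accuracy column missing")
    d = d[d["prev_acc"].notna()].copy()
    gaze_terms = [g for g in ("gaze_x_z", "gaze_y_z") if g in d]
    acc_terms = ["pupil_z", "prev_acc"] + gaze_terms
    res_acc = _per_subject(d, acc_terms, _fit_logistic, "acc")
    d["acc_x_pupil"] = d["acc"] * d["pupil_z"]
    rt_terms = ["acc", "pupil_z", "acc_x_pupil", "prev_acc"] + gaze_terms
    res_rt = _per_subject(d, rt_terms, _fit_ols, "log_rt_z")
    return res_acc, res_rt


def group_beta_test(betas, tail: str = "two"):
    """One-sample t-test of per-subject coefficients against zero."""
    b = np.asarray(betas, dtype=float)
    b = b[np.isfinite(b)]
    if len(b) < 2:
        raise ValueError("need >= 2 converged subjects")
    if b.std(ddof=1) == 0:
        raise ValueError("zero variance across subjects")
    t, p = stats.ttest_1samp(b, 0.0)
    if tail == "one":
        p = p / 2  # directional test in the observed direction
    elif tail != "two":
        raise ValueError("tail must be 'two' or 'one'")
    return float(t), float(p)


def behavioral_summary(trials: pd.DataFrame):
    """Per-subject mean correct/error RT and accuracy, plus the group
    paired t-test of correct vs error RT.

    Subjects without error trials are excluded from the paired test (their
    ids are reported in the result dict).
    """
    recs = []
    for sid, sub in trials.groupby("subject"):
        cor = sub[sub["accuracy"] > 0.5]["rt"]
        err = sub[sub["accuracy"] <= 0.5]["rt"]
        recs.append({"subject": sid, "accuracy": (sub["accuracy"] > 0.5).mean(),
                     "mean_rt_correct": cor.mean() if len(cor) else np.nan,
                     "mean_rt_error": err.mean() if len(err) else np.nan,
                     "n_correct": len(cor), "n_error": len(err)})
    table = pd.DataFrame.from_records(recs).set_index("subject")
    paired = table.dropna(subset=["mean_rt_correct", "mean_rt_error"])
    excluded = [s for s in table.index if s not in paired.index]
    if len(paired) >= 2:
        t, p = stats.ttest_rel(paired["mean_rt_error"], paired["mean_rt_correct"])
    else:
        t, p = np.nan, np.nan
    return {"table": table, "t": float(t), "p": float(p),
            "excluded_from_paired": excluded}


def rt_variability_by_bin(trials: pd.DataFrame):
    """Per-subject RT SD per (pupil bin x accuracy) and paired low-vs-high
    t-tests for correct and error trials separately.

    Cells with fewer than 2 trials are missing and drop pairwise.
    """
    recs = []
    for (sid, bname, acc), sub in trials.groupby(
            ["subject", "pupil_bin", trials["accuracy"] > 0.5]):
        if bname not in ("low", "high"):
            continue
        recs.append({"subject": sid, "pupil_bin": bname,
                     "correct": bool(acc),
                     "rt_sd": sub["rt"].std(ddof=1) if len(sub) >= 2 else np.nan})
    cells = pd.DataFrame.from_records(recs)
    out = {"cells": cells}
    for correct in (True, False):
        sub = cells[cells["correct"] == correct].pivot(
            index="subject", columns="pupil_bin", values="rt_sd").dropna()
        key = "correct" if correct else "error"
        if len(sub) >= 2 and {"low", "high"} <= set(sub.columns):
            t, p = stats.ttest_rel(sub["high"], sub["low"])
            out[key] = {"t": float(t), "p": float(p), "n": len(sub),
                        "mean_diff": float((sub["high"] - sub["low"]).mean())}
        else:
            out[key] = {"t": np.nan, "p": np.nan, "n": len(sub),
                        "mean_diff": np.nan}
    return out


def between_subject_correlations(x, y):
    """Pearson correlation across subjects with a two-tailed p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m = np.isfinite(x) & np.isfinite(y)
    if m.sum() < 3:
        raise ValueError("need >= 3 paired finite values")
    if x[m].std() == 0 or y[m].std() == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x[m], y[m])
    return float(r), float(p)
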
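"""Tests of the two-boundary and one-choice diffusion numerics."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import cumulative_trapezoid, quad

from pupilddm.ddm import (DDMParams, choice_probability, draw_subject_params,
                          fpt_density, mean_decision_time, simulate_one_choice,
                          simulate_trials)


class TestParams:
    @pytest.mark.parametrize("kw", [
        dict(a=-0.1), dict(z=0.2), dict(z=0.0), dict(eta=-0.01),
        dict(st=-0.1), dict(s=0.0), dict(t=0.01, st=0.1),
    ])
    def test_invalid_rejected(self, kw):
        base = dict(v=0.2, a=0.1, t=0.3)
        base.update(kw)
        with pytest.raises(ValueError):
            DDMParams(**base)

    def test_default_start_is_midpoint(self):
        assert DDMParams(v=0.2, a=0.1, t=0.3).z == pytest.approx(0.05)


class TestDensity:
    def test_reduces_to_plain_wiener_and_conserves_mass(self):
        p = DDMParams(v=0.2, a=0.1, t=0.3, eta=0.0, st=0.0)
        iu = quad(lambda t: fpt_density(t, "upper", p), p.t, 10, limit=200)[0]
        il = quad(lambda t: fpt_density(t, "lower", p), p.t, 10, limit=200)[0]
        assert iu + il == pytest.approx(1.0, abs=1e-6)
        assert iu == pytest.approx(choice_probability(p), abs=1e-6)

    def test_zero_before_nondecision_floor(self):
        p = DDMParams(v=0.2, a=0.1, t=0.3, st=0.1)
        assert fpt_density(0.24, "upper", p) == 0.0
        assert fpt_density(0.26, "upper", p) > 0.0

    def test_symmetry_zero_drift(self):
        p = DDMParams(v=0.0, a=0.1, t=0.3)
        rts = np.array([0.35, 0.5, 0.8, 1.5])
        np.testing.assert_allclose(fpt_density(rts, "upper", p),
                                   fpt_density(rts, "lower", p), rtol=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_mass_conservation_random_params(self, seed):
        r = np.random.default_rng(seed)
        p = DDMParams(v=r.uniform(-0.3, 0.4), a=r.uniform(0.06, 0.18),
                      t=r.uniform(0.2, 0.6), eta=r.uniform(0, 0.2),
                      st=r.uniform(0, 0.15))
        grid = np.linspace(p.t - p.st / 2, 15, 8000)
        total = (np.trapezoid(fpt_density(grid, "upper", p), grid)
                 + np.trapezoid(fpt_density(grid, "lower", p), grid))
        assert total == pytest.approx(1.0, abs=1e-5)

    def test_invalid_bound_name(self):
        with pytest.raises(ValueError):
            fpt_density(0.5, "top", DDMParams(v=0.2, a=0.1, t=0.3))


class TestChoiceProbability:
    def test_symmetric_start_zero_drift(self):
        assert choice_probability(DDMParams(v=0.0, a=0.1, t=0.3)) == pytest.approx(0.5)

    def test_closed_form_value(self):
        # 2*v*z/s^2 = 2, 2*v*a/s^2 = 4 -> (1-e^-2)/(1-e^-4) = 1/(1+e^-2)
        p = DDMParams(v=0.2, a=0.1, t=0.3, z=0.05)
        assert choice_probability(p) == pytest.approx(1 / (1 + np.exp(-2)), rel=1e-9)

    def test_reflection_symmetry(self):
        p1 = DDMParams(v=0.15, a=0.1, t=0.3, z=0.03, eta=0.1)
        p2 = DDMParams(v=-0.15, a=0.1, t=0.3, z=0.07, eta=0.1)
        assert choice_probability(p1) + choice_probability(p2) == pytest.approx(1.0, abs=1e-9)

    def test_study_scale_accuracy(self):
        # pooled fitted parameters land near the observed ~82% correct
        p = DDMParams(v=0.204, a=0.108, t=0.523, eta=0.145)
        assert 0.80 <= choice_probability(p) <= 0.85


class TestSimulator:
    def test_deterministic_limit_high_drift(self):
        rt, ch = simulate_trials(DDMParams(v=5.0, a=0.1, t=0.2), 2000, seed=3)
        assert np.all(ch == 1)

    def test_matches_choice_probability(self):
        p = DDMParams(v=0.15, a=0.12, t=0.3, eta=0.1, st=0.08)
        n = 100_000
        rt, ch = simulate_trials(p, n, seed=11)
        pu = choice_probability(p)
        se = np.sqrt(pu * (1 - pu) / n)
        assert abs((ch == 1).mean() - pu) < 3 * se

    def test_mean_decision_time_closed_form(self):
        p = DDMParams(v=0.2, a=0.1, t=0.0)
        # (a/2v) tanh(va/2s^2) = 0.1904 s
        assert mean_decision_time(p) == pytest.approx(
            (p.a / (2 * p.v)) * np.tanh(p.v * p.a / (2 * p.s ** 2)))
        rt, ch = simulate_trials(p, 100_000, seed=5)
        assert rt.mean() == pytest.approx(mean_decision_time(p), abs=0.002)

    def test_slow_errors_iff_drift_variability(self):
        # with z = a/2, eta > 0 produces slower errors than corrects;
        # eta = st = 0 leaves them equal in expectation
        n = 150_000
        p_eta = DDMParams(v=0.2, a=0.11, t=0.3, eta=0.18)
        rt, ch = simulate_trials(p_eta, n, seed=21)
        assert rt[ch == 0].mean() - rt[ch == 1].mean() > 0.01
        p0 = DDMParams(v=0.2, a=0.11, t=0.3)
        rt, ch = simulate_trials(p0, n, seed=22)
        assert abs(rt[ch == 0].mean() - rt[ch == 1].mean()) < 0.01

    def test_density_simulator_ks_agreement(self):
        # signed-RT (lower bound negated) KS between 1e5 simulated trials
        # and the defective distribution
        p = DDMParams(v=0.2, a=0.1, t=0.3, eta=0.12, st=0.08)
        d = ks_distance_signed(p, n=100_000, seed=9)
        assert d < 0.01


def ks_distance_signed(p, n, seed, dt=0.001):
    """KS distance between simulation and density on signed RTs
    (error RTs negated), covering both defective distributions at once."""
    rt, ch = simulate_trials(p, n, seed=seed, dt=dt)
    keep = ch >= 0
    x = np.where(ch[keep] == 1, rt[keep], -rt[keep])
    hi = max(rt.max() + 0.5, 5.0)
    grid = np.linspace(p.t - p.st / 2 - 1e-9, hi, 4000)
    fu = cumulative_trapezoid(fpt_density(grid, "upper", p), grid, initial=0)
    fl = cumulative_trapezoid(fpt_density(grid, "lower", p), grid, initial=0)
    pl = fl[-1]

    def cdf(xs):
        xs = np.asarray(xs)
        pos = np.interp(np.abs(xs), grid, fu) + pl
        neg = pl - np.interp(np.abs(xs), grid, fl)
        return np.clip(np.where(xs >= 0, pos, neg), 0, 1)

    return stats.kstest(x, cdf).statistic


def test_euler_step_size_converged():
    """Halving dt leaves the simulated RT distribution and choice fraction
    unchanged within Monte-Carlo error (bridge correction removes the
    leading-order discretization bias)."""
    p = DDMParams(v=0.2, a=0.108, t=0.3, eta=0.14, st=0.077)
    rt1, ch1 = simulate_trials(p, 60_000, seed=31, dt=0.001)
    rt2, ch2 = simulate_trials(p, 60_000, seed=32, dt=0.0005)
    assert abs((ch1 == 1).mean() - (ch2 == 1).mean()) < 0.006
    assert abs(rt1[ch1 == 1].mean() - rt2[ch2 == 1].mean()) < 0.004


class TestOneChoice:
    def test_wald_moments(self):
        v, a, t = 0.777, 0.136, 0.253
        rt = simulate_one_choice(v, a, t, n=200_000, seed=4)
        assert np.nanmean(rt) == pytest.approx(a / v + t, rel=0.01)
        assert np.nanvar(rt) == pytest.approx(a * 0.1 ** 2 / v ** 3, rel=0.05)

    def test_higher_eta_more_rt_variability(self):
        v, a, t, st = 0.777, 0.136, 0.253, 0.136
        lo = simulate_one_choice(v, a, t, eta=0.1, st=st, n=100_000, seed=6)
        hi = simulate_one_choice(v, a, t, eta=0.4, st=st, n=100_000, seed=6)
        assert np.nanstd(hi) > np.nanstd(lo)

    def test_negative_drift_censoring_honest(self):
        with pytest.warns(UserWarning):
            rt = simulate_one_choice(-0.5, 0.136, 0.0, n=5000, seed=8)
        # absorption probability exp(2*u*a/s^2) = exp(-13.6): essentially none
        assert np.isnan(rt).mean() > 0.99

    def test_rejects_bad_bound(self):
        with pytest.raises(ValueError):
            simulate_one_choice(0.5, -1.0, 0.2, n=10, seed=0)


class TestDrawSubjects:
    def test_zero_sd_reproduces_means(self):
        means = {"v": 0.2, "a": 0.1, "t": 0.4, "eta": 0.1, "st": 0.05}
        subs = draw_subject_params(means, {k: 0.0 for k in means}, 5, seed=1)
        assert len(subs) == 5
        for s in subs:
            assert s.v == pytest.approx(0.2) and s.a == pytest.approx(0.1)

    def test_sample_mean_converges(self):
        means = {"v": 0.2, "a": 0.1, "t": 0.4}
        sds = {"v": 0.03, "a": 0.015, "t": 0.06}
        subs = draw_subject_params(means, sds, 10_000, seed=2)
        assert np.mean([s.v for s in subs]) == pytest.approx(0.2, abs=0.002)
        assert np.mean([s.a for s in subs]) == pytest.approx(0.1, abs=0.001)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            draw_subject_params({"a": 0.1, "t": 0.3}, {"a": -1.0}, 3, seed=0)
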
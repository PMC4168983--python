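"""Tests of the hierarchical model: spec construction, convergence
diagnostics, effect distributions, determinism, prediction."""

import numpy as np
import pytest

from pupilddm.hier import (EffectDistribution, PosteriorSamples, build_model,
                           effect_distribution, posterior_predict, rhat,
                           sample_posterior, subject_delta_eta, _rhat_array)
from pupilddm.synthetic import gen_binned_dataset


@pytest.fixture(scope="module")
def tiny_fit():
    df = gen_binned_dataset(n_subjects=3, n_trials_per_bin=60, seed=21)
    post = sample_posterior(build_model("primary"), df, chains=2,
                            iterations=200, burnin=100, seed=5)
    return df, post


class TestBuildModel:
    def test_primary_structure(self):
        spec = build_model("primary")
        assert spec.bin_varying == frozenset({"a", "t", "v", "eta"})
        assert spec.eta_level == "subject"

    def test_group_eta_and_eta_only(self):
        assert build_model("group_eta").eta_level == "group_only"
        assert build_model("eta_only").bin_varying == frozenset({"eta"})

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            build_model("full_sz")


class TestRhat:
    def test_identical_chains_give_one(self):
        draws = np.tile(np.random.default_rng(0).normal(size=200), (3, 1))
        assert _rhat_array(draws) == pytest.approx(1.0, abs=0.01)

    def test_disjoint_chains_blow_up(self):
        rng = np.random.default_rng(1)
        draws = np.vstack([rng.normal(0, 0.1, 300), rng.normal(5, 0.1, 300)])
        # direct evaluation of the formula on the toy chains
        n = 300
        w = draws.var(axis=1, ddof=1).mean()
        b = n * draws.mean(axis=1).var(ddof=1)
        expected = np.sqrt(((n - 1) / n * w + b / n) / w)
        assert _rhat_array(draws) == pytest.approx(expected)
        assert _rhat_array(draws) > 5

    def test_single_chain_errors(self, tiny_fit):
        _, post = tiny_fit
        clipped = PosteriorSamples(
            spec=post.spec,
            group={k: v[:1] for k, v in post.group.items()},
            subject=post.subject, subjects=post.subjects)
        with pytest.raises(ValueError):
            rhat(clipped)

    def test_agrees_with_arviz(self, tiny_fit):
        az = pytest.importorskip("arviz")
        _, post = tiny_fit
        ours = _rhat_array(post.group["mu_v_low"])
        theirs = float(az.rhat(
            az.convert_to_dataset(post.group["mu_v_low"]))["x"])
        # conventions differ (split vs non-split); both should be near 1
        assert abs(ours - theirs) < 0.2


class TestEffectDistribution:
    def _with_draws(self, post, hi, lo):
        g = dict(post.group)
        g["mu_eta_high"] = np.asarray(hi, dtype=float).reshape(1, -1)
        g["mu_eta_low"] = np.asarray(lo, dtype=float).reshape(1, -1)
        return PosteriorSamples(spec=post.spec, group=g,
                                subject=post.subject, subjects=post.subjects)

    def test_counting(self, tiny_fit):
        _, post = tiny_fit
        s = self._with_draws(post, [0, 2, 3, 4], [1, 1, 1, 1])
        ed = effect_distribution(s, "eta")
        assert ed.p_above_zero == pytest.approx(0.75)

    def test_all_zero_ties_give_half(self, tiny_fit):
        _, post = tiny_fit
        s = self._with_draws(post, [1.0, 1.0], [1.0, 1.0])
        assert effect_distribution(s, "eta").p_above_zero == pytest.approx(0.5)

    def test_non_bin_varying_errors(self):
        df = gen_binned_dataset(n_subjects=3, n_trials_per_bin=40, seed=22)
        post = sample_posterior(build_model("eta_only"), df, chains=2,
                                iterations=60, burnin=30, seed=2)
        with pytest.raises(ValueError):
            effect_distribution(post, "a")


class TestSampler:
    def test_same_seed_identical_draws(self):
        df = gen_binned_dataset(n_subjects=2, n_trials_per_bin=40, seed=23)
        spec = build_model("primary")
        a = sample_posterior(spec, df, chains=2, iterations=80, burnin=40, seed=9)
        b = sample_posterior(spec, df, chains=2, iterations=80, burnin=40, seed=9)
        for k in a.group:
            np.testing.assert_array_equal(a.group[k], b.group[k])

    def test_pooled_draw_count(self, tiny_fit):
        _, post = tiny_fit
        assert post.pooled("mu_v_low").shape == (2 * 100,)

    def test_burnin_validation(self):
        df = gen_binned_dataset(n_subjects=2, n_trials_per_bin=30, seed=24)
        with pytest.raises(ValueError):
            sample_posterior(build_model("primary"), df, iterations=100,
                             burnin=100)

    def test_draws_respect_domains(self, tiny_fit):
        _, post = tiny_fit
        assert (post.pooled("mu_a_low") > 0).all()
        assert (post.pooled("mu_eta_low") >= 0).all()
        assert (post.pooled("sigma_v_low") > 0).all()


class TestSubjectDeltaEta:
    def test_constant_difference(self, tiny_fit):
        _, post = tiny_fit
        sub = dict(post.subject)
        e = np.array(post.subject["eta"], dtype=np.float32)
        e[:, :, 1, :] = e[:, :, 0, :] + 0.04
        sub["eta"] = e
        s = PosteriorSamples(spec=post.spec, group=post.group, subject=sub,
                             subjects=post.subjects)
        np.testing.assert_allclose(subject_delta_eta(s), 0.04, atol=1e-6)

    def test_group_only_variant_errors(self):
        df = gen_binned_dataset(n_subjects=2, n_trials_per_bin=40, seed=25)
        post = sample_posterior(build_model("group_eta"), df, chains=2,
                                iterations=60, burnin=30, seed=3)
        with pytest.raises(ValueError):
            subject_delta_eta(post)


class TestPriorPredictive:
    def test_prior_draws_yield_valid_data(self):
        """Sampling the hyperpriors and simulating produces datasets with
        finite trial likelihoods for nearly all draws."""
        from pupilddm.ddm import sample_exact
        from pupilddm import _wfpt
        from pupilddm.ddm import _GL_X, _GL_W, LIKELIHOOD_FLOOR
        rng = np.random.default_rng(77)
        ok = 0
        n_draws = 60
        for _ in range(n_draws):
            v = rng.normal(0.2, 0.5)
            a = abs(rng.normal(0.12, 0.1)) + 1e-3
            t = abs(rng.normal(0.4, 0.3)) + 1e-3
            eta = abs(rng.normal(0.15, 0.2))
            st = min(abs(rng.normal(0.1, 0.2)), 1.8 * t)
            from pupilddm.ddm import DDMParams
            try:
                p = DDMParams(v=v, a=a, t=t, eta=eta, st=st)
                rt, ch = sample_exact(p, 40, seed=int(rng.integers(2 ** 31)))
            except (ValueError, FloatingPointError):
                continue
            out = np.zeros(1)
            _wfpt.loglik_by_subject(rt, ch == 1, np.zeros(40, dtype=np.int64),
                                    np.array([v]), np.array([a]),
                                    np.array([t]), np.array([eta]),
                                    np.array([st]), 0.1, _GL_X, _GL_W,
                                    LIKELIHOOD_FLOOR, out)
            ok += np.isfinite(out[0])
        assert ok / n_draws >= 0.95


class TestVariantComparison:
    def test_group_eta_variant_narrower_effect(self):
        """Estimating eta only at the group level shrinks the uncertainty
        of the eta effect distribution relative to the primary model."""
        df = gen_binned_dataset(n_subjects=6, n_trials_per_bin=120, seed=31)
        kw = dict(chains=2, iterations=500, burnin=250, seed=6)
        post_p = sample_posterior(build_model("primary"), df, **kw)
        post_g = sample_posterior(build_model("group_eta"), df, **kw)
        sd_p = effect_distribution(post_p, "eta").draws.std()
        sd_g = effect_distribution(post_g, "eta").draws.std()
        assert sd_g < sd_p


class TestPosteriorPredict:
    def test_dataset_count_and_bounds(self, tiny_fit):
        df, post = tiny_fit
        pred = posterior_predict(post, n_datasets=20, seed=1)
        assert pred["accuracy"].shape == (20, 2)
        assert np.all(pred["accuracy"] >= 0) and np.all(pred["accuracy"] <= 1)
        # predictive accuracy should bracket the observed accuracy
        obs = df.groupby("pupil_bin")["accuracy"].mean()
        for b, bname in enumerate(("low", "high")):
            lo, hi = np.quantile(pred["accuracy"][:, b], [0.025, 0.975])
            assert lo - 0.1 < obs[bname] < hi + 0.1

    def test_too_many_datasets_errors(self, tiny_fit):
        _, post = tiny_fit
        with pytest.raises(ValueError):
            posterior_predict(post, n_datasets=10_000)
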
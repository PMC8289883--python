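"""Estimation tests: quadrature, EM behaviour, oracle equivalence, SEs."""


import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import ralisim as rl
from ralisim.estimation import CalibrationSpec, build_quadrature, marginal_loglik


def _simulate_form(design, timepoint, seed, anchor_count=9):
    rng = rl.substream_rng(seed, "est-fixture", timepoint)
    bank, anchor_sets = rl.restrict_anchors(
        rl.build_item_banks(design, rng), anchor_count
    )
    beta = rl.draw_abilities(design, timepoint, rng)
    resp = rl.simulate_responses(beta, bank.items_for_form(timepoint), rng, timepoint)
    return bank, anchor_sets, resp


class TestQuadrature:
    def test_gauss_hermite_is_a_probability_measure(self):
        _, w = build_quadrature("gauss_hermite", 41)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert (w > 0).all()

    def test_gauss_hermite_second_moment(self):
        nodes, w = build_quadrature("gauss_hermite", 41, mu=0.0, sigma=1.0)
        assert w @ nodes**2 == pytest.approx(1.0, abs=1e-8)

    def test_gauss_hermite_rescaling(self):
        nodes, w = build_quadrature("gauss_hermite", 41, mu=1.2, sigma=0.8)
        assert w @ nodes == pytest.approx(1.2, abs=1e-10)
        assert w @ (nodes - 1.2) ** 2 == pytest.approx(0.64, abs=1e-8)

    def test_qmc_nodes_track_the_latent_mean(self):
        nodes, w = build_quadrature("quasi_monte_carlo", 1000, mu=0.5, sigma=1.0)
        assert w.sum() == pytest.approx(1.0)
        assert np.all(np.isfinite(nodes))
        assert w @ nodes == pytest.approx(0.5, abs=0.01)

    def test_invalid_requests_rejected(self):
        with pytest.raises(rl.ConfigurationError):
            build_quadrature("trapezoid", 41)
        with pytest.raises(rl.ConfigurationError):
            build_quadrature("gauss_hermite", 1)


@pytest.fixture(scope="module")
def free_fit():
    design = rl.StudyDesign(sample_size=3000)
    bank, _, resp = _simulate_form(design, 1, seed=21)
    fit = rl.fit_mml_em(resp, CalibrationSpec())
    return bank, resp, fit


class TestFreeCalibration:
    def test_em_loglik_is_monotone(self, free_fit):
        _, _, fit = free_fit
        ll = np.asarray(fit.loglik_path)
        assert np.all(np.diff(ll) > -1e-8)

    def test_parameter_recovery(self, free_fit):
        bank, _, fit = free_fit
        truth = bank.items_for_form(1).set_index("global_id")["difficulty"]
        errors = np.array([fit.difficulties[i] - truth[i] for i in truth.index])
        assert np.mean(np.abs(errors)) < 0.10
        assert fit.sigma2 == pytest.approx(1.0, abs=0.08)
        assert fit.mu == 0.0  # identification
        assert fit.converged

    def test_translation_equivariant_data_generation(self):
        # shifting abilities and difficulties by a constant leaves the
        # response distribution, hence the fit, unchanged
        design = rl.StudyDesign(sample_size=400)
        rng = rl.substream_rng(9, "shift")
        bank = rl.build_item_banks(design, rng)
        items = bank.items_for_form(1)
        beta = rl.draw_abilities(design, 1, rl.substream_rng(9, "shift-b"))
        c = 0.8
        shifted = items.assign(difficulty=items["difficulty"] + c)
        r0 = rl.simulate_responses(beta, items, rl.substream_rng(9, "shift-r"))
        r1 = rl.simulate_responses(beta + c, shifted, rl.substream_rng(9, "shift-r"))
        f0 = rl.fit_mml_em(r0, CalibrationSpec())
        f1 = rl.fit_mml_em(r1, CalibrationSpec())
        d0 = np.array([f0.difficulties[i] for i in r0.items])
        d1 = np.array([f1.difficulties[i] for i in r1.items])
        np.testing.assert_allclose(np.diff(d0), np.diff(d1), atol=1e-12)
        assert f0.sigma2 == pytest.approx(f1.sigma2, abs=1e-12)

    def test_forced_nonconvergence_reports_finite_loglik(self, free_fit):
        _, resp, _ = free_fit
        fit = rl.fit_mml_em(resp, CalibrationSpec(max_iter=1))
        assert fit.converged is False
        assert np.isfinite(fit.loglik)

    def test_zero_variance_item_excluded_with_warning(self):
        design = rl.StudyDesign(sample_size=300)
        _, _, resp = _simulate_form(design, 1, seed=33)
        data = resp.data.copy()
        data[:, 0] = 1  # nobody misses the first item
        degenerate = rl.ResponseMatrix(items=resp.items, data=data)
        with pytest.warns(UserWarning, match="zero-variance"):
            fit = rl.fit_mml_em(degenerate, CalibrationSpec())
        assert resp.items[0] in fit.excluded
        assert resp.items[0] not in fit.difficulties

    def test_misfit_data_estimation_is_robust(self):
        design = rl.StudyDesign(sample_size=500, misfit=True)
        for rep in range(10):
            _, _, resp = _simulate_form(design, 2, seed=100 + rep)
            fit = rl.fit_mml_em(resp, CalibrationSpec())
            assert fit.converged

    def test_sufficiency_equal_scores_equal_eap(self, fitted_form):
        _, _, resp, fit = fitted_form
        eap = rl.eap_abilities(fit, resp)
        scores = resp.data.sum(axis=1)
        frame = pd.DataFrame({"score": scores, "eap": eap})
        assert (frame.groupby("score")["eap"].nunique() == 1).all()
        means = frame.groupby("score")["eap"].first()
        assert means.is_monotonic_increasing


class TestOracleEquivalence:
    @pytest.mark.parametrize("n_items", [2, 3])
    def test_em_matches_brute_force_optimum(self, n_items):
        """The EM solution maximizes the same quadrature marginal likelihood
        that a generic optimizer maximizes directly."""
        rng = rl.substream_rng(55, "oracle", n_items)
        # generous latent spread keeps the variance optimum interior (with
        # so few items a weakly associated sample can push sigma^2 to 0)
        beta = rng.normal(0.0, 1.5, size=200)
        deltas = np.linspace(-0.8, 0.8, n_items)
        items = pd.DataFrame(
            {"global_id": [f"i{j}" for j in range(n_items)],
             "difficulty": deltas, "discrimination": 1.0}
        )
        resp = rl.simulate_responses(beta, items, rng)
        fit = rl.fit_mml_em(
            resp, CalibrationSpec(tol=1e-9, loglik_tol=1e-14, max_iter=50000)
        )

        def negll(params):
            d, log_s = params[:-1], params[-1]
            return -marginal_loglik(resp, d, mu=0.0, sigma2=np.exp(2 * log_s))

        x0 = np.concatenate([np.zeros(n_items), [0.0]])
        res = optimize.minimize(negll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-7, "fatol": 1e-10,
                                         "maxiter": 20000})
        assert res.success
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-4)
        np.testing.assert_allclose(
            [fit.difficulties[f"i{j}"] for j in range(n_items)],
            res.x[:-1], atol=5e-3,
        )


class TestFixedAnchorCalibration:
    def test_requires_fixed_items(self):
        with pytest.raises(rl.ConfigurationError):
            CalibrationSpec(mode="fixed_anchor")

    def test_estimates_latent_mean_and_variance(self):
        design = rl.StudyDesign(sample_size=2000)
        bank, anchor_sets, resp = _simulate_form(design, 2, seed=61)
        truth = bank.items_for_form(2).set_index("global_id")["difficulty"]
        fixed = {i: float(truth[i]) for i in anchor_sets[1]}
        fit = rl.fit_mml_em(
            resp, CalibrationSpec(mode="fixed_anchor", fixed_items=fixed)
        )
        assert fit.converged
        # anchors were fixed at *true* values, so the latent mean comes back
        # on the generating scale
        assert fit.mu == pytest.approx(0.7, abs=0.1)
        assert fit.sigma2 == pytest.approx(1.0, abs=0.12)
        for gid, value in fixed.items():
            assert fit.difficulties[gid] == value
            assert fit.se[gid] == 0.0


class TestStandardErrors:
    def test_symmetric_items_have_matching_ses(self):
        rng = rl.substream_rng(71, "se-sym")
        beta = rng.normal(0, 1, size=4000)
        items = pd.DataFrame(
            {"global_id": ["a", "b"], "difficulty": [0.4, 0.4],
             "discrimination": 1.0}
        )
        resp = rl.simulate_responses(beta, items, rng)
        fit = rl.fit_mml_em(resp, CalibrationSpec())
        assert fit.se["a"] == pytest.approx(fit.se["b"], rel=0.15)

    def test_se_scales_with_inverse_root_n(self):
        ses = {}
        for n in (500, 2000):
            design = rl.StudyDesign(sample_size=n)
            _, _, resp = _simulate_form(design, 1, seed=83)
            fit = rl.fit_mml_em(resp, CalibrationSpec())
            ses[n] = np.mean(list(fit.se.values()))
        assert ses[500] / ses[2000] == pytest.approx(2.0, rel=0.15)

    def test_off_target_items_are_less_precise(self):
        rng = rl.substream_rng(97, "se-target")
        beta = rng.normal(0, 1, size=3000)
        items = pd.DataFrame(
            {"global_id": ["near", "far"], "difficulty": [0.0, 3.0],
             "discrimination": 1.0}
        )
        resp = rl.simulate_responses(beta, items, rng)
        fit = rl.fit_mml_em(resp, CalibrationSpec())
        assert fit.se["far"] > fit.se["near"]

    def test_public_recomputation_matches_fit(self, fitted_form):
        _, _, resp, fit = fitted_form
        recomputed = rl.estimate_item_ses(fit, resp)
        for gid, se in fit.se.items():
            assert recomputed[gid] == pytest.approx(se, rel=1e-6)


@pytest.fixture(scope="module")
def concurrent_fit():
    design = rl.StudyDesign(sample_size=1500)
    rng = rl.substream_rng(31, "cc")
    bank, anchor_sets = rl.restrict_anchors(rl.build_item_banks(design, rng), 9)
    responses = [
        rl.simulate_responses(
            rl.draw_abilities(design, t, rng), bank.items_for_form(t), rng, t
        )
        for t in range(1, 5)
    ]
    fit = rl.fit_concurrent(
        responses, CalibrationSpec(mode="concurrent", n_nodes=600)
    )
    return bank, responses, fit


class TestConcurrentCalibration:
    def test_anchor_difficulties_shared_across_forms(self, concurrent_fit):
        bank, responses, fit = concurrent_fit
        # a shared global id maps to exactly one estimate
        shared = set(responses[0].items) & set(responses[1].items)
        assert shared
        for gid in shared:
            assert gid in fit.difficulties

    def test_em_loglik_is_monotone(self, concurrent_fit):
        _, _, fit = concurrent_fit
        ll = np.asarray(fit.loglik_path)
        assert np.all(np.diff(ll) > -1e-6 * np.abs(ll[1:]))

    def test_growth_recovery_on_common_scale(self, concurrent_fit):
        _, _, fit = concurrent_fit
        assert fit.mu_by_form[1] == 0.0
        for t, truth in zip((2, 3, 4), (0.7, 1.2, 1.5)):
            assert fit.mu_by_form[t] == pytest.approx(truth, abs=0.12)
            assert fit.sigma2_by_form[t] == pytest.approx(1.0, abs=0.15)

    def test_disconnected_forms_rejected(self):
        rng = rl.substream_rng(13, "cc-disc")
        mk = lambda pre: rl.ResponseMatrix(
            items=[f"{pre}{j}" for j in range(3)],
            data=(rng.random((50, 3)) < 0.5).astype(int),
        )
        with pytest.raises(rl.ConfigurationError):
            rl.fit_concurrent([mk("x"), mk("y")], CalibrationSpec(mode="concurrent"))

    def test_forced_nonconvergence(self, concurrent_fit):
        _, responses, _ = concurrent_fit
        fit = rl.fit_concurrent(
            responses, CalibrationSpec(mode="concurrent", n_nodes=200, max_iter=1)
        )
        assert fit.converged is False
        assert np.isfinite(fit.loglik)
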
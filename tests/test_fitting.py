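"""Objective correctness, Monte Carlo search contracts, CG refinement."""

import numpy as np
import pytest

import pparclock as pc
from pparclock.fitting import (DEFAULT_BOUNDS, _FitProblem, _from_z, _to_z,
                               monte_carlo_search)
from pparclock.model import PARAM_NAMES
from conftest import make_curve

TIMES = [6.0, 10.0, 14.0, 18.0, 22.0, 2.0]


def small_cfg(**kw):
    base = dict(n_monte_carlo=200, seed=0)
    base.update(kw)
    return pc.FitConfig(**base)


@pytest.fixture(scope="module")
def truth_pair(bmal1_forcing, base_params):
    """Noiseless group-mean curve generated by the model itself, plus the
    generating parameters with X0 set to the limit-cycle 6 AM value."""
    traj = pc.periodic_solution(base_params, bmal1_forcing, tol=1e-9)
    p_true = base_params.replace(X0=float(traj.values[0]))
    wrapped = np.mod(traj.times, 24.0)
    means = [float(np.interp(t, traj.times, traj.values)) if t >= 6
             else float(traj.values[np.argmin(np.abs(wrapped - t))])
             for t in sorted(TIMES)]
    curve = make_curve(sorted(TIMES), means, sems=0.05 * np.asarray(means),
                       gene="PPARA")
    return curve, p_true


@pytest.fixture(scope="module")
def truth_curve(truth_pair):
    return truth_pair[0]


class TestObjective:
    def test_perfect_fit_rss_near_zero(self, truth_pair, bmal1_forcing):
        curve, p_true = truth_pair
        rss = pc.objective(p_true, curve, bmal1_forcing)
        assert rss < 1e-8

    def test_single_offset_point_unit_weight(self, bmal1_forcing, base_params):
        # flat forcing + equilibrium start: the model stays constant, so a
        # curve equal to that constant except one point off by 2 gives rss 4
        f = pc.cosinor_forcing(mesor=1.0, amplitude=0.0)
        x_star = pc.steady_state(base_params, 1.0)
        p = base_params.replace(X0=x_star)
        means = np.full(6, x_star)
        means[3] += 2.0
        curve = make_curve([6, 10, 14, 18, 22, 26], means)
        rss = pc.objective(p, curve, f)
        assert rss == pytest.approx(4.0, abs=1e-5)

    def test_matches_hand_looped_weighted_sum(self, truth_curve,
                                              bmal1_forcing):
        rng = np.random.default_rng(3)
        theta = np.array([0.05, 1.2, 0.9, 2.5, 0.2, 0.7, 0.2, 1.5])
        cfg = small_cfg(weight_by_sem=True)
        prob = _FitProblem(truth_curve, bmal1_forcing, cfg)
        pred = prob.predict_batch(theta.reshape(1, -1))[0]
        t, m, s, _ = truth_curve.unwrapped()
        expected = sum((1.0 / s[i] ** 2) * (pred[i] - m[i]) ** 2
                       for i in range(6))
        assert prob.rss(theta) == pytest.approx(expected, rel=1e-12)

    def test_fast_path_agrees_with_adaptive_integrator(self, bmal1_forcing,
                                                       base_params):
        """RK4 fitting kernel vs LSODA simulate on the observation grid."""
        cfg = small_cfg()
        curve = make_curve([6, 10, 14, 18, 22, 26], np.ones(6), gene="PPARA")
        prob = _FitProblem(curve, bmal1_forcing, cfg)
        pred = prob.predict_batch(base_params.to_array().reshape(1, -1))[0]
        traj = pc.simulate(base_params, bmal1_forcing,
                           np.array([6.0, 10, 14, 18, 22, 26]))
        np.testing.assert_allclose(pred, traj.values, atol=1e-7)


class TestMonteCarlo:
    def test_singleton_search(self, truth_curve, bmal1_forcing):
        thetas, rss = monte_carlo_search(truth_curve, bmal1_forcing,
                                         small_cfg(n_monte_carlo=1))
        assert thetas.shape == (1, 8) and rss.shape == (1,)

    def test_same_seed_identical_ranking(self, truth_curve, bmal1_forcing):
        a = monte_carlo_search(truth_curve, bmal1_forcing, small_cfg(seed=4))
        b = monte_carlo_search(truth_curve, bmal1_forcing, small_cfg(seed=4))
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_results_sorted_ascending(self, truth_curve, bmal1_forcing):
        _, rss = monte_carlo_search(truth_curve, bmal1_forcing, small_cfg())
        finite = rss[np.isfinite(rss)]
        assert np.all(np.diff(finite) >= 0)

    def test_best_draw_in_low_tail(self, truth_curve, bmal1_forcing):
        """With truth inside the bounds, the best of 10,000 draws sits far
        below the 1st percentile of the draw-rss distribution."""
        thetas, rss = monte_carlo_search(truth_curve, bmal1_forcing,
                                         small_cfg(n_monte_carlo=10_000))
        finite = rss[np.isfinite(rss)]
        assert finite[0] < np.percentile(finite, 1.0)

    def test_draws_respect_bounds(self, truth_curve, bmal1_forcing):
        cfg = small_cfg(n_monte_carlo=500)
        thetas, _ = monte_carlo_search(truth_curve, bmal1_forcing, cfg)
        for j, nm in enumerate(PARAM_NAMES):
            lo, hi = cfg.bounds[nm]
            assert thetas[:, j].min() >= lo and thetas[:, j].max() <= hi


class TestBoxTransform:
    def test_round_trip(self):
        cfg = small_cfg()
        theta = np.array([0.05, 1.0, 1.0, 2.0, 0.1, 0.5, 0.1, 1.0])
        np.testing.assert_allclose(_from_z(_to_z(theta, cfg), cfg), theta,
                                   rtol=1e-9)


class TestRefine:
    def test_stationary_at_truth_on_noiseless_curve(self, truth_pair,
                                                    bmal1_forcing):
        curve, p_true = truth_pair
        res = pc.refine(p_true, curve, bmal1_forcing, small_cfg())
        assert res.rss < 1e-7
        np.testing.assert_allclose(res.params.to_array(),
                                   p_true.to_array(), rtol=1e-3)

    def test_quadratic_seam_converges_to_minimum(self):
        """(v_p - 3)^2 injected through the objective seam; a tight ftol
        drives v_p to the known minimum."""
        cfg = small_cfg(ftol=1e-18, max_iter=2000)
        start = np.array([0.05, 1.0, 1.0, 2.0, 0.1, 0.5, 0.1, 1.0])

        def quad(thetas):
            return (thetas[:, 1] - 3.0) ** 2

        res = pc.refine(start, None, None, cfg, objective_fn=quad)
        assert res.params.v_p == pytest.approx(3.0, abs=1e-6)

    def test_perturbed_start_returns_to_truth(self, truth_pair,
                                              bmal1_forcing):
        curve, p_true = truth_pair
        start = p_true.replace(v_p=p_true.v_p * 1.2)
        res = pc.refine(start, curve, bmal1_forcing, small_cfg())
        assert abs(res.params.v_p - p_true.v_p) / p_true.v_p < 0.01

    def test_refined_rss_never_exceeds_start(self, truth_curve,
                                             bmal1_forcing):
        thetas, rss = monte_carlo_search(truth_curve, bmal1_forcing,
                                         small_cfg(seed=2))
        res = pc.refine(thetas[0], truth_curve, bmal1_forcing, small_cfg(seed=2))
        assert res.rss <= rss[0] + 1e-15


class TestFitGroup:
    def test_empty_group_raises(self, bmal1_forcing):
        ds = pc.synth_dataset(pc.cosinor_scenario("null", seed=0))
        with pytest.raises(pc.data_io.GeneLookupError):
            pc.fit_group(ds, "PPARA", "lean", "control", bmal1_forcing,
                         small_cfg())

    def test_determinism_end_to_end(self, ppar_dataset, bmal1_forcing):
        ds, _ = ppar_dataset
        cfg = small_cfg(n_monte_carlo=300, seed=9)
        a = pc.fit_group(ds, "PPARA", "lean", "HFD", bmal1_forcing, cfg)
        b = pc.fit_group(ds, "PPARA", "lean", "HFD", bmal1_forcing, cfg)
        np.testing.assert_array_equal(a.params.to_array(), b.params.to_array())
        assert a.rss == b.rss
        assert a.trace == b.trace

    def test_refinement_dominates_monte_carlo(self, ppar_dataset,
                                              bmal1_forcing):
        ds, _ = ppar_dataset
        cfg = small_cfg(n_monte_carlo=500, seed=1)
        res = pc.fit_group(ds, "PPARA", "obese", "HFD", bmal1_forcing, cfg)
        assert res.rss <= res.mc_best_rss

    def test_flat_kp_profile_flagged(self, bmal1_forcing):
        """With v_p ~ 0 the BMAL1 activation constant is inert, so the rss
        profile over K_p is flat and the fit is flagged weakly identified."""
        p = pc.PparModelParams(v0=0.3, v_p=1e-6, K_p=1.0, n=2.0, v_d=0.0,
                               K_d=0.5, delta_p=0.3, X0=1.0)
        ds, _ = pc.synth_ppar_groups(
            bmal1_forcing, {g: p for g in pc.GROUPS}, noise_cv=0.05, seed=0)
        bounds = dict(DEFAULT_BOUNDS)
        bounds["v_p"] = (1e-7, 1e-5)  # keep the synthesis term negligible
        cfg = small_cfg(n_monte_carlo=300, bounds=bounds)
        res = pc.fit_group(ds, "PPARA", "lean", "control", bmal1_forcing, cfg)
        assert "K_p" in res.weakly_identified
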
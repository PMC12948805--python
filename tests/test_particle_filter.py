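"""Particle-filter mechanics: initialization, weighting, SIR, the Gamma
lambda process, and collapse to the plain simulator."""

import numpy as np
import pandas as pd
import pytest

from dynqs import simulate as sim
from dynqs import particle_filter as pf
from dynqs.models import KineticParameters, ModelConstants, PlantState

C = ModelConstants()


def small_ensemble(n=64, seed=0, config=None):
    rng = np.random.default_rng(seed)
    cfg = config or pf.PFConfig(n_particles=n)
    return pf.init_particles(PlantState(0.05, 8.0, 0.5, 1.0),
                             pf.default_prior(), cfg, rng), cfg, rng


class TestInitParticles:
    def test_reference_initialization_contract(self):
        ens, cfg, _ = small_ensemble(n=500)
        assert np.all(ens.lam == 0.0)
        assert np.all(ens.qS <= ens.qS_max)
        assert np.all(ens.qS >= 0.0)
        assert ens.weights.sum() == pytest.approx(1.0)
        assert np.all(np.abs(ens.X / 0.05 - 1) <= 0.10 + 1e-12)
        assert np.all(np.abs(ens.S / 8.0 - 1) <= 0.10 + 1e-12)
        lo, hi = pf.PRIOR_BOUNDS["qS_max"]
        assert np.all((ens.qS_max >= lo) & (ens.qS_max <= hi))

    def test_invalid_nominal_state(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            pf.init_particles(PlantState(0.0, 8.0, 0.5, 1.0),
                              pf.default_prior(), pf.PFConfig(), rng)


class TestLikelihoodAndWeights:
    def test_log_density_at_mode(self):
        cfg = pf.PFConfig()
        assert pf.log_likelihood(1.0, 1.0, cfg) == pytest.approx(
            -0.5 * np.log(2 * np.pi * 0.2))

    def test_symmetry_and_exponent(self):
        cfg = pf.PFConfig()
        assert pf.log_likelihood(1.0, 2.0, cfg) == pf.log_likelihood(1.0, 0.0, cfg)
        # residual 1, sigma^2 = 0.2 -> quadratic exponent -2.5
        delta = pf.log_likelihood(1.0, 0.0, cfg) - pf.log_likelihood(0.0, 0.0, cfg)
        assert delta == pytest.approx(-2.5)

    def test_identical_particles_uniform_weights(self):
        ens, cfg, _ = small_ensemble()
        for name in ("X", "S", "qS", "V", "qS_max", "Y_XC"):
            arr = getattr(ens, name)
            arr[:] = arr[0]
        pf.update_weights(ens, 5.0, cfg)
        assert np.allclose(ens.weights, 1.0 / ens.n)

    def test_three_to_one_ratio(self):
        ens, cfg, _ = small_ensemble(n=2)
        # same Y_XC/qS, X chosen so CER residuals give likelihood ratio 3
        ens.Y_XC[:] = 0.62
        ens.qS_max[:] = 1.2
        ens.qS[:] = 1.0
        per_x = 1.0 / C.MW_S * (1 - 0.62) + C.m_c
        r1 = 0.1
        r2 = np.sqrt(r1 ** 2 + 2 * cfg.sigma2_cer * np.log(3.0))
        y = 5.0
        ens.X[0] = (y - r1) / per_x
        ens.X[1] = (y - r2) / per_x
        pf.update_weights(ens, y, cfg)
        assert ens.weights[0] == pytest.approx(0.75, rel=1e-12)
        assert ens.weights[1] == pytest.approx(0.25, rel=1e-12)

    def test_brute_force_oracle(self):
        ens, cfg, rng = small_ensemble(n=5)
        w_prior = rng.dirichlet(np.ones(5))
        ens.weights = w_prior.copy()
        y = 3.0
        pf.update_weights(ens, y, cfg)
        # independent brute-force: direct density formula, plain python
        dens = []
        for i in range(5):
            cer = ens.X[i] * (min(ens.qS[i], ens.qS_max[i]) / C.MW_S
                              * (1 - ens.Y_XC[i]) + C.m_c)
            dens.append(w_prior[i] * np.exp(-(y - cer) ** 2 / (2 * 0.2))
                        / np.sqrt(2 * np.pi * 0.2))
        dens = np.array(dens) / np.sum(dens)
        assert np.allclose(ens.weights, dens, atol=1e-12)

    def test_degenerate_update_resets_uniform(self):
        ens, cfg, _ = small_ensemble(n=4)
        ens.X[:] = np.inf  # non-finite predictions: every likelihood dies
        degenerated = pf.update_weights(ens, 1.0, cfg)
        assert degenerated
        assert np.allclose(ens.weights, 0.25)


class TestEffectiveSampleSize:
    @pytest.mark.parametrize("weights, expected", [
        (np.full(1000, 1e-3), 1000.0),
        (np.array([1.0, 0.0, 0.0]), 1.0),
        (np.array([0.5, 0.25, 0.25]), 1.0 / 0.375),
    ])
    def test_values(self, weights, expected):
        assert pf.effective_sample_size(weights) == pytest.approx(expected)


class TestResampling:
    def test_uniform_weights_preserve_multiset(self):
        ens, _, rng = small_ensemble(n=32)
        out = pf.resample_sir(ens, rng)
        assert np.array_equal(np.sort(out.qS_max), np.sort(ens.qS_max))
        assert np.allclose(out.weights, 1.0 / 32)

    def test_dominant_weight_takes_all(self):
        ens, _, rng = small_ensemble(n=16)
        ens.weights = np.zeros(16)
        ens.weights[7] = 1.0
        out = pf.resample_sir(ens, rng)
        assert np.all(out.qS_max == ens.qS_max[7])

    def test_ancestor_counts_match_expectation(self):
        rng = np.random.default_rng(3)
        w = rng.dirichlet(np.ones(50))
        idx = pf.systematic_indices(w, rng)
        counts = np.bincount(idx, minlength=50)
        assert np.all(np.abs(counts - 50 * w) <= 1.0 + 1e-12)


class TestLambdaIncrement:
    def test_zero_age_increment_is_degenerate(self):
        ens, cfg, rng = small_ensemble()
        lam_before = ens.lam.copy()
        pf.lambda_increment(ens, cfg, rng)  # phi == phi_last_draw == 0
        assert np.array_equal(ens.lam, lam_before)

    def test_gamma_mean_monte_carlo(self):
        """E[dlam] = alpha * dphi * beta, checked at 1e5 draws."""
        cfg = pf.PFConfig(n_particles=100000)
        rng = np.random.default_rng(11)
        ens = pf.init_particles(PlantState(0.05, 8.0, 0.5, 1.0),
                                pf.default_prior(), cfg, rng)
        dphi = 0.8
        ens.phi[:] = dphi
        pf.lambda_increment(ens, cfg, rng)
        expected = cfg.alpha * dphi * cfg.beta
        assert ens.lam.mean() == pytest.approx(expected, rel=0.02)
        # shape < 1: mass concentrates near zero (median < mean)
        assert np.median(ens.lam) < ens.lam.mean()
        assert np.all(ens.lam >= 0)
        assert np.array_equal(ens.phi_last_draw, ens.phi)

    def test_monotone_over_repeated_events(self):
        ens, cfg, rng = small_ensemble()
        history = [ens.lam.copy()]
        for k in range(5):
            ens.phi += 0.1
            pf.lambda_increment(ens, cfg, rng)
            assert np.all(ens.lam >= history[-1])
            history.append(ens.lam.copy())


class TestPropagate:
    def test_zero_growth_cell_age_is_maintenance_clock(self):
        """With mu = 0 the age integrand reduces to MW_X * m_c."""
        cfg = pf.PFConfig(n_particles=8, transition="monod")
        ens, _, rng = small_ensemble(n=8, config=cfg)
        q_star = C.m_c * C.MW_S / 0.62      # uptake balancing maintenance
        s_star = C.k_S * q_star / (1.2 - q_star)
        ens.Y_XC[:] = 0.62
        ens.qS_max[:] = 1.2
        ens.X[:] = 1e-8                      # negligible consumption
        ens.S[:] = s_star
        ens.V[:] = 1.0
        out = pf.propagate(ens, lambda t: 0.0, 0.0, 0.05, cfg)
        assert np.allclose(out.phi, C.MW_X * C.m_c * 0.05, rtol=1e-6)
        assert np.allclose(out.phi, 0.025960 * 0.05, rtol=1e-3)

    def test_zero_state_fixed_point(self):
        cfg = pf.PFConfig(n_particles=4)
        ens, _, _ = small_ensemble(n=4, config=cfg)
        ens.X[:] = 0.0
        ens.S[:] = 0.0
        ens.qS[:] = 0.0
        out = pf.propagate(ens, lambda t: 0.0, 0.0, 0.05, cfg)
        assert np.allclose(out.X, 0) and np.allclose(out.S, 0)
        assert np.allclose(out.qS, 0)

    def test_identical_particles_stay_identical(self):
        cfg = pf.PFConfig(n_particles=16)
        ens, _, _ = small_ensemble(n=16, config=cfg)
        for name in ("X", "S", "qS", "qS_max", "Y_XC", "lam"):
            getattr(ens, name)[:] = getattr(ens, name)[0]
        out = pf.propagate(ens, sim.reference_feed(), 1.0, 1.05, cfg)
        for name in ("X", "S", "qS", "phi"):
            assert np.ptp(getattr(out, name)) == 0.0

    def test_feasibility_clipping(self):
        cfg = pf.PFConfig(n_particles=8)
        ens, _, _ = small_ensemble(n=8, config=cfg)
        ens.S[:] = 1e-6  # at the edge of depletion
        out = pf.propagate(ens, lambda t: 0.0, 0.0, 0.05, cfg)
        assert np.all(out.S >= 0) and np.all(out.qS >= 0)
        assert np.all(out.qS <= out.qS_max + 1e-15)


class TestRunFilter:
    def test_collapses_to_simulator_with_point_prior(self):
        """No parameter/process noise, no spread, known lambda=0: the MMSE
        trajectory is the plain ODE solution of the dynamic model."""
        p = KineticParameters(1.05, 0.62)
        feed = sim.FeedProfile(u0=0.0, mu_set=0.0, t_start=0.0)
        act = sim.ActivationProfile(lambda_act=0.0, a=1.0, t_act=0.0)
        traj = sim.simulate_plant(PlantState(0.1, 8.0, 0.5, 1.0), p, feed,
                                  act, t_end=6.0)
        obs = traj.observations(0.05)
        cfg = pf.PFConfig(n_particles=50, init_spread=0.0,
                          lambda_updates=False, yxc_walk=False)
        res = pf.run_filter(obs, feed, PlantState(0.1, 8.0, 0.5, 1.0),
                            prior=pf.PointMassPrior(1.05, 0.62),
                            config=cfg, seed=0, qs0=0.5)
        X_ref = np.interp(res.t, traj.t, traj.X)
        qS_ref = np.interp(res.t, traj.t, traj.qS)
        assert np.max(np.abs(res.mmse["X"] - X_ref) / X_ref) < 1e-3
        assert np.max(np.abs(res.mmse["qS"] - qS_ref)) < 1e-3
        assert np.max(np.abs(res.residual_mean)) < 1e-2
        assert res.resample_events.size == 0

    def test_determinism(self, short_obs):
        feed = sim.reference_feed()
        x0 = sim.reference_initial_state()
        cfg = pf.PFConfig(n_particles=100)
        a = pf.run_filter(short_obs, feed, x0, config=cfg, seed=5)
        b = pf.run_filter(short_obs, feed, x0, config=cfg, seed=5)
        assert np.array_equal(a.mmse["lam"], b.mmse["lam"])
        assert np.array_equal(a.neff, b.neff)

    def test_weight_and_neff_bounds(self, pf_runs):
        for res in pf_runs[:3]:
            assert np.all(res.neff >= 1.0 - 1e-9)
            assert np.all(res.neff <= res.config.n_particles + 1e-9)
            # MMSE lies inside the ensemble range by construction
            assert (res.mmse["qS_max"] >= pf.PRIOR_BOUNDS["qS_max"][0]).all()
            assert (res.mmse["qS_max"] <= pf.PRIOR_BOUNDS["qS_max"][1]).all()

    def test_nonuniform_grid_rejected(self):
        obs = pd.DataFrame({"t": [0.0, 0.05, 0.2], "CER": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="uniform"):
            pf.run_filter(obs, lambda t: 0.0, sim.reference_initial_state(),
                          config=pf.PFConfig(n_particles=10), seed=0)

    def test_per_particle_age_nondecreasing(self):
        """phi accumulates a non-negative integrand for every particle,
        whatever the parameter draw (the ensemble MEAN may still dip when
        selection favours younger lineages)."""
        cfg = pf.PFConfig(n_particles=64)
        ens, _, _ = small_ensemble(n=64, config=cfg)
        for t0 in np.arange(0.0, 2.0, 0.05):
            nxt = pf.propagate(ens, sim.reference_feed(), t0, t0 + 0.05, cfg)
            assert np.all(nxt.phi >= ens.phi - 1e-15)
            ens = nxt
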
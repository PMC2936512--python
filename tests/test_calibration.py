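import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from canfat.calibration import (CaNFATCalibrator, MeanSimulator,
                                ObservationTable, ProfileGrid, SAConfig,
                                anneal, fit_abm, knockout_fit,
                                log_likelihood_from_means, lrt,
                                profile_ci, profile_variances,
                                restoration_experiment)
from canfat.mechanics import LoadingProtocol
from canfat.params import (AGED_MLE, PARAM_NAMES, YOUNG_MLE, ParameterVector,
                           bounds_array)
from canfat.synthetic import make_protocol_suite, simulate_observations, \
    SyntheticStudyConfig

from reference_engine import reference_loglik


def _obs(groups, means_strain=1700.0):
    rows = []
    for i, ys in enumerate(groups):
        for j, y in enumerate(ys):
            rows.append((f"p{i+1}", f"a{j+1}", means_strain, y))
    return ObservationTable(pd.DataFrame(
        rows, columns=["protocol_id", "animal_id", "peak_strain_ue", "rp_bfr"]))


class TestProfileVariances:
    def test_mean_square_residual(self):
        obs = _obs([[1.0, -1.0]])
        assert profile_variances(obs, {"p1": 0.0})["p1"] == 1.0

    def test_perfect_fit_hits_floor(self):
        obs = _obs([[2.0, 2.0, 2.0]])
        assert profile_variances(obs, {"p1": 2.0})["p1"] == 1e-8

    def test_shift_bias_identity(self):
        obs = _obs([[1.0, -1.0]])
        v0 = profile_variances(obs, {"p1": 0.0})["p1"]
        vc = profile_variances(obs, {"p1": 3.0})["p1"]
        assert vc == pytest.approx(v0 + 9.0)

    def test_single_animal_rejected(self):
        obs = _obs([[1.0]])
        with pytest.raises(ValueError, match="pooled"):
            profile_variances(obs, {"p1": 0.0})
        assert profile_variances(obs, {"p1": 0.0}, pooled=True)["p1"] == 1.0


class TestLogLikelihood:
    def test_two_animal_closed_form(self):
        obs = _obs([[1.0, -1.0]])
        ll = log_likelihood_from_means(obs, {"p1": 0.0})
        assert ll == pytest.approx(-math.log(2 * math.pi) - 1.0)

    def test_matches_reference_summation(self):
        groups = [[0.5, 1.5, 0.9], [2.0, 2.4]]
        obs = _obs(groups)
        mu = {"p1": 1.0, "p2": 2.1}
        assert log_likelihood_from_means(obs, mu) == pytest.approx(
            reference_loglik(groups, [1.0, 2.1]))

    def test_perfect_fit_floor_value(self):
        obs = _obs([[2.0, 2.0]])
        ll = log_likelihood_from_means(obs, {"p1": 2.0})
        v = 1e-8
        assert ll == pytest.approx(-math.log(2 * math.pi * v))

    def test_duplicate_protocol_additivity(self):
        obs1 = _obs([[1.0, -1.0]])
        obs2 = _obs([[1.0, -1.0], [1.0, -1.0]])
        ll1 = log_likelihood_from_means(obs1, {"p1": 0.0})
        ll2 = log_likelihood_from_means(obs2, {"p1": 0.0, "p2": 0.0})
        assert ll2 == pytest.approx(2 * ll1)


QUAD_OPT = np.array([2000.0, 20000.0, 50.0, 0.5, 5e6, 25.0])


def _quadratic(x):
    scale = bounds_array()[:, 1] - bounds_array()[:, 0]
    z = (x - QUAD_OPT) / scale
    return -200.0 * float(z @ z)


class TestAnnealer:
    def test_recovers_quadratic_optimum(self):
        cfg = SAConfig(n_restarts=3, steps_per_temp=60, cooling=0.9,
                       t_initial=5.0, t_min=1e-3, step_scale=0.15,
                       max_evals_per_restart=4000)
        res = anneal(_quadratic, bounds_array(), cfg, seed=1)
        scale = bounds_array()[:, 1] - bounds_array()[:, 0]
        assert np.all(np.abs(res.x - QUAD_OPT) / scale < 0.05)

    def test_determinism(self):
        cfg = SAConfig(n_restarts=2, max_evals_per_restart=200)
        r1 = anneal(_quadratic, bounds_array(), cfg, seed=7)
        r2 = anneal(_quadratic, bounds_array(), cfg, seed=7)
        assert np.array_equal(r1.x, r2.x) and r1.fun == r2.fun
        assert r1.n_evals == r2.n_evals

    def test_collapsed_bound_fixes_parameter(self):
        b = bounds_array()
        b[3] = (0.25, 0.25)
        res = anneal(_quadratic, b, SAConfig(n_restarts=1,
                                             max_evals_per_restart=300),
                     seed=0)
        assert res.x[3] == 0.25

    def test_warm_start_never_hurts(self):
        res = anneal(_quadratic, bounds_array(),
                     SAConfig(n_restarts=1, max_evals_per_restart=50),
                     seed=3, x0_list=[QUAD_OPT])
        assert res.fun >= _quadratic(QUAD_OPT)

    def test_trace_best_is_monotone(self):
        res = anneal(_quadratic, bounds_array(),
                     SAConfig(n_restarts=2, max_evals_per_restart=400),
                     seed=5)
        assert (res.trace["best"].diff().dropna() >= 0).all()

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            SAConfig(n_restarts=0)
        with pytest.raises(ValueError):
            SAConfig(cooling=1.5)


class TestLRT:
    def test_identical_likelihoods(self):
        t = lrt(-10.0, -10.0, df=1)
        assert t.statistic == 0.0 and t.p_value == 1.0

    @pytest.mark.parametrize("lam,df", [(3.8415, 1), (12.592, 6)])
    def test_chi_square_quantiles(self, lam, df):
        t = lrt(0.0, -lam / 2, df=df)
        assert t.p_value == pytest.approx(0.05, abs=1e-3)

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            lrt(-10.0, -5.0, df=1)


class TestProfileCI:
    def test_quadratic_ci_matches_analytic(self):
        # 1-D quadratic logL = -(x-mu)^2 / (2 se^2): CI = mu +/- 1.96 se
        mu, se = 2000.0, 150.0

        def obj(x):
            return -((x[0] - mu) ** 2) / (2 * se**2)

        bounds = np.array([[0.0, 5500.0]])
        # exact objective: no optimizer-noise margin needed
        grid = ProfileGrid(n_side=40, noise_margin=0.0)
        lo, hi = profile_ci(obj, np.array([mu]), 0.0, 0, bounds, 0.95, grid)
        z = stats.norm.ppf(0.975)
        assert lo == pytest.approx(mu - z * se, rel=0.05)
        assert hi == pytest.approx(mu + z * se, rel=0.05)

    def test_flat_profile_hits_bounds(self):
        def obj(x):
            return 0.0
        bounds = np.array([[0.0, 10.0]])
        lo, hi = profile_ci(obj, np.array([4.0]), 0.0, 0, bounds, 0.95)
        assert (lo, hi) == (0.0, 10.0)

    def test_level_zero_degenerate(self):
        def obj(x):
            return 0.0
        bounds = np.array([[0.0, 10.0]])
        assert profile_ci(obj, np.array([4.0]), 0.0, 0, bounds, 0.0) == (4.0, 4.0)


@pytest.fixture(scope="module")
def tiny_protocols():
    return make_protocol_suite(n_protocols=4, strain_range=(1200, 3000),
                               cycle_counts=(15, 30), rest_intervals=(0, 10))


@pytest.fixture(scope="module")
def tiny_obs(calib_network_mod, tiny_protocols):
    cfg = SyntheticStudyConfig(theta_star=YOUNG_MLE, n_animals=4, seed=5)
    return simulate_observations(YOUNG_MLE, tiny_protocols, calib_network_mod,
                                 cfg)


@pytest.fixture(scope="module")
def calib_network_mod():
    from canfat.network import CrossSectionGeometry, generate_network
    g = CrossSectionGeometry(outer_a=130, outer_b=100, inner_a=75,
                             inner_b=50, n_subsectors=32, n_surface_sectors=8)
    return generate_network(geometry=g, age_class="young", seed=11)


class TestModelFits:
    def test_lethal_knockouts_zero_means(self, calib_network_mod,
                                         tiny_protocols):
        sim = MeanSimulator(calib_network_mod, tiny_protocols)
        for name in ("er_capacity", "mar_max"):
            mu = sim.means(YOUNG_MLE.replace(**{name: 0.0}))
            assert all(v == 0.0 for v in mu.values())

    def test_unknown_knockout_param(self, calib_network_mod, tiny_protocols,
                                    tiny_obs):
        with pytest.raises(KeyError):
            knockout_fit(tiny_obs, calib_network_mod, tiny_protocols,
                         "not_a_param")

    def test_fit_determinism(self, calib_network_mod, tiny_protocols,
                             tiny_obs):
        cfg = SAConfig(n_restarts=1, max_evals_per_restart=40)
        f1 = fit_abm(tiny_obs, calib_network_mod, tiny_protocols,
                     sa_config=cfg, seed=3)
        f2 = fit_abm(tiny_obs, calib_network_mod, tiny_protocols,
                     sa_config=cfg, seed=3)
        assert f1.theta == f2.theta and f1.loglik == f2.loglik

    def test_knockout_never_beats_full_fit(self, calib_network_mod,
                                           tiny_protocols, tiny_obs):
        cfg = SAConfig(n_restarts=1, max_evals_per_restart=60)
        full = fit_abm(tiny_obs, calib_network_mod, tiny_protocols,
                       sa_config=cfg, seed=3,
                       x0_list=[YOUNG_MLE.to_array()])
        ko = knockout_fit(tiny_obs, calib_network_mod, tiny_protocols,
                          "er_capacity", sa_config=cfg, seed=3)
        assert ko.loglik <= full.loglik + 1e-6

    def test_estimator_interface(self, calib_network_mod, tiny_protocols,
                                 tiny_obs):
        est = CaNFATCalibrator(network=calib_network_mod,
                               protocols=tiny_protocols,
                               sa_config=SAConfig(n_restarts=1,
                                                  max_evals_per_restart=30),
                               seed=2)
        est.fit(tiny_obs.frame)
        assert hasattr(est, "theta_") and np.isfinite(est.loglik_)
        mu = est.predict()
        assert mu.shape == (len(tiny_protocols),)
        assert est.score(tiny_obs.frame) == pytest.approx(est.loglik_)
        # sklearn param plumbing
        assert est.get_params()["seed"] == 2
        est.set_params(seed=5)
        assert est.seed == 5


class TestRestoration:
    def test_empty_restore_set_is_identity(self, calib_network_mod,
                                           tiny_protocols):
        rep = restoration_experiment(AGED_MLE, YOUNG_MLE, set(),
                                     calib_network_mod, tiny_protocols)
        vals = [v for v in rep["percent_change"].values() if v is not None]
        assert all(v == 0.0 for v in vals)

    def test_full_restore_equals_young(self, calib_network_mod,
                                       tiny_protocols):
        rep = restoration_experiment(AGED_MLE, YOUNG_MLE, set(PARAM_NAMES),
                                     calib_network_mod, tiny_protocols)
        sim = MeanSimulator(calib_network_mod, tiny_protocols)
        mu_young = sim.means(YOUNG_MLE)
        for pid, v in rep["mu_restored"].items():
            assert v == pytest.approx(mu_young[pid])

    def test_zero_baseline_reported_absent(self, calib_network_mod,
                                           tiny_protocols):
        dead = AGED_MLE.replace(er_capacity=0.0)
        rep = restoration_experiment(dead, YOUNG_MLE, {"nfat_memory"},
                                     calib_network_mod, tiny_protocols)
        assert all(v is None for v in rep["percent_change"].values())
        assert rep["mean"] is None
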
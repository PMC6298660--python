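import numpy as np
import pytest

from ministep.data_model import BehaviorScale, Wave, WavePanel
from ministep.effects import Effect, EffectSpec
from ministep.engine import ParameterVector, SaomModel
from ministep.estimation import (
    EstimationOptions,
    EstimationResult,
    estimate,
    impute_behavior,
    similarity_centering,
    simulate_statistics,
    target_statistics,
    wald_tests,
)

from conftest import random_graph


def panel_from_states(states):
    """Build a fully observed panel from a list of (adjacency, behavior)."""
    n = states[0][0].shape[0]
    part = np.ones(n, dtype=bool)
    waves = [Wave(x.astype(np.int8), z.astype(float), part.copy()) for x, z in states]
    return WavePanel([f"a{i}" for i in range(n)], waves)


class TestImputation:
    def test_carry_forward_then_backward(self):
        x = np.zeros((2, 2), dtype=np.int8)
        waves = [
            Wave(x.copy(), np.array([np.nan, 4.0]), np.array([False, True])),
            Wave(x.copy(), np.array([3.0, np.nan]), np.array([True, False])),
            Wave(x.copy(), np.array([5.0, 6.0]), np.array([True, True])),
        ]
        panel = WavePanel(["A", "B"], waves)
        codes, imputed = impute_behavior(panel)
        assert codes[0].tolist() == [3.0, 3.0, 5.0]  # backward fill at wave 1
        assert codes[1].tolist() == [4.0, 4.0, 6.0]  # forward fill at wave 2
        assert imputed[0].tolist() == [True, False, False]


class TestTargets:
    def _model(self, spec=None):
        spec = spec or EffectSpec([
            Effect("network", "outdegree"), Effect("network", "reciprocity"),
            Effect("behavior", "linear_shape")])
        return SaomModel(spec, BehaviorScale(11, 5.0, 10.0), sim_c=0.0)

    def test_identical_waves_zero_rate_targets(self):
        x = np.array([[0, 1], [0, 0]], dtype=np.int8)
        z = np.array([4.0, 6.0])
        panel = panel_from_states([(x, z), (x, z)])
        model = self._model()
        targets = target_statistics(panel, model)
        assert targets[0] == 0.0 and targets[1] == 0.0

    def test_single_tie_gain_rate_one(self):
        x0 = np.zeros((2, 2), dtype=np.int8)
        x1 = np.array([[0, 1], [0, 0]], dtype=np.int8)
        z = np.array([4.0, 6.0])
        panel = panel_from_states([(x0, z), (x1, z)])
        targets = target_statistics(panel, self._model())
        assert targets[0] == 1.0

    def test_reciprocity_target_matches_hand_count(self):
        # wave 2: mutual dyad (0,1) plus tie 2->0
        x0 = np.zeros((3, 3), dtype=np.int8)
        x1 = np.zeros((3, 3), dtype=np.int8)
        x1[0, 1] = x1[1, 0] = x1[2, 0] = 1
        z = np.array([4.0, 5.0, 6.0])
        panel = panel_from_states([(x0, z), (x1, z)])
        targets = target_statistics(panel, self._model())
        # labels: [net_rate, beh_rate, outdegree, reciprocity, linear]
        assert targets[2] == 3.0   # sum of out-degrees at wave 2
        assert targets[3] == 2.0   # each member of the mutual dyad counts 1
        assert targets[4] == (4.0 - 5.0) + (5.0 - 5.0) + (6.0 - 5.0)

    def test_behavior_rate_counts_absolute_change(self):
        x = np.zeros((3, 3), dtype=np.int8)
        panel = panel_from_states([
            (x, np.array([4.0, 5.0, 6.0])), (x, np.array([6.0, 5.0, 5.0]))])
        targets = target_statistics(panel, self._model())
        assert targets[1] == 3.0  # |+2| + 0 + |-1|


class TestSimilarityCentering:
    def test_two_actor_value(self):
        x = np.zeros((2, 2), dtype=np.int8)
        panel = panel_from_states([
            (x, np.array([4.0, 6.0])), (x, np.array([4.0, 6.0]))])
        # |4-6|/10 -> sim 0.8 for both ordered pairs at both waves
        assert similarity_centering(panel, 10.0) == pytest.approx(0.8)


class TestMomentCondition:
    def test_simulated_moments_match_targets_at_truth(self, small_model, simulated_panel):
        """At the data-generating parameters, expected simulated statistics
        sit within Monte Carlo range of the observed targets."""
        panel, theta = simulated_panel
        targets = target_statistics(panel, small_model)
        rng = np.random.default_rng(3)
        sims = np.array([
            simulate_statistics(panel, small_model, theta, rng)[0]
            for _ in range(150)])
        mean, sd = sims.mean(0), sims.std(0, ddof=1)
        # one panel realization: its statistics are a single draw from the
        # simulated distribution, so deviations of a few sd are expected
        assert np.all(np.abs(mean - targets) < 4.0 * sd)


class TestEstimate:
    def test_recovers_network_parameters(self, rng):
        """Data simulated from known structural parameters are recovered
        within three reported standard errors."""
        n = 30
        spec = EffectSpec([Effect("network", "outdegree"),
                           Effect("network", "reciprocity")])
        model = SaomModel(spec, BehaviorScale(11, 6.0, 10.0), sim_c=0.0)
        theta_true = ParameterVector([3.0, 3.0], [0.5, 0.5], [-2.0, 1.5], [])
        x0 = random_graph(rng, n, 0.1)
        z0 = rng.integers(4, 9, size=n).astype(float)
        panel = model.simulate_panel(x0, z0, theta_true, 2, rng)
        options = EstimationOptions(n_subphases=3, n2start=25, n3=200)
        result = estimate(panel, model, options=options, seed=11)
        err = np.abs(result.theta_hat.as_array() - theta_true.as_array())
        assert np.all(err <= 3.0 * result.se)
        assert np.all(np.abs(result.t_conv) < 0.2)

    def test_behavior_rate_moment_equation(self, rng):
        """With a flat behavior objective the rate estimate solves the
        moment equation: simulating at theta-hat reproduces the observed
        total |category change| within Monte Carlo error."""
        n = 25
        spec = EffectSpec([Effect("network", "outdegree")])
        model = SaomModel(spec, BehaviorScale(11, 6.0, 10.0), sim_c=0.0)
        theta_true = ParameterVector([1.0], [1.2], [-2.5], [])
        x0 = random_graph(rng, n, 0.1)
        z0 = rng.integers(3, 10, size=n).astype(float)
        panel = model.simulate_panel(x0, z0, theta_true, 1, rng)
        options = EstimationOptions(n_subphases=3, n2start=25, n3=300)
        result = estimate(panel, model, options=options, seed=13)
        targets = target_statistics(panel, model)
        k = 1  # behavior rate statistic
        sims = np.array([
            simulate_statistics(panel, model, result.theta_hat,
                                np.random.default_rng(1000 + r))[0][k]
            for r in range(200)])
        se_mc = sims.std(ddof=1) / np.sqrt(len(sims))
        assert abs(sims.mean() - targets[k]) < max(4.0 * se_mc, 0.05 * max(targets[k], 1))

    def test_bitwise_reproducible_given_seed(self, simulated_panel, small_model):
        panel, _ = simulated_panel
        options = EstimationOptions(n_subphases=1, n2start=5, n3=20)
        with pytest.warns(UserWarning):
            a = estimate(panel, small_model, options=options, seed=21)
        with pytest.warns(UserWarning):
            b = estimate(panel, small_model, options=options, seed=21)
        assert np.array_equal(a.theta_hat.as_array(), b.theta_hat.as_array())
        assert np.array_equal(a.se, b.se)

    def test_covariance_symmetric_psd(self, simulated_panel, small_model):
        panel, theta = simulated_panel
        options = EstimationOptions(n_subphases=2, n2start=10, n3=100)
        result = estimate(panel, small_model, options=options, seed=31,
                          theta0=theta)
        cov = result.covariance
        assert np.allclose(cov, cov.T, atol=1e-8)
        assert np.linalg.eigvalsh(cov).min() > -1e-8
        assert np.all(result.se >= 0)


class TestWald:
    def _result(self, est, se):
        est, se = np.asarray(est, float), np.asarray(se, float)
        theta = ParameterVector([1.0], [1.0], est, [])
        full_se = np.concatenate([[0.1, 0.1], se])
        return EstimationResult(
            theta_hat=theta, labels=["r1", "r2", "b1", "b2"][: 2 + len(est)],
            se=full_se, covariance=np.diag(full_se ** 2),
            t_conv=np.zeros(full_se.size), overall_conv=0.0,
            p_values=np.zeros(full_se.size), targets=np.zeros(full_se.size),
            sim_mean=np.zeros(full_se.size), n_phase3=0, seed=0, converged=True)

    def test_published_coefficient_z_and_p(self):
        out = wald_tests(self._result([0.441], [0.098]))
        assert out["z"][2] == pytest.approx(4.5, abs=0.1)
        assert out["p"][2] < 0.001

    def test_marginal_coefficient(self):
        out = wald_tests(self._result([0.041], [0.022]))
        assert out["p"][2] == pytest.approx(0.062, abs=0.005)

    def test_zero_estimate_gives_p_one(self):
        out = wald_tests(self._result([0.0], [0.5]))
        assert out["p"][2] == pytest.approx(1.0)

    def test_zero_se_reported_undefined(self):
        with pytest.warns(UserWarning, match="zero standard error"):
            out = wald_tests(self._result([0.3], [0.0]))
        assert np.isnan(out["z"][2])
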
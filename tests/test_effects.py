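import numpy as np
import pytest

from ministep.effects import (
    BEHAVIOR_EFFECTS,
    Effect,
    EffectSpec,
    NETWORK_EFFECTS,
    behavior_change_statistic,
    behavior_statistic,
    network_change_statistics,
    network_statistic,
    objective,
    standard_spec,
)

COVARIATE_EFFECTS = [n for n, needs in NETWORK_EFFECTS.items() if needs]
STRUCTURAL_EFFECTS = [n for n, needs in NETWORK_EFFECTS.items() if not needs]


def graph(n, ties):
    x = np.zeros((n, n), dtype=np.int8)
    for i, j in ties:
        x[i, j] = 1
    return x


class TestNetworkStatistics:
    def test_reciprocity_and_degree_example(self):
        # ties 1->2, 2->1, 1->3 (0-indexed: 0->1, 1->0, 0->2)
        x = graph(3, [(0, 1), (1, 0), (0, 2)])
        assert network_statistic("reciprocity", x, 0) == 1
        assert network_statistic("outdegree", x, 0) == 2
        assert network_statistic("outdegree_activity", x, 0) == 4
        assert network_statistic("indegree_activity", x, 0) == 2  # outdeg 2 x indeg 1

    def test_transitive_triplet_enumeration(self):
        # 1->2, 2->3, 1->3: actor 1 closes the two-path 1->2->3 with 1->3
        x = graph(3, [(0, 1), (1, 2), (0, 2)])
        assert network_statistic("transitive_triplets", x, 0) == 1
        assert network_statistic("transitive_triplets", x, 1) == 0

    def test_complete_graph_transitive_closed_form(self):
        for n in (3, 4, 5, 6):
            x = np.ones((n, n), dtype=np.int8)
            np.fill_diagonal(x, 0)
            assert network_statistic("transitive_triplets", x, 0) == (n - 1) * (n - 2)

    def test_covariate_sums(self):
        x = graph(3, [(0, 1), (0, 2)])
        v = np.array([0.25, 0.5, -1.5])
        assert network_statistic("alter", x, 0, v) == pytest.approx(-1.0)
        assert network_statistic("alter_squared", x, 0, v) == pytest.approx(2.5)
        assert network_statistic("ego_x_alter", x, 0, v) == pytest.approx(0.25 * -1.0)
        same = np.array(["a", "b", "a"])
        assert network_statistic("same", x, 0, same) == 1

    def test_count_statistics_nonnegative_integers(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 7))
            x = (rng.random((n, n)) < 0.5).astype(np.int8)
            np.fill_diagonal(x, 0)
            for name in STRUCTURAL_EFFECTS:
                for i in range(n):
                    s = network_statistic(name, x, i)
                    assert s >= 0 and s == int(s)

    def test_unknown_name_and_missing_covariate(self):
        x = graph(2, [])
        with pytest.raises(ValueError):
            network_statistic("popularity_sqrt", x, 0)
        with pytest.raises(ValueError):
            network_statistic("alter", x, 0, None)


class TestBehaviorStatistics:
    def test_shape_terms(self):
        z = np.array([2.0, -1.0])
        x = np.zeros((2, 2), dtype=np.int8)
        assert behavior_statistic("linear_shape", z, x, 0, 10.0) == 2.0
        assert behavior_statistic("quadratic_shape", z, x, 0, 10.0) == 4.0

    def test_average_similarity_example(self):
        # ego at 0 with friends at +1 and -1, range 10, sim_c 0
        z = np.array([0.0, 1.0, -1.0])
        x = graph(3, [(0, 1), (0, 2)])
        assert behavior_statistic("average_similarity", z, x, 0, 10.0) == pytest.approx(0.9)

    def test_isolate_similarity_is_zero(self):
        z = np.array([0.0, 5.0])
        x = np.zeros((2, 2), dtype=np.int8)
        assert behavior_statistic("average_similarity", z, x, 0, 10.0) == 0.0

    def test_similarity_bounded(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 7))
            x = (rng.random((n, n)) < 0.5).astype(np.int8)
            np.fill_diagonal(x, 0)
            z = rng.uniform(-5.25, 4.75, size=n)
            sim_c = rng.uniform(0, 1)
            s = behavior_statistic("average_similarity", z, x, 0, 10.0, sim_c)
            assert -1.0 <= s <= 1.0

    def test_missing_behavior_rejected(self):
        z = np.array([np.nan, 1.0])
        with pytest.raises(ValueError):
            behavior_statistic("linear_shape", z, np.zeros((2, 2), dtype=np.int8), 0, 10.0)


class TestObjective:
    def test_zero_coefficients_give_zero(self, rng):
        spec = standard_spec()
        n = 8
        x = (rng.random((n, n)) < 0.3).astype(np.int8)
        np.fill_diagonal(x, 0)
        z = rng.uniform(-5, 5, size=n)
        val = objective("network", spec, np.zeros(len(spec.network_effects)), 0, x, z)
        assert val == 0.0

    def test_single_effect_arithmetic(self):
        spec = EffectSpec([Effect("network", "outdegree")])
        x = graph(4, [(0, 1), (0, 2), (0, 3)])
        assert objective("network", spec, [-2.341], 0, x) == pytest.approx(-7.023)

    def test_order_permutation_invariance(self, rng):
        e1 = [Effect("network", "outdegree"), Effect("network", "reciprocity")]
        x = (rng.random((5, 5)) < 0.5).astype(np.int8)
        np.fill_diagonal(x, 0)
        beta = [0.7, -1.2]
        a = objective("network", EffectSpec(e1), beta, 1, x)
        b = objective("network", EffectSpec(e1[::-1]), beta[::-1], 1, x)
        assert a == pytest.approx(b)

    def test_length_mismatch_rejected(self):
        spec = EffectSpec([Effect("network", "outdegree")])
        with pytest.raises(ValueError):
            objective("network", spec, [1.0, 2.0], 0, graph(2, []))


class TestChangeStatistics:
    def test_toggle_on_empty_graph(self):
        x = np.zeros((3, 3), dtype=np.int8)
        d_out = network_change_statistics("outdegree", x, 0)
        d_rec = network_change_statistics("reciprocity", x, 0)
        assert d_out[1] == 1 and d_rec[1] == 0

    def test_matches_full_recompute_all_effects(self, rng):
        """Exhaustive agreement of vectorized deltas with recomputation on
        random graphs of up to 6 actors, for every effect and toggle."""
        for _ in range(60):
            n = int(rng.integers(2, 7))
            x = (rng.random((n, n)) < rng.uniform(0.1, 0.7)).astype(np.int8)
            np.fill_diagonal(x, 0)
            v_num = rng.normal(size=n)
            v_cat = rng.integers(0, 3, size=n)
            for name in NETWORK_EFFECTS:
                v = (v_cat if name == "same"
                     else v_num if NETWORK_EFFECTS[name] else None)
                for i in range(n):
                    delta = network_change_statistics(name, x, i, v)
                    assert delta[i] == 0.0
                    for a in range(n):
                        if a == i:
                            continue
                        x2 = x.copy()
                        x2[i, a] = 1 - x2[i, a]
                        full = (network_statistic(name, x2, i, v)
                                - network_statistic(name, x, i, v))
                        assert delta[a] == pytest.approx(full, abs=1e-9)

    def test_behavior_step_matches_recompute(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 7))
            x = (rng.random((n, n)) < 0.5).astype(np.int8)
            np.fill_diagonal(x, 0)
            z = rng.integers(2, 10, size=n).astype(float) - 6.0
            for name in BEHAVIOR_EFFECTS:
                for i in range(n):
                    for step in (-1, 1):
                        d = behavior_change_statistic(name, z, x, i, step, 10.0, 0.3)
                        z2 = z.copy()
                        z2[i] += step
                        full = (behavior_statistic(name, z2, x, i, 10.0, 0.3)
                                - behavior_statistic(name, z, x, i, 10.0, 0.3))
                        assert d == pytest.approx(full, abs=1e-12)

    def test_step_up_toward_friends(self):
        # ego below all friends: similarity gains 1/range per friend on average
        z = np.array([0.0, 1.0, 1.0])
        x = graph(3, [(0, 1), (0, 2)])
        d = behavior_change_statistic("average_similarity", z, x, 0, 1, 10.0)
        assert d == pytest.approx(0.1)


class TestEffectSpec:
    def test_yaml_round_trip(self, tmp_path):
        spec = standard_spec(demographics=True)
        path = tmp_path / "effects.yaml"
        spec.to_yaml(path)
        back = EffectSpec.from_yaml(path)
        assert back.effects == spec.effects

    def test_validation(self):
        with pytest.raises(ValueError):
            Effect("network", "no_such_effect")
        with pytest.raises(ValueError):
            Effect("network", "alter")  # covariate required
        with pytest.raises(ValueError):
            Effect("behavior", "average_similarity", covariate="bmi")

    def test_order_fixes_coefficient_order(self):
        spec = standard_spec()
        assert spec.labels("network")[0] == "outdegree"
        assert spec.labels("behavior") == [
            "linear_shape", "quadratic_shape", "average_similarity"]
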
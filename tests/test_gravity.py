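import numpy as np
import pandas as pd
import pytest

import settleflow as sf
from settleflow.gravity import read_flows, write_flows

from conftest import naive_gravity


def dist_matrix(ids, values):
    return sf.DistanceMatrix(np.asarray(ids), np.asarray(values, dtype=float),
                             kind="euclidean")


class TestDecay:
    def test_power_unit_distance_is_one(self):
        for beta in (0.5, 1.0, 3.0):
            assert sf.decay(1.0, beta, "power") == pytest.approx(1.0)

    def test_exponential_zero_beta_is_one(self):
        assert sf.decay(123.0, 0.0, "exponential") == pytest.approx(1.0)

    def test_exponential_halving_distance(self):
        assert sf.decay(np.log(2), 1.0, "exponential") == pytest.approx(0.5)

    def test_power_zero_distance_error(self):
        with pytest.raises(sf.ValidationError):
            sf.decay(0.0, 1.0, "power")


class TestNormaliseK:
    def test_two_settlement_hand_value(self):
        d = dist_matrix(["A", "B"], [[0, 1], [1, 0]])
        params = sf.normalise_k([10, 10], d, sf.ModelParams("power", 1.0, 1.0), T=100)
        # denominator: 10*10*1 + 10*10*1 = 200
        assert params.k == pytest.approx(0.5)

    def test_zero_volume_gives_zero_flows(self):
        d = dist_matrix(["A", "B"], [[0, 1], [1, 0]])
        params = sf.normalise_k([10, 10], d, sf.ModelParams("power", 1.0, 1.0), T=0)
        flows = sf.predict_flows([10, 10], d, params)
        assert params.k == 0 and flows.total == 0

    def test_volume_linearity(self, toy_settlements):
        d = sf.euclidean_matrix(toy_settlements)
        pops = toy_settlements.population("t0")
        base = sf.ModelParams("power", 1.0, 1.5)
        f1 = sf.predict_flows(pops, d, sf.normalise_k(pops, d, base, T=50))
        f2 = sf.predict_flows(pops, d, sf.normalise_k(pops, d, base, T=100))
        np.testing.assert_allclose(f2.values, 2 * f1.values, rtol=1e-12)


class TestPredictFlows:
    def test_equal_populations_symmetric(self):
        d = dist_matrix(["A", "B"], [[0, 7], [7, 0]])
        params = sf.normalise_k([50, 50], d, sf.ModelParams("power", 1.0, 1.3), T=10)
        f = sf.predict_flows([50, 50], d, params)
        assert f.values[0, 1] == pytest.approx(f.values[1, 0])

    @pytest.mark.parametrize("family,beta,gamma", [
        ("power", 1.0, 1.5), ("power", 2.5, 1.2), ("exponential", 0.05, 1.9),
    ])
    def test_total_equals_T_after_normalisation(self, toy_settlements, family, beta, gamma):
        d = sf.euclidean_matrix(toy_settlements)
        pops = toy_settlements.population("t0")
        params = sf.normalise_k(pops, d, sf.ModelParams(family, beta, gamma), T=50.0)
        f = sf.predict_flows(pops, d, params)
        assert f.total == pytest.approx(50.0, rel=1e-9)

    def test_three_settlement_hand_computation(self):
        """Six-term brute-force evaluation, gamma=1.5 beta=1 power, T=50."""
        pops = np.array([100.0, 200.0, 400.0])
        dv = np.array([[0, 10, 20], [10, 0, 30], [20, 30, 0]], dtype=float)
        d = dist_matrix(["A", "B", "C"], dv)
        params = sf.normalise_k(pops, d, sf.ModelParams("power", 1.0, 1.5), T=50.0)
        f = sf.predict_flows(pops, d, params)
        want = naive_gravity(pops, dv, "power", 1.0, 1.5, params.k)
        np.testing.assert_allclose(f.values, want, rtol=1e-12)
        assert want.sum() == pytest.approx(50.0, rel=1e-12)

    def test_oracle_equivalence_random(self, noiseless_world):
        """Vectorised prediction equals the naive double loop on 10 settlements."""
        w = noiseless_world
        pops = w.settlements.population("t0").to_numpy()[:10]
        ids = w.settlements.ids[:10]
        dv = w.distances.values[:10, :10]
        d = dist_matrix(ids, dv)
        params = sf.normalise_k(pops, d, sf.ModelParams("exponential", 0.03, 1.4), T=123.0)
        f = sf.predict_flows(pops, d, params)
        want = naive_gravity(pops, dv, "exponential", 0.03, 1.4, params.k)
        np.testing.assert_allclose(f.values, want, rtol=1e-10)

    def test_normalised_share_on_shortest_pair_nondecreasing_in_beta(self, toy_settlements):
        """Higher distance decay redistributes flow toward the shortest pair."""
        d = sf.euclidean_matrix(toy_settlements)
        pops = toy_settlements.population("t0")
        i, j = np.unravel_index(
            np.argmin(np.where(d.values > 0, d.values, np.inf)), d.values.shape
        )
        shares = []
        for beta in (0.5, 1.0, 2.0, 3.0):
            p = sf.normalise_k(pops, d, sf.ModelParams("power", beta, 1.5), T=1.0)
            shares.append(sf.predict_flows(pops, d, p).values[i, j])
        assert all(a <= b + 1e-12 for a, b in zip(shares, shares[1:]))


class TestFlowSummary:
    def test_single_flow(self):
        f = sf.FlowMatrix(np.array(["A", "B"]), [[0, 5], [0, 0]])
        s = sf.flow_summary(f).set_index("id")
        assert s.loc["A", "outflow"] == 5 and s.loc["B", "inflow"] == 5
        assert s.loc["A", "net"] == -5 and s.loc["B", "net"] == 5

    def test_symmetric_matrix_zero_nets(self):
        v = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
        s = sf.flow_summary(sf.FlowMatrix(np.array(list("ABC")), v))
        assert (s["net"] == 0).all()

    def test_matches_loop_oracle_and_net_sums_to_zero(self):
        rng = np.random.default_rng(3)
        v = rng.uniform(0, 10, (6, 6))
        np.fill_diagonal(v, 0)
        f = sf.FlowMatrix(np.array([f"s{i}" for i in range(6)]), v)
        s = sf.flow_summary(f)
        for r in range(6):
            assert s["outflow"].iloc[r] == pytest.approx(sum(v[r, c] for c in range(6)))
            assert s["inflow"].iloc[r] == pytest.approx(sum(v[c, r] for c in range(6)))
        assert s["net"].sum() == pytest.approx(0, abs=1e-9 * v.sum())


class TestTargets:
    def test_no_change_no_volume(self):
        p = pd.Series([100.0, 200.0], index=["A", "B"])
        t = sf.derive_targets(p, p)
        assert t.g == 1.0 and t.T == 0.0

    def test_uniform_growth_absorbed(self):
        p = pd.Series([100.0, 200.0], index=["A", "B"])
        t = sf.derive_targets(p, 2 * p)
        assert t.g == pytest.approx(2.0)
        np.testing.assert_allclose(t.delta, 0.0, atol=1e-9)
        assert t.T == pytest.approx(0.0, abs=1e-9)

    def test_hand_arithmetic(self):
        start = pd.Series([100.0, 100.0], index=["A", "B"])
        end = pd.Series([130.0, 90.0], index=["A", "B"])
        t = sf.derive_targets(start, end)
        assert t.g == pytest.approx(1.1)
        np.testing.assert_allclose(t.baseline, [110.0, 110.0])
        np.testing.assert_allclose(t.delta, [20.0, -20.0])
        assert t.T == pytest.approx(20.0)
        assert t.delta.sum() == pytest.approx(0.0, abs=1e-9)

    def test_zero_start_total_error(self):
        z = pd.Series([0.0, 0.0], index=["A", "B"])
        with pytest.raises(sf.ValidationError):
            sf.derive_targets(z, z)


class TestProjection:
    def test_identity(self):
        start = pd.Series([100.0, 50.0], index=["A", "B"])
        s = pd.DataFrame({"id": ["A", "B"], "inflow": [0.0, 0], "outflow": [0.0, 0],
                          "net": [0.0, 0]})
        proj, n = sf.project_population(start, 1.0, s)
        assert n == 0
        np.testing.assert_allclose(proj, start)

    def test_growth_plus_net(self):
        start = pd.Series([100.0], index=["A"])
        s = pd.DataFrame({"id": ["A"], "inflow": [0.0], "outflow": [5.0], "net": [-5.0]})
        proj, _ = sf.project_population(start, 1.1, s)
        assert proj["A"] == pytest.approx(105.0)

    def test_conservation_on_synthetic_world(self, noiseless_world):
        w = noiseless_world
        start = w.settlements.population("t0")
        summary = sf.flow_summary(w.true_flows)
        proj, n = sf.project_population(start, w.g, summary)
        assert n == 0
        assert proj.sum() == pytest.approx(w.g * start.sum(), rel=1e-9)

    def test_clamping_counted(self):
        start = pd.Series([10.0], index=["A"])
        s = pd.DataFrame({"id": ["A"], "inflow": [0.0], "outflow": [50.0], "net": [-50.0]})
        proj, n = sf.project_population(start, 1.0, s)
        assert n == 1 and proj["A"] == 0.0


def test_flow_long_csv_round_trip(tmp_path):
    rng = np.random.default_rng(8)
    v = rng.poisson(2, (5, 5)).astype(float)
    np.fill_diagonal(v, 0)
    ids = np.array([f"s{i}" for i in range(5)])
    f = sf.FlowMatrix(ids, v, interval=("t0", "t1"))
    path = tmp_path / "flows.csv"
    write_flows(f, path)
    back = read_flows(path, ids=ids, interval=("t0", "t1"))
    np.testing.assert_allclose(back.values, v)
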
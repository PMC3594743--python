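"""Leaky-integrator units, squashing, and selection competence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actdisc import network as nw


class TestIntegrateUnit:
    def test_fixed_point_at_zero(self):
        assert nw.integrate_unit(0.0, 0.0, 0.01, 0.04) == 0.0

    def test_hand_evaluated_step(self):
        assert nw.integrate_unit(0.0, 1.0, 0.01, 0.04) == pytest.approx(0.25)

    def test_converges_to_constant_input(self):
        a = 0.0
        for _ in range(2000):
            a = nw.integrate_unit(a, 1.0, 0.01, 0.04)
        assert a == pytest.approx(1.0, abs=1e-9)

    def test_unstable_step_rejected(self):
        with pytest.raises(ValueError):
            nw.integrate_unit(0.0, 1.0, 0.05, 0.04)
        with pytest.raises(ValueError):
            nw.integrate_unit(0.0, 1.0, -0.01, 0.04)


class TestSquash:
    @pytest.mark.parametrize("a, eps, expected",
                             [(0.2, 0.2, 0.0), (0.7, 0.2, 0.5), (2.0, 0.2, 1.0),
                              (-0.5, -0.2, 0.0), (0.0, -0.2, 0.2)])
    def test_piecewise_branches(self, a, eps, expected):
        assert nw.squash(a, eps) == pytest.approx(expected)

    @given(st.floats(-5, 5), st.floats(-0.5, 0.5))
    @settings(derandomize=True)
    def test_output_always_in_unit_interval(self, a, eps):
        assert 0.0 <= nw.squash(a, eps) <= 1.0


class TestEffectiveWeight:
    def test_d1_facilitated_d2_attenuated(self):
        assert nw.effective_cortico_striatal_weight(1.0, 0.2, "D1") == pytest.approx(1.2)
        assert nw.effective_cortico_striatal_weight(1.0, 0.2, "D2") == pytest.approx(0.8)

    def test_zero_tonic_dopamine_is_identity(self):
        for receptor in ("D1", "D2"):
            assert nw.effective_cortico_striatal_weight(0.7, 0.0, receptor) == 0.7

    def test_invalid_receptor_rejected(self):
        with pytest.raises(ValueError):
            nw.effective_cortico_striatal_weight(1.0, 0.2, "D3")


class TestSelectActions:
    def test_threshold_comparisons(self):
        assert nw.select_actions(np.array([0.6, 0.3, 0.1]), 0.5) == {0}
        assert nw.select_actions(np.array([0.2, 0.3, 0.1]), 0.5) == set()
        assert nw.select_actions(np.array([0.6, 0.7, 0.1]), 0.5) == {0, 1}


@pytest.fixture(scope="module")
def calibrated():
    return nw.CorticoStriatalWeights.initial()


class TestNetworkDynamics:
    def test_rest_state_no_selection_gpi_tonic(self, calibrated):
        st_ = nw.run_to_equilibrium(nw.NetworkState(), np.zeros(3), calibrated)
        y = st_.outputs()
        assert nw.select_actions(y[nw.BS]) == set()
        assert np.all(y[nw.GPI] > 0)

    def test_dominant_salience_wins(self, calibrated):
        st_ = nw.run_to_equilibrium(nw.NetworkState(), np.array([0.8, 0.4, 0.1]),
                                    calibrated)
        y = st_.outputs()
        assert nw.select_actions(y[nw.BS]) == {0}
        assert np.argmin(y[nw.GPI]) == 0  # winner's inhibition released

    def test_channel_permutation_symmetry(self, calibrated):
        sal = np.array([0.7, 0.3, 0.1])
        perm = [2, 0, 1]
        st1 = nw.run_to_equilibrium(nw.NetworkState(), sal, calibrated)
        st2 = nw.run_to_equilibrium(nw.NetworkState(), sal[perm], calibrated)
        assert np.allclose(st1.a[:, perm], st2.a, atol=1e-12)

    def test_outputs_bounded_on_long_runs(self, calibrated, rng):
        st_ = nw.NetworkState()
        for _ in range(2000):
            sal = rng.uniform(0, 1, 3)
            nw.step_network(st_, sal, calibrated, 0.01,
                            noise=rng.normal(0, 0.06, 3))
        y = st_.outputs()
        assert np.all((y >= 0) & (y <= 1))
        assert np.all(np.isfinite(st_.a))

    def test_selection_battery_passes(self, calibrated):
        ok, failures = nw.selection_battery(calibrated)
        assert ok, failures

    def test_switching_after_salience_reversal(self, calibrated):
        """An engaged channel is sticky (behavioural maintenance), but a
        clearly higher rival salience takes the selection over."""
        st_ = nw.run_to_equilibrium(nw.NetworkState(), np.array([0.1, 0.4, 0.0]),
                                    calibrated)
        assert nw.select_actions(st_.outputs()[nw.BS]) == {1}
        nw.run_to_equilibrium(st_, np.array([0.8, 0.4, 0.0]), calibrated,
                              duration=2.0)
        assert nw.select_actions(st_.outputs()[nw.BS]) == {0}


class TestCalibration:
    def test_calibrated_weights_positive_and_selectable(self):
        w = nw.calibrate_motor_weights()
        assert np.all(w.motor > 0)
        for ch in range(3):
            sal = np.full(3, 0.1)
            sal[ch] = 0.8
            st_ = nw.run_to_equilibrium(nw.NetworkState(), sal, w)
            assert nw.select_actions(st_.outputs()[nw.BS]) == {ch}


class TestContainers:
    def test_unit_params_validation(self):
        with pytest.raises(ValueError):
            nw.UnitParams(tau=0.0)

    def test_weights_validation(self):
        with pytest.raises(ValueError):
            nw.CorticoStriatalWeights(np.full((2, 3), -0.1), np.zeros((2, 3)))
        with pytest.raises(ValueError):
            nw.CorticoStriatalWeights(np.full((2, 3), 0.5), np.zeros((2, 3)),
                                      lam=1.0)

    def test_population_accessor(self):
        state = nw.NetworkState()
        pop = state.population("gpi_snr")
        assert pop.y.shape == (3,)
        assert np.all(pop.y > 0)  # tonically active at rest
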
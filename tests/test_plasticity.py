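"""Dopamine-blended BCM rule: mixing, sign structure, weight dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actdisc import plasticity as pl


@pytest.fixture
def coeffs():
    return pl.PlasticityCoefficients()


@pytest.fixture
def params():
    return pl.LearningRuleParams()


class TestAlphaAndBlending:
    @pytest.mark.parametrize("d, expected", [(0.0, 0.0), (0.25, 0.5), (1.0, 0.8)])
    def test_alpha_values(self, d, expected):
        assert pl.alpha(d) == pytest.approx(expected, abs=1e-15)

    @given(st.floats(0.0, 100.0))
    @settings(derandomize=True)
    def test_alpha_monotone_saturating(self, d):
        assert 0.0 <= pl.alpha(d) < 1.0
        assert pl.alpha(d + 0.1) > pl.alpha(d)

    def test_blend_endpoints_and_midpoint(self):
        assert pl.blend_coefficient(1.0, -1.0, 0.0) == -1.0
        assert pl.blend_coefficient(1.0, -1.0, 1e9) == pytest.approx(1.0, abs=1e-8)
        assert pl.blend_coefficient(1.0, -1.0, 0.25) == pytest.approx(0.0)


class TestCBcmSignStructure:
    def test_d1_low_dopamine_positive(self, coeffs, params):
        """Dips (d ~ 0) make C_BCM > 0 for D1: LTD of the GO pathway."""
        assert pl.c_bcm(0.0, "D1", coeffs, params) > 0

    def test_d2_low_dopamine_negative(self, coeffs, params):
        assert pl.c_bcm(0.0, "D2", coeffs, params) < 0

    def test_d1_high_dopamine_negative(self, coeffs, params):
        """Bursts make C_BCM < 0 for D1: strong LTP of the GO pathway."""
        assert pl.c_bcm(2.0, "D1", coeffs, params) < 0

    def test_d2_high_dopamine_positive(self, coeffs, params):
        assert pl.c_bcm(2.0, "D2", coeffs, params) > 0

    def test_coefficient_sign_pattern(self, coeffs):
        # D1 high dopamine: strong LTP for positive timing, weak LTD negative
        ap, am = coeffs.pair("D1", "hi")
        assert ap > 0 > am and abs(ap) > abs(am)
        # D2 low dopamine: uniform LTP for both timings
        ap, am = coeffs.pair("D2", "lo")
        assert ap > 0 and am > 0


class TestThetaAndWeightUpdate:
    def test_theta_is_product(self):
        assert pl.theta_bcm(0.0, -3.0) == 0.0
        assert pl.theta_bcm(0.25, -2.0) == -0.5

    def test_no_update_without_pre_or_post_activity(self):
        assert pl.weight_update(0.5, 0.0, 0.7, -1.0, 1.0, 0.01, 0.0, 2.0) == 0.5
        assert pl.weight_update(0.5, 0.7, 0.0, -1.0, 1.0, 0.01, 0.0, 2.0) == 0.5

    def test_negative_theta_gives_ltp(self):
        w2 = pl.weight_update(0.5, 0.5, 0.5, -1.0, 1.0, 0.01, 0.0, 2.0)
        assert w2 > 0.5

    def test_bcm_zero_crossing_exact(self):
        """dw = 0 exactly when the post-rate equals the sliding threshold."""
        theta = 0.37
        w2 = pl.weight_update(0.5, 0.8, theta, theta, 5.0, 0.01, 0.0, 2.0)
        assert w2 == 0.5

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0), st.floats(-3.0, 3.0))
    @settings(derandomize=True)
    def test_weights_stay_within_bounds(self, x, y, theta):
        w = 0.5
        for _ in range(50):
            w = pl.weight_update(w, x, y, theta, 10.0, 0.1, 0.1, 1.5)
        assert 0.1 <= w <= 1.5


class TestYsqTracker:
    def test_converges_to_y_squared(self):
        tr = pl.YsqTracker()
        y = np.array([[0.6, 0.0, 0.3], [0.2, 0.0, 0.0]])
        for _ in range(20_000):
            tr.update(y, 0.01, 5.0)
        assert np.allclose(tr.ysq, y**2, atol=1e-6)

    def test_decays_to_zero_without_activity(self):
        tr = pl.YsqTracker()
        tr.ysq[:] = 0.5
        for _ in range(20_000):
            tr.update(np.zeros((2, 3)), 0.01, 5.0)
        assert np.all(tr.ysq < 1e-6)

    def test_ema_time_constant(self):
        """After one time constant the tracker covers 1 - 1/e of a step."""
        tr = pl.YsqTracker()
        y = np.ones((2, 3))
        n = int(5.0 / 0.001)
        for _ in range(n):
            tr.update(y, 0.001, 5.0)
        assert tr.ysq[0, 0] == pytest.approx(1 - np.exp(-1), abs=0.01)


class TestEventStreamDrift:
    """Directional weight drift under characteristic dopamine event streams."""

    def _run_events(self, d_level, n_events=30):
        coeffs = pl.PlasticityCoefficients()
        params = pl.LearningRuleParams(eta=0.002, c_gain=10.0)
        w = {"D1": 0.5, "D2": 0.5}
        x, y, ysq = 0.7, 0.5, 0.25
        for _ in range(n_events):
            for receptor in ("D1", "D2"):
                c = pl.c_bcm(d_level, receptor, coeffs, params)
                theta = pl.theta_bcm(ysq, c)
                for _ in range(100):  # 1 s window at dt = 0.01
                    w[receptor] = pl.weight_update(
                        w[receptor], x, y, theta, params.eta, 0.01,
                        params.w_min, params.w_max)
        return w

    def test_dip_dominated_stream_d1_down_d2_up(self):
        w = self._run_events(d_level=0.0)
        assert w["D1"] < 0.5
        assert w["D2"] > 0.5

    def test_burst_dominated_stream_d1_up(self):
        w = self._run_events(d_level=1.5)
        assert w["D1"] > 0.5

    def test_motor_and_sensory_mirror_under_equal_pre_rates(self):
        """Identical pre-rates produce identical trajectories for two weights
        subjected to the same rule (motor vs sensory inputs)."""
        params = pl.LearningRuleParams(eta=0.002)
        w_mot, w_sen = 0.5, 0.5
        for _ in range(200):
            w_mot = pl.weight_update(w_mot, 0.6, 0.5, -0.4, params.eta, 0.01,
                                     params.w_min, params.w_max)
            w_sen = pl.weight_update(w_sen, 0.6, 0.5, -0.4, params.eta, 0.01,
                                     params.w_min, params.w_max)
        assert w_mot == w_sen
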
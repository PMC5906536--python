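"""Tests of the two-state cross-bridge scheme: overlap geometry, Hill
activation, the closed-form steady state, boundedness under integration, and
the length dependence of tension and ATP turnover."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from counterpulse.calcium import ca_at
from counterpulse.myofilament import (active_tension, atp_rate,
                                      hill_activation, sl_from_volume,
                                      sovf_thick, xb_derivative,
                                      xb_steady_state)
from counterpulse.params import CaTransientConfig, MyofilamentParams

P = MyofilamentParams()


class TestSingleOverlapFraction:
    def test_plateau_is_full_overlap(self):
        for sl in (P.sl_min_overlap, 2.1, P.sl_max_overlap):
            assert sovf_thick(sl, P) == 1.0

    def test_zero_beyond_overlap_bounds(self):
        assert sovf_thick(P.sl_zero_low, P) == 0.0
        assert sovf_thick(P.sl_zero_high, P) == 0.0
        assert sovf_thick(1.0, P) == 0.0
        assert sovf_thick(3.5, P) == 0.0

    def test_linear_midpoints(self):
        # halfway between the zero-overlap bound and the plateau edge
        lo_mid = 0.5 * (P.sl_zero_low + P.sl_min_overlap)
        hi_mid = 0.5 * (P.sl_max_overlap + P.sl_zero_high)
        assert sovf_thick(lo_mid, P) == pytest.approx(0.5)
        assert sovf_thick(hi_mid, P) == pytest.approx(0.5)

    def test_clamped_to_unit_interval(self):
        sl = np.linspace(0.5, 4.0, 200)
        out = sovf_thick(sl, P)
        assert np.all((out >= 0.0) & (out <= 1.0))

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            sovf_thick(0.0, P)


class TestCrossBridgeKinetics:
    def test_no_activation_no_bridges_is_stationary(self):
        assert xb_derivative(0.0, 0.0, P) == 0.0

    def test_hill_midpoint(self):
        assert hill_activation(P.ca50, P) == pytest.approx(0.5)

    def test_negative_ca_rejected(self):
        with pytest.raises(ValueError):
            xb_derivative(0.0, -0.1, P)

    def test_saturating_ca_fixed_point(self):
        # Hill activation saturates to 1, so xb* -> f/(f+g)
        assert xb_steady_state(1e6, P) == pytest.approx(
            P.f_xb / (P.f_xb + P.g_xbT), rel=1e-9)

    @pytest.mark.parametrize("ca", [0.2, 0.5, 1.0])
    def test_integrated_xb_converges_to_closed_form(self, ca):
        """Independent oracle: integrating the ODE at constant Ca must land on
        the analytic fixed point."""
        sol = solve_ivp(lambda t, y: [xb_derivative(y[0], ca, P)],
                        (0.0, 5e4), [0.0], rtol=1e-10, atol=1e-12)
        assert sol.y[0, -1] == pytest.approx(xb_steady_state(ca, P), abs=1e-6)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.floats(min_value=0.0, max_value=10.0),
                    min_size=3, max_size=8),
           st.floats(min_value=0.0, max_value=1.0))
    def test_xb_stays_in_unit_interval(self, ca_knots, xb0):
        """For any nonnegative piecewise Ca drive, occupancy remains in
        [0, 1]."""
        knots_t = np.linspace(0.0, 600.0, len(ca_knots))

        def rhs(t, y):
            ca = float(np.interp(t, knots_t, ca_knots))
            return [xb_derivative(min(max(y[0], 0.0), 1.0), ca, P)]

        sol = solve_ivp(rhs, (0.0, 600.0), [xb0], rtol=1e-8, atol=1e-10)
        assert np.all(sol.y[0] >= -1e-9)
        assert np.all(sol.y[0] <= 1.0 + 1e-9)


class TestTensionAndAtp:
    def test_tension_product_form(self):
        sl_mid = 0.5 * (P.sl_zero_low + P.sl_min_overlap)  # sovf = 0.5
        assert active_tension(0.6, sl_mid, P) == pytest.approx(0.3)
        assert active_tension(0.0, 2.1, P) == 0.0
        assert active_tension(1.0, 2.1, P) == 1.0

    def test_atp_rate_product_form(self):
        p = MyofilamentParams(f_xb=0.1, g_xbT=0.05)
        # sovf = 0.8 on the ascending limb: sl = zero_low + 0.8*(plateau span)
        sl = p.sl_zero_low + 0.8 * (p.sl_min_overlap - p.sl_zero_low)
        assert atp_rate(0.5, sl, p) == pytest.approx(0.05 * 0.8 * 0.5)

    def test_atp_rate_vanishes_without_overlap_or_bridges(self):
        assert atp_rate(0.5, P.sl_zero_low, P) == 0.0
        assert atp_rate(0.0, 2.1, P) == 0.0

    def test_frank_starling_ascending_limb(self):
        """Longer sarcomeres (below the plateau) raise both tension and ATP
        turnover at fixed occupancy."""
        sls = np.linspace(P.sl_zero_low + 0.05, P.sl_min_overlap, 20)
        ten = [active_tension(0.5, s, P) for s in sls]
        atp = [atp_rate(0.5, s, P) for s in sls]
        assert np.all(np.diff(ten) > 0)
        assert np.all(np.diff(atp) > 0)

    def test_reduced_peak_ca_reduces_peak_tension(self):
        """The 70% heart-failure Ca amplitude strictly lowers peak tension of
        the driven twitch."""
        cfg = CaTransientConfig()
        t = np.linspace(0.0, cfg.bcl, 601)

        def peak_tension(failing):
            def rhs(tt, y):
                return [xb_derivative(y[0], ca_at(tt, cfg, failing), P)]
            sol = solve_ivp(rhs, (0.0, cfg.bcl), [0.0], t_eval=t, rtol=1e-8)
            return np.max(active_tension(sol.y[0], 2.1, P))

        assert peak_tension(True) < peak_tension(False)


def test_sl_volume_mapping_reference_point():
    assert sl_from_volume(100.0, 2.0, 100.0) == pytest.approx(2.0)
    assert sl_from_volume(50.0, 2.0, 100.0) == pytest.approx(
        2.0 * 0.5 ** (1 / 3))
    # with a wall-volume offset the reference point is preserved
    assert sl_from_volume(100.0, 2.0, 100.0, 50.0) == pytest.approx(2.0)
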
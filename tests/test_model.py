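"""Core delay-ODE model: regulation functions, spline activity, RK4 solver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nlhvdm import (
    GeneKinetics,
    TFActivityProfile,
    cis_regulatory_value,
    delayed_activity,
    expand_time_grid,
    hill_regulation,
    simulate_gene,
)
from nlhvdm.errors import InvalidInputError, InvalidParameterError

from conftest import MEASUREMENT_TIMES


class TestHillRegulation:
    @pytest.mark.parametrize(
        "p, K, n, m, expected",
        [
            (0.0, 1.0, 4, 1, 0.0),            # zero activator
            (1.0, 1.0, 4, 1, 0.5),            # half-saturation
            (2.0, 1.0, 4, 1, 16.0 / 17.0),    # p^4/(1+p^4)
            (1.0, 1.0, 1, 1, 0.5),            # Michaelis-Menten limit
            (1.0, 1.0, 4, 2, 0.25),           # (1/2)^m at p = K
        ],
    )
    def test_closed_form_values(self, p, K, n, m, expected):
        assert hill_regulation(p, K, n, m) == pytest.approx(expected, abs=1e-12)

    def test_invalid_K_raises(self):
        with pytest.raises(InvalidParameterError):
            hill_regulation(1.0, 0.0)
        with pytest.raises(InvalidParameterError):
            hill_regulation(1.0, -1.0)

    @settings(max_examples=100, derandomize=True)
    @given(
        p=st.floats(0.0, 10.0), q=st.floats(0.0, 10.0),
        K=st.floats(0.01, 10.0), n=st.integers(1, 6), m=st.integers(1, 3),
    )
    def test_bounded_and_monotone_in_activity(self, p, q, K, n, m):
        gp = hill_regulation(p, K, n, m)
        gq = hill_regulation(q, K, n, m)
        assert 0.0 <= gp <= 1.0
        if p <= q:
            assert gp <= gq + 1e-15

    @settings(max_examples=50, derandomize=True)
    @given(K1=st.floats(0.01, 10.0), K2=st.floats(0.01, 10.0))
    def test_monotone_decreasing_in_K(self, K1, K2):
        p = 1.0
        if K1 <= K2:
            assert hill_regulation(p, K1) >= hill_regulation(p, K2) - 1e-15


class TestCisRegulation:
    def test_values(self):
        assert cis_regulatory_value(0.5, 1) == 0.5
        assert cis_regulatory_value(0.0, 0) == 1.0
        assert cis_regulatory_value(16.0 / 17.0, 0) == pytest.approx(1.0 / 17.0)

    @settings(max_examples=50, derandomize=True)
    @given(g=st.floats(0.0, 1.0))
    def test_activator_inhibitor_complementarity(self, g):
        assert cis_regulatory_value(g, 1) + cis_regulatory_value(g, 0) == pytest.approx(1.0, abs=1e-15)

    def test_invalid_delta(self):
        with pytest.raises(InvalidParameterError):
            cis_regulatory_value(0.5, 2)


class TestActivityProfile:
    def test_spline_passes_through_knots(self, pulse_profile):
        for t, v in zip(pulse_profile.knot_times, pulse_profile.knot_values):
            if t > 0:
                assert pulse_profile.value(t) == pytest.approx(v, abs=1e-12)

    def test_baseline_before_zero(self, pulse_profile):
        assert pulse_profile.value(0.0) == pulse_profile.baseline_value
        assert pulse_profile.value(-3.0) == pulse_profile.baseline_value

    def test_collinear_knots_reproduce_line(self):
        t = np.array([0.0, 2.0, 4.0, 6.0])
        prof = TFActivityProfile(t, 0.1 * t, baseline_value=0.0)
        tt = np.linspace(0.5, 6.0, 23)
        assert np.allclose(prof.value(tt), 0.1 * tt, atol=1e-12)

    def test_extrapolation_clamps_to_last_knot(self, pulse_profile):
        last = pulse_profile.knot_values[-1]
        assert pulse_profile.value(99.0) == pytest.approx(last)

    def test_values_outside_unit_box_rejected(self):
        with pytest.raises(InvalidParameterError):
            TFActivityProfile([0.0, 1.0], [0.0, 1.5])

    def test_non_monotone_knots_rejected(self):
        with pytest.raises(InvalidInputError):
            TFActivityProfile([0.0, 0.0], [0.0, 1.0])


class TestDelayedActivity:
    def test_zero_before_delay(self, pulse_profile):
        assert delayed_activity(pulse_profile, 1.0, 1.5) == 0.0
        assert delayed_activity(pulse_profile, 1.5, 1.5) == 0.0

    def test_knot_passthrough_with_delay(self):
        prof = TFActivityProfile([0.0, 2.0, 4.0], [0.0, 0.7, 0.1])
        assert delayed_activity(prof, 4.0, 2.0) == pytest.approx(0.7, abs=1e-12)

    def test_constant_profile(self):
        prof = TFActivityProfile([0.0, 6.0, 12.0], [0.3, 0.3, 0.3], baseline_value=0.3)
        assert delayed_activity(prof, 5.3, 0.0) == pytest.approx(0.3, abs=1e-12)

    def test_negative_delay_rejected(self, pulse_profile):
        with pytest.raises(InvalidParameterError):
            delayed_activity(pulse_profile, 1.0, -0.5)


class TestExpandTimeGrid:
    def test_seven_to_twentyfive(self):
        grid = expand_time_grid(MEASUREMENT_TIMES, 3)
        assert grid.size == 25
        assert np.all(np.diff(grid) > 0)
        assert set(MEASUREMENT_TIMES).issubset(set(grid))

    def test_identity_at_zero_inserts(self):
        assert np.array_equal(expand_time_grid(MEASUREMENT_TIMES, 0), MEASUREMENT_TIMES)

    def test_equidistant_insertion(self):
        assert np.allclose(expand_time_grid([0.0, 4.0], 3), [0.0, 1.0, 2.0, 3.0, 4.0])

    def test_non_monotone_rejected(self):
        with pytest.raises(InvalidInputError):
            expand_time_grid([0.0, 2.0, 1.0], 3)


class TestSimulateGene:
    def test_linear_ode_closed_form(self, pulse_profile):
        # k = 0 decouples the gene from the TF: x(t) = c/d + (x0 - c/d) e^{-dt}
        kin = GeneKinetics(c=1.0, k=0.0, K=1.0, d=1.0)
        tr = simulate_gene(kin, pulse_profile, 0.0, MEASUREMENT_TIMES, step=0.01)
        exact = 1.0 - np.exp(-tr.times)
        rel = np.abs(tr.values[1:] - exact[1:]) / exact[1:]
        assert np.max(rel) <= 1e-6
        assert tr.values[-1] == pytest.approx(0.9999938558, abs=1e-6)

    def test_no_dynamics(self, pulse_profile):
        kin = GeneKinetics(c=0.0, k=0.0, K=1.0, d=0.0)
        tr = simulate_gene(kin, pulse_profile, 2.5, MEASUREMENT_TIMES)
        assert np.allclose(tr.values, 2.5)

    def test_steady_state_with_constant_activity(self, constant_profile):
        # f = 0.5 at p = K = 1, so x* = (c + k/2)/d = 1.5
        kin = GeneKinetics(c=0.5, k=2.0, K=1.0, d=1.0, delta=1)
        tr = simulate_gene(kin, constant_profile, 0.0, MEASUREMENT_TIMES, step=0.01)
        expected_12 = 1.5 * (1.0 - np.exp(-12.0))
        assert tr.values[-1] == pytest.approx(expected_12, abs=1e-4)

    def test_fourth_order_convergence(self, pulse_profile):
        kin = GeneKinetics(c=0.5, k=3.0, K=0.4, d=1.2)
        times = np.array([0.0, 12.0])
        ref = simulate_gene(kin, pulse_profile, 0.2, times, step=0.001).values[-1]
        errs = []
        for step in (0.2, 0.1):
            errs.append(abs(simulate_gene(kin, pulse_profile, 0.2, times, step=step).values[-1] - ref))
        order = np.log2(errs[0] / errs[1])
        assert 3.5 <= order <= 4.5

    def test_invalid_inputs(self, pulse_profile):
        kin = GeneKinetics(c=1.0, k=1.0, K=1.0, d=1.0)
        with pytest.raises(InvalidInputError):
            simulate_gene(kin, pulse_profile, 0.0, [], step=0.05)
        with pytest.raises(InvalidInputError):
            simulate_gene(kin, pulse_profile, 0.0, MEASUREMENT_TIMES, step=-0.1)

    def test_vectorised_path_matches_stepwise_rk4(self, pulse_profile):
        # the cumulative-sum linear-forced solver must agree with plain RK4
        from nlhvdm.model import _forcing, _rk4_forced_linear, _rk4_grid

        kin = GeneKinetics(c=1.2, k=2.5, K=0.5, d=1.7, tau=1.0)
        tr = simulate_gene(kin, pulse_profile, 0.3, MEASUREMENT_TIMES, step=0.05)
        h, n_steps, nodes, rec = _rk4_grid(MEASUREMENT_TIMES, 0.05)
        A = _forcing(kin, pulse_profile, nodes)
        xs = _rk4_forced_linear(A[None, :], np.array([kin.d]), h, np.array([0.3]))
        assert np.allclose(xs[0, rec], tr.values[1:], rtol=1e-9, atol=1e-12)
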
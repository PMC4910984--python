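"""Kill-law kinetics: hand-computed values, limits and invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tumordecay.kinetics import (
    KillParams,
    PopulationState,
    closed_form_power_decay,
    decay_rhs,
    effectiveness_rescale,
    exponential_decay,
    fractional_cell_kill,
    integrate_decay,
    linear_limit_rate,
    power_extinction_time,
)

params_strategy = st.builds(
    KillParams,
    d=st.floats(0.01, 10.0),
    lambda_=st.floats(0.05, 1.0),
    s=st.floats(0.01, 100.0),
    nu=st.floats(0.05, 1.0),
)


class TestFractionalCellKill:
    @pytest.mark.parametrize(
        "params, T, E, expected",
        [
            (KillParams(1, 1, 1, 1), 100, 0, 0.0),  # no effectors, no kill
            (KillParams(1, 1, 1, 1), 50, 50, 0.5),  # E^l = s T: half-max
            (KillParams(2, 0.5, 3, 2 / 3), 8, 16, 0.5),  # 2*4/(3*4+4)
        ],
    )
    def test_hand_computed_values(self, params, T, E, expected):
        K = fractional_cell_kill(params, PopulationState(T=T, E=E))
        assert K == pytest.approx(expected)

    def test_half_maximum_when_effectors_match_scaled_tumor(self):
        # K = d/2 exactly when E^lambda = s T^nu, for any parameter set
        p = KillParams(d=3.0, lambda_=0.7, s=2.5, nu=0.5)
        T = 400.0
        E = (p.s * T**p.nu) ** (1 / p.lambda_)
        K = fractional_cell_kill(p, PopulationState(T=T, E=E))
        assert K == pytest.approx(p.d / 2)

    def test_saturates_to_d_with_growing_effector_population(self):
        p = KillParams(d=2.0, lambda_=0.8, s=5.0, nu=0.5)
        T = 1000.0
        ks = [fractional_cell_kill(p, PopulationState(T=T, E=10.0**k)) for k in range(1, 10)]
        assert all(k1 < k2 for k1, k2 in zip(ks, ks[1:]))
        assert all(k < p.d for k in ks)
        assert ks[-1] == pytest.approx(p.d, rel=1e-4)

    @given(params=params_strategy, T=st.floats(0.1, 1e6), E=st.floats(0.1, 1e6))
    @settings(max_examples=100, derandomize=True)
    def test_bounded_by_maximal_rate(self, params, T, E):
        K = fractional_cell_kill(params, PopulationState(T=T, E=E))
        assert 0 < K < params.d

    @given(params=params_strategy, T=st.floats(1.0, 1e5), E=st.floats(1.0, 1e5))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_each_population(self, params, T, E):
        base = fractional_cell_kill(params, PopulationState(T=T, E=E))
        more_e = fractional_cell_kill(params, PopulationState(T=T, E=2 * E))
        more_t = fractional_cell_kill(params, PopulationState(T=2 * T, E=E))
        assert more_e > base  # more effectors kill faster
        assert more_t < base  # bigger tumors dilute the effectors

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            KillParams(d=-1, lambda_=1, s=1)
        with pytest.raises(ValueError):
            KillParams(d=1, lambda_=1.5, s=1)  # geometry exponent must be <= 1
        with pytest.raises(ValueError):
            KillParams(d=1, lambda_=1, s=1, nu=0.0)
        with pytest.raises(ValueError):
            PopulationState(T=-1, E=0)


class TestDecayRhs:
    def test_extinct_tumor_has_zero_rate(self):
        assert decay_rhs(KillParams(1, 1, 1), PopulationState(T=0, E=100)) == 0.0

    def test_half_max_kill_of_fifty_cells(self):
        rate = decay_rhs(KillParams(1, 1, 1, 1), PopulationState(T=50, E=50))
        assert rate == pytest.approx(-25.0)

    def test_effector_excess_approaches_exponential_limit(self):
        rate = decay_rhs(KillParams(0.04, 1, 1, 1), PopulationState(T=10, E=1e6))
        assert rate == pytest.approx(-0.4, rel=1e-4)

    @given(
        params=params_strategy,
        T=st.floats(0.0, 1e6),
        E=st.floats(0.0, 1e6),
    )
    @settings(max_examples=100, derandomize=True)
    def test_never_positive(self, params, T, E):
        assert decay_rhs(params, PopulationState(T=T, E=E)) <= 0.0


class TestLinearLimit:
    @pytest.mark.parametrize(
        "params, E0, expected",
        [
            (KillParams(1, 1, 1), 1, 1.0),  # one effector, one cell per hour
            (KillParams(1, 1, 1), 0, 0.0),
            (KillParams(3, 0.5, 2), 16, 6.0),
        ],
    )
    def test_constant_speed(self, params, E0, expected):
        assert linear_limit_rate(params, E0) == pytest.approx(expected)

    @given(params=params_strategy, E0=st.floats(0.5, 100.0))
    @settings(max_examples=50, derandomize=True)
    def test_is_the_big_tumor_limit_of_the_rhs(self, params, E0):
        # pick T large enough that s T^nu dwarfs E0^lambda by 1e8
        T = (1e8 * E0**params.lambda_ / params.s) ** (1.0 / params.nu)
        huge = decay_rhs(params, PopulationState(T=T, E=E0))
        assert -huge == pytest.approx(linear_limit_rate(params, E0), rel=1e-4)


class TestClosedFormPowerDecay:
    def test_initial_condition(self):
        assert closed_form_power_decay(2.0, 0.5, 100.0, 0.0) == pytest.approx(100.0)

    def test_hand_computed_point_and_extinction(self):
        # nu=1/2, d=2, T0=100: T(5) = (10 - 5)^2 = 25, extinct at t* = 10
        assert closed_form_power_decay(2.0, 0.5, 100.0, 5.0) == pytest.approx(25.0)
        assert power_extinction_time(2.0, 0.5, 100.0) == pytest.approx(10.0)
        assert closed_form_power_decay(2.0, 0.5, 100.0, 10.0) == 0.0
        assert closed_form_power_decay(2.0, 0.5, 100.0, 11.0) == 0.0

    def test_rejects_nu_one(self):
        with pytest.raises(ValueError):
            closed_form_power_decay(1.0, 1.0, 100.0, 1.0)


class TestIntegrateDecay:
    t_grid = np.linspace(0.0, 50.0, 201)

    def test_no_effectors_means_no_decay(self):
        series = integrate_decay(KillParams(1, 1, 1), T0=500.0, E0=0.0, t_grid=self.t_grid)
        assert np.all(series.tumor_cells == 500.0)

    def test_exponential_limit_when_effectors_dominate(self):
        p = KillParams(d=0.1, lambda_=1, s=1, nu=1)
        series = integrate_decay(p, T0=100.0, E0=1e7, t_grid=self.t_grid)
        expected = exponential_decay(p.d, 100.0, self.t_grid)
        np.testing.assert_allclose(series.tumor_cells, expected, rtol=1e-4)

    def test_parabolic_limit_when_effectors_dominate(self):
        p = KillParams(d=2.0, lambda_=1, s=1, nu=0.5)
        t = np.linspace(0.0, 12.0, 121)
        series = integrate_decay(p, T0=100.0, E0=1e7, t_grid=t)
        expected = closed_form_power_decay(p.d, p.nu, 100.0, t)
        np.testing.assert_allclose(
            series.tumor_cells, expected, rtol=1e-4, atol=1e-4 * 100.0
        )

    def test_linear_limit_when_tumor_dominates(self):
        # E0^lambda / (s T0^nu) = 1e-3: the first half of the decay follows
        # the constant-speed ramp to within 1%
        p = KillParams(d=1.0, lambda_=1, s=1, nu=1)
        T0, E0 = 1e6, 1e3
        speed = linear_limit_rate(p, E0)
        t_half = 0.5 * T0 / speed
        t = np.linspace(0.0, t_half, 101)
        series = integrate_decay(p, T0=T0, E0=E0, t_grid=t)
        ramp = T0 - speed * t
        np.testing.assert_allclose(series.tumor_cells, ramp, rtol=0.01)

    def test_monotone_and_clamped_at_zero(self):
        p = KillParams(d=5.0, lambda_=1, s=1, nu=0.5)
        series = integrate_decay(p, T0=50.0, E0=1e6, t_grid=self.t_grid)
        assert series.is_nonincreasing(atol=1e-12)
        assert np.all(series.tumor_cells >= 0.0)
        assert series.tumor_cells[-1] == 0.0  # extinct well before t=50

    def test_rejects_bad_grid(self):
        with pytest.raises(ValueError):
            integrate_decay(KillParams(1, 1, 1), 10.0, 1.0, np.array([1.0, 2.0]))


class TestEffectivenessRescale:
    def test_identity_at_full_effectiveness(self):
        p = KillParams(1, 1, 1)
        assert effectiveness_rescale(p, 1.0) == p

    def test_hand_computed_rescalings(self):
        assert effectiveness_rescale(KillParams(1, 1, 1), 0.5).s == pytest.approx(2.0)
        # s' = s / f^lambda = 3 / 0.01^0.5 = 30
        assert effectiveness_rescale(KillParams(1, 0.5, 3), 0.01).s == pytest.approx(30.0)

    def test_equivalence_of_ineffective_population(self):
        p = KillParams(1, 1, 1)
        rescaled = effectiveness_rescale(p, 0.5)
        lhs = fractional_cell_kill(rescaled, PopulationState(T=10, E=10))
        rhs = fractional_cell_kill(p, PopulationState(T=10, E=5))
        assert lhs == pytest.approx(rhs)

    @given(
        params=params_strategy,
        T=st.floats(0.1, 1e5),
        E=st.floats(0.1, 1e5),
        f=st.floats(0.01, 1.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_rescaling_identity_everywhere(self, params, T, E, f):
        # K(E, T; s/f^lambda) == K(f E, T; s) to machine precision
        lhs = fractional_cell_kill(effectiveness_rescale(params, f), PopulationState(T=T, E=E))
        rhs = fractional_cell_kill(params, PopulationState(T=T, E=f * E))
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_rejects_nonpositive_fraction(self):
        with pytest.raises(ValueError):
            effectiveness_rescale(KillParams(1, 1, 1), 0.0)


def test_params_roundtrip_through_yaml(tmp_path):
    import yaml

    p = KillParams(d=1.5, lambda_=0.8, s=2.0, nu=0.5)
    path = tmp_path / "params.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(p.to_dict(), fh)
    assert KillParams.from_yaml(path) == p
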
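"""Right-hand sides, Jacobians and parameter validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutswitch.model import (
    ModelParameters,
    PARAM_NAMES,
    jacobian,
    preset,
    rhs,
    rhs_param_derivative,
    state_dim,
)

from conftest import INFLAMED_STATE

PUBLISHED_DEFAULTS = {
    "k_a": 12.0, "k_s": 1.0, "k_ai": 5.0, "k_r": 0.5, "k_bn": 4.7,
    "k_b": 5.0, "k_br": 0.5, "k_n": 0.2, "k_p": 7.0, "k_t": 0.2,
    "k_tl": 2.8, "k_bl": 1.02, "k_lb": 3.4, "k_l": 0.7, "k_bt": 2.1,
    "k_d": 0.125, "k_B": 2.9,
}


class TestParameters:
    def test_preset_matches_published_values(self, params):
        for name, value in PUBLISHED_DEFAULTS.items():
            assert getattr(params, name) == value

    @pytest.mark.parametrize(
        "bad", [{"k_a": -1.0}, {"k_B": 0.0}, {"k_s": -0.5}, {"k_br": 0.0}]
    )
    def test_invalid_constants_rejected(self, bad):
        with pytest.raises(ValueError):
            ModelParameters(**bad)

    def test_unknown_override_rejected(self, params):
        with pytest.raises(ValueError, match="k_zz"):
            params.with_(k_zz=1.0)

    def test_with_returns_new_immutable_object(self, params):
        p2 = params.with_(k_Bo=200.0)
        assert p2.k_Bo == 200.0 and params.k_Bo == 130.0
        with pytest.raises(AttributeError):
            params.k_a = 1.0

    def test_extrema_over_rate_constants(self, params):
        vals = [v for n, v in params.to_dict().items() if n != "k_Bo"]
        assert params.u == max(vals) and params.d == min(vals) > 0


class TestRhs:
    def test_inflammatory_components_vanish_at_reported_inflamed_state(self, params):
        # the N, R, T, L equations do not involve the lumen butyrate drive,
        # so they must vanish at the reported equilibrium regardless of k_Bo
        f = rhs(INFLAMED_STATE, params, "core")
        assert np.all(np.abs(f[:4]) < 1e-4)

    def test_drive_balancing_the_butyrate_equation(self, params):
        # solving dB/dt = 0 for the drive at the reported inflamed state
        N, R, T, L, B = INFLAMED_STATE
        k_Bo = params.k_B * B / (params.k_bt**2 / (T**2 + params.k_bt**2) + params.k_d)
        assert 129.0 <= k_Bo <= 131.0
        f = rhs(INFLAMED_STATE, params.with_(k_Bo=k_Bo), "core")
        assert abs(f[4]) < 1e-9

    def test_zero_hill_numerators(self, params):
        # with T = 0 and N = 0 both production Hill terms vanish and
        # repressor production needs N
        f = rhs(np.array([0.0, 0.0, 0.0, 0.0, 1.0]), params, "core")
        assert f[0] == 0.0 and f[1] == 0.0

    def test_variant_dimensions(self, params):
        assert rhs(np.zeros(4), params, "base").shape == (4,)
        with pytest.raises(ValueError):
            rhs(np.zeros(4), params, "core")
        with pytest.raises(ValueError):
            rhs(np.zeros(5), params, "base")

    @pytest.mark.parametrize(
        "state", [[-0.1, 1, 1, 1, 1], [1.2, 1, 1, 1, 1], [0.5, -1, 1, 1, 1]]
    )
    def test_inadmissible_states_rejected(self, params, state):
        with pytest.raises(ValueError):
            rhs(np.array(state, dtype=float), params, "core")

    def test_extended_transporter_suppressed_at_low_butyrate(self, params):
        # the cooperative factor B^2/(B^2+k_2B^2) throttles the transporter
        # at low B, so extended inflow is below core inflow there
        x = np.array([0.1, 1.0, 5.0, 0.3, 1.0])
        assert rhs(x, params, "extended")[4] < rhs(x, params, "core")[4]


class TestJacobian:
    @pytest.mark.parametrize("variant", ["base", "core", "extended"])
    def test_matches_finite_differences(self, params, variant):
        rng = np.random.default_rng(7)
        n = state_dim(variant)
        for _ in range(20):
            x = np.empty(n)
            x[0] = rng.uniform(0.01, 0.95)
            x[1:] = rng.uniform(0.1, 30.0, size=n - 1)
            J = jacobian(x, params, variant)
            J_fd = np.empty_like(J)
            for j in range(n):
                h = 1e-6 * max(1.0, abs(x[j]))
                e = np.zeros(n)
                e[j] = h
                J_fd[:, j] = (
                    rhs(x + e, params, variant, check=False)
                    - rhs(x - e, params, variant, check=False)
                ) / (2 * h)
            scale = np.maximum(np.abs(J_fd), 1.0)
            assert np.max(np.abs(J - J_fd) / scale) < 1e-5

    def test_cubic_hill_is_flat_at_origin(self, params):
        J = jacobian(np.array([0.5, 1.0, 0.0, 1.0, 1.0]), params, "core")
        assert J[0, 2] == 0.0

    def test_repressor_row_is_linear(self, params):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = np.abs(rng.uniform(0, 1, 5))
            row = jacobian(x, params, "core")[1]
            assert np.allclose(row, [params.k_b, -params.k_br, 0.0, 0.0, 0.0])

    @pytest.mark.parametrize("name", ["k_Bo", "k_bl", "k_a"])
    def test_parameter_derivative_matches_finite_differences(self, params, name):
        x = np.array([0.2, 1.5, 8.0, 0.3, 7.0])
        d = rhs_param_derivative(x, params, "core", name)
        h = 1e-6 * max(1.0, getattr(params, name))
        fd = (
            rhs(x, params.with_(**{name: getattr(params, name) + h}), "core")
            - rhs(x, params.with_(**{name: getattr(params, name) - h}), "core")
        ) / (2 * h)
        assert np.allclose(d, fd, rtol=1e-6, atol=1e-9)


@settings(max_examples=50, deadline=None)
@given(
    N=st.floats(0.0, 1.0),
    R=st.floats(0.0, 100.0),
    T=st.floats(0.0, 100.0),
    L=st.floats(0.0, 10.0),
    B=st.floats(0.0, 200.0),
)
def test_rhs_finite_and_bound_preserving_on_admissible_states(N, R, T, L, B):
    """The vector field is finite everywhere in the admissible box and
    points inward on the N in {0, 1} boundaries."""
    p = preset("fig2a")
    x = np.array([N, R, T, L, B])
    f = rhs(x, p, "core")
    assert np.all(np.isfinite(f))
    if N == 0.0:
        assert f[0] >= 0.0
    if N == 1.0:
        assert f[0] <= 0.0
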
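"""Unit tests for the column model: sigmoid, impulse response, dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from laminarcfc.model import (
    ColumnModel,
    ModelState,
    POPULATION_ORDER,
    PopulationSpec,
    SigmoidParams,
    default_column_model,
    impulse_response,
    load_model,
    natural_frequency,
    rhs,
    sigmoid,
    sigmoid_derivative,
    three_population_chain,
)


class TestSigmoid:
    def test_half_maximum_at_v0(self):
        p = SigmoidParams(e0=5.0, v0=6.0, r=0.56)
        assert sigmoid(6.0, p) == pytest.approx(2.5)

    def test_closed_form_value(self):
        # S(7) = e0 / (1 + exp(r (v0 - 7))) = 5 / (1 + e^{-0.56})
        p = SigmoidParams(e0=5.0, v0=6.0, r=0.56)
        assert sigmoid(7.0, p) == pytest.approx(5.0 / (1.0 + math.exp(-0.56)))

    def test_saturation_limits(self):
        p = SigmoidParams()
        assert sigmoid(1e6, p) == pytest.approx(p.e0)
        assert sigmoid(-1e6, p) == pytest.approx(0.0, abs=1e-12)

    def test_no_overflow_at_extreme_hyperpolarization(self):
        assert np.isfinite(sigmoid(-1e9))

    @given(st.floats(-50, 50), st.floats(-50, 50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_increasing(self, a, b):
        lo, hi = min(a, b), max(a, b)
        assert sigmoid(lo) <= sigmoid(hi) + 1e-15

    def test_derivative_matches_finite_difference(self):
        p = SigmoidParams()
        x = np.linspace(-5, 20, 41)
        h = 1e-6
        fd = (sigmoid(x + h, p) - sigmoid(x - h, p)) / (2 * h)
        assert np.allclose(sigmoid_derivative(x, p), fd, atol=1e-7)

    def test_rejects_nonpositive_parameters(self):
        with pytest.raises(ValueError):
            SigmoidParams(e0=-1.0)
        with pytest.raises(ValueError):
            SigmoidParams(r=0.0)


class TestImpulseResponse:
    def test_peak_location_and_value(self):
        G, g = 3.25, 100.0
        t = np.linspace(0, 0.2, 20001)
        h = impulse_response(t, G, g)
        assert t[np.argmax(h)] == pytest.approx(1.0 / g, abs=1e-4)
        assert h.max() == pytest.approx(G / math.e, rel=1e-6)

    def test_integral_equals_G_over_g(self):
        # independent oracle: analytic integral of G g t e^{-g t} over [0, inf)
        G, g = 2.0, 50.0
        t = np.linspace(0, 1.0, 200001)
        area = np.trapezoid(impulse_response(t, G, g), t)
        assert area == pytest.approx(G / g, rel=1e-4)

    def test_zero_at_origin_and_negative_rejected(self):
        assert impulse_response(0.0, 1.0, 100.0) == 0.0
        with pytest.raises(ValueError):
            impulse_response(np.array([-0.1, 0.1]), 1.0, 100.0)


class TestNaturalFrequency:
    def test_underdamped_formula(self):
        pop = PopulationSpec("P1", "L4", "RS", G=3.25, g=2 * math.pi * 10, b=0.6)
        assert natural_frequency(pop) == pytest.approx(10 * math.sqrt(1 - 0.36))

    def test_overdamped_returns_none(self):
        pop = PopulationSpec("P1", "L4", "RS", G=3.25, g=100.0, b=1.0)
        assert natural_frequency(pop) is None


class TestColumnModel:
    def test_default_model_has_14_populations_in_canonical_order(self):
        m = default_column_model()
        assert m.n == 14
        assert tuple(m.names) == POPULATION_ORDER

    def test_sign_structure_of_gamma(self):
        m = default_column_model()
        for i, pop in enumerate(m.populations):
            row = m.gamma[i]
            if pop.excitatory:
                assert np.all(row >= 0), pop.name
            else:
                assert np.all(row <= 0), pop.name

    def test_l4fs_self_connection_present(self):
        m = default_column_model()
        i = m.names.index("L4FS")
        assert m.gamma[i, i] != 0.0

    def test_rejects_wrong_sign(self):
        m = default_column_model()
        bad = m.gamma.copy()
        i = m.names.index("L4LTS")
        bad[i, 0] = 5.0  # inhibitory source with positive weight
        with pytest.raises(ValueError):
            ColumnModel(m.populations, bad)

    def test_rejects_wrong_shape(self):
        m = default_column_model()
        with pytest.raises(ValueError):
            ColumnModel(m.populations, np.zeros((3, 3)))

    def test_fixed_point_uncoupled(self):
        # x* = G p / g: with G=3.25, g=100, p=120 -> 3.9 mV
        pop = PopulationSpec("P1", "L4", "RS", G=3.25, g=100.0, b=0.5, p_mean=120.0)
        m = ColumnModel([pop], np.zeros((1, 1)))
        assert m.fixed_point_uncoupled()[0] == pytest.approx(3.9)

    def test_rhs_zero_at_fixed_point_when_uncoupled(self):
        pop = PopulationSpec("P1", "L4", "RS", G=3.25, g=100.0, b=0.5, p_mean=120.0)
        m = ColumnModel([pop], np.zeros((1, 1)))
        state = ModelState(x=m.fixed_point_uncoupled(), y=np.zeros(1))
        d = rhs(state, m, m.vector("p_mean"))
        assert np.allclose(d.x, 0.0) and np.allclose(d.y, 0.0)

    def test_rhs_matches_componentwise_equations(self):
        # duplicate implementation oracle: scalar loop over the published form
        m = three_population_chain()
        rng = np.random.default_rng(0)
        x = rng.normal(4, 2, 3)
        y = rng.normal(0, 10, 3)
        p = rng.uniform(50, 200, 3)
        d = rhs(ModelState(x=x, y=y), m, p)
        for k, pop in enumerate(m.populations):
            drive = sum(
                m.gamma[n, k] * sigmoid(x[n], m.populations[n].sigmoid)
                for n in range(3)
            )
            expected = (
                -2 * pop.g * pop.b * y[k]
                - pop.g**2 * x[k]
                + pop.G * pop.g * (p[k] + drive)
            )
            assert d.y[k] == pytest.approx(expected, rel=1e-12)
        assert np.array_equal(d.x, y)

    def test_linear_model_firing_rate_is_identity(self):
        m = three_population_chain()
        lin = ColumnModel(m.populations, m.gamma, linear=True)
        x = np.array([1.0, -2.0, 7.5])
        assert np.array_equal(lin.firing_rate(x), x)
        assert np.array_equal(lin.firing_rate_derivative(x), np.ones(3))

    def test_drift_jacobian_matches_finite_difference(self):
        m = three_population_chain()
        x0 = np.array([3.0, 4.0, 5.0])
        y0 = np.array([1.0, -1.0, 0.5])
        p = m.vector("p_mean")

        def drift(z):
            s = ModelState(x=z[:3], y=z[3:])
            d = rhs(s, m, p)
            return np.concatenate([d.x, d.y])

        z0 = np.concatenate([x0, y0])
        J = m.drift_jacobian(x0)
        h = 1e-6
        for j in range(6):
            e = np.zeros(6)
            e[j] = h
            col = (drift(z0 + e) - drift(z0 - e)) / (2 * h)
            assert np.allclose(J[:, j], col, atol=1e-3), j

    def test_serialization_round_trip(self, tmp_path):
        m = default_column_model()
        path = tmp_path / "model.json"
        m.save(path)
        m2 = load_model(path)
        assert m2.names == m.names
        assert np.array_equal(m2.gamma, m.gamma)
        assert m2.populations[0].g == pytest.approx(m.populations[0].g)

    def test_gamma_csv_round_trip(self, tmp_path):
        m = default_column_model()
        path = tmp_path / "gamma.csv"
        m.save_gamma_csv(path)
        m2 = m.with_gamma_csv(path)
        assert np.allclose(m2.gamma, m.gamma)


class TestThreePopulationChain:
    def test_architecture(self):
        m = three_population_chain()
        g = m.gamma
        assert g[1, 0] > 0 and g[1, 2] > 0  # 2 -> 1, 2 -> 3
        assert g[0, 2] == 0 and g[2, 0] == 0  # no 1 <-> 3
        assert g[0, 1] == 0 and g[2, 1] == 0  # no feedback into 2

    def test_population_count_and_state_dimension(self):
        m = three_population_chain()
        assert m.n == 3
        assert m.drift_jacobian(np.zeros(3)).shape == (6, 6)

    def test_driven_populations_have_self_connections(self):
        m = three_population_chain()
        assert m.gamma[0, 0] > 0 and m.gamma[2, 2] > 0
        assert m.gamma[1, 1] == 0

    def test_coupled_fixed_point_at_operating_point(self):
        # the drive is solved so x* = operating_point is a fixed point of the
        # coupled system: rhs must vanish there
        xstar = 3.6
        m = three_population_chain(operating_point=xstar)
        state = ModelState(x=np.full(3, xstar), y=np.zeros(3))
        d = rhs(state, m, m.vector("p_mean"))
        assert np.allclose(d.x, 0.0, atol=1e-9)
        assert np.allclose(d.y, 0.0, atol=1e-8)

    def test_effective_frequency_at_operating_point(self):
        # linearized around x*, the oscillation frequency (imaginary part of
        # the Jacobian eigenvalues / 2 pi) must equal the nominal band values
        xstar = 3.6
        m = three_population_chain(operating_point=xstar)
        J = m.drift_jacobian(np.full(3, xstar))
        freqs = np.sort(np.unique(np.round(
            np.abs(np.linalg.eigvals(J).imag) / (2 * np.pi), 1
        )))
        for f in (4.4, 50.0, 57.8):
            assert np.any(np.abs(freqs - f) < 0.5), (f, freqs)

    def test_zero_self_coupling_recovers_linear_targets(self):
        m = three_population_chain(self_coupling=0.0)
        assert m.gamma[0, 0] == 0 and m.gamma[2, 2] == 0
        # g then reduces to the plain underdamped formula
        for pop, f in zip(m.populations, (50.0, 4.4, 57.8)):
            assert pop.g == pytest.approx(
                2 * np.pi * f / np.sqrt(1 - pop.b**2), rel=1e-9
            )

    def test_explicit_p_mean_override(self):
        m = three_population_chain(p_mean=120.0)
        assert all(p.p_mean == 120.0 for p in m.populations)
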
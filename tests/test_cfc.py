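"""Information-theoretic coupling estimators: exact discrete oracles,
closed-form Midx/ESC examples, and integration on planted-PAC signals."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from laminarcfc.cfc import (
    COUPLING_FEATURES,
    CFCResult,
    CouplingSpec,
    DiscretizationScheme,
    conditional_mutual_information,
    conditional_mutual_information_knn,
    conditional_transfer_entropy,
    discretize,
    entropy_bits,
    esc,
    estimate_cfc,
    modulation_index,
    mutual_information,
)
from laminarcfc.signals import BandDefinition, decompose
from laminarcfc.synthetic import XOR_TABLE, am_coupled, markov_discrete


class TestDiscretize:
    def test_phase_uniform_bins(self):
        phases = np.array([-np.pi, -np.pi / 2, 0.0, np.pi / 2])
        assert list(discretize(phases, 4, circular=True)) == [0, 1, 2, 3]

    def test_phase_upper_edge_clipped(self):
        codes = discretize(np.array([np.pi - 1e-12]), 8, circular=True)
        assert codes[0] == 7

    def test_quantile_bins_equipopulated(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(4000)
        codes = discretize(x, 4, circular=False)
        _, counts = np.unique(codes, return_counts=True)
        assert counts.size == 4
        assert counts.max() - counts.min() <= 2

    def test_quantile_bins_monotone_in_value(self):
        x = np.array([5.0, -1.0, 2.0, 0.0, 9.0, 3.0, -4.0, 7.0])
        codes = discretize(x, 4, circular=False)
        order = np.argsort(x)
        assert np.all(np.diff(codes[order]) >= 0)


class TestEntropy:
    def test_fair_coin_one_bit(self):
        assert entropy_bits([np.array([0, 1] * 500)]) == pytest.approx(1.0)

    def test_uniform_four_symbols_two_bits(self):
        assert entropy_bits([np.tile(np.arange(4), 100)]) == pytest.approx(2.0)

    def test_constant_zero_bits(self):
        assert entropy_bits([np.zeros(100, dtype=int)]) == pytest.approx(0.0)

    def test_joint_of_independent_adds(self):
        x = np.repeat([0, 1], 4)          # every (x, y) cell equally often
        y = np.tile([0, 1, 2, 3], 2)
        assert entropy_bits([x, y]) == pytest.approx(
            entropy_bits([x]) + entropy_bits([y])
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_histogram_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 3, size=200)
        y = rng.integers(0, 4, size=200)
        # independent oracle: explicit 2-d contingency table
        table = np.zeros((3, 4))
        for a, b in zip(x, y):
            table[a, b] += 1
        p = table.ravel() / table.sum()
        p = p[p > 0]
        assert entropy_bits([x, y]) == pytest.approx(
            float(-(p * np.log2(p)).sum()), abs=1e-12
        )


class TestXorOracle:
    """Z = X xor Y with X, Y iid fair bits: I(X;Y) = 0, I(X;Y|Z) = 1 bit,
    exactly, on a sample whose counts match the joint table exactly."""

    def _xyz(self):
        fix = markov_discrete(XOR_TABLE, n=4096, exact=True)
        return fix.data[:, 0], fix.data[:, 1], fix.data[:, 2]

    def test_marginal_mi_zero(self):
        x, y, _ = self._xyz()
        assert mutual_information(x, [y]) == pytest.approx(0.0, abs=1e-12)

    def test_conditional_mi_one_bit(self):
        x, y, z = self._xyz()
        assert conditional_mutual_information(x, y, [z]) == pytest.approx(1.0, abs=1e-12)

    def test_conditioning_can_create_information(self):
        x, y, z = self._xyz()
        assert (
            conditional_mutual_information(x, y, [z])
            > mutual_information(x, [y]) + 0.5
        )

    def test_mi_of_copy_equals_entropy(self):
        x, _, _ = self._xyz()
        assert mutual_information(x, [x]) == pytest.approx(entropy_bits([x]))


class TestCMIBruteForce:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_matches_triple_table_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 3, size=300)
        y = rng.integers(0, 3, size=300)
        z = rng.integers(0, 2, size=300)
        # oracle: I(x;y|z) = sum_z p(z) * I(x;y | Z=z) from explicit tables
        total = 0.0
        for zv in (0, 1):
            sel = z == zv
            pz = sel.mean()
            if pz == 0:
                continue
            tab = np.zeros((3, 3))
            for a, b in zip(x[sel], y[sel]):
                tab[a, b] += 1
            pxy = tab / tab.sum()
            px = pxy.sum(axis=1, keepdims=True)
            py = pxy.sum(axis=0, keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = pxy * np.log2(pxy / (px * py))
            total += pz * np.nansum(terms)
        assert conditional_mutual_information(x, y, [z]) == pytest.approx(
            total, abs=1e-9
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            conditional_mutual_information(np.zeros(5, int), np.zeros(6, int))
        with pytest.raises(ValueError):
            conditional_mutual_information(
                np.zeros(5, int), np.zeros(5, int), [np.zeros(4, int)]
            )

    def test_nonnegative_on_random_data(self):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 4, 500)
        y = rng.integers(0, 4, 500)
        z = rng.integers(0, 4, 500)
        assert conditional_mutual_information(x, y, [z]) >= -1e-12


class TestKnnEstimator:
    def test_independent_gaussians_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2000)
        y = rng.standard_normal(2000)
        assert abs(conditional_mutual_information_knn(x, y)) < 0.05

    def test_correlated_gaussians_closed_form(self):
        rho = 0.8
        rng = np.random.default_rng(1)
        x = rng.standard_normal(4000)
        y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(4000)
        truth = -0.5 * np.log2(1 - rho**2)
        assert conditional_mutual_information_knn(x, y) == pytest.approx(
            truth, abs=0.08
        )

    def test_conditioning_removes_common_driver(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal(2000)
        x = z + 0.3 * rng.standard_normal(2000)
        y = z + 0.3 * rng.standard_normal(2000)
        marginal = conditional_mutual_information_knn(x, y)
        conditional = conditional_mutual_information_knn(x, y, [z])
        assert conditional < 0.3 * marginal


class TestGaussianCopula:
    def test_transform_margins_standard_normal(self):
        from laminarcfc.cfc import gaussian_copula_transform

        rng = np.random.default_rng(0)
        g = gaussian_copula_transform(rng.exponential(size=5000))
        assert abs(g.mean()) < 0.02
        assert g.std() == pytest.approx(1.0, abs=0.02)

    def test_transform_monotone_invariance(self):
        from laminarcfc.cfc import gaussian_copula_transform

        rng = np.random.default_rng(1)
        x = rng.standard_normal(500)
        assert np.allclose(
            gaussian_copula_transform(x), gaussian_copula_transform(np.exp(x))
        )

    def test_correlated_gaussians_closed_form(self):
        from laminarcfc.cfc import (
            conditional_mutual_information_gaussian,
            gaussian_copula_transform,
        )

        rho = 0.7
        rng = np.random.default_rng(2)
        x = rng.standard_normal(20000)
        y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(20000)
        got = conditional_mutual_information_gaussian(
            gaussian_copula_transform(x)[:, None],
            gaussian_copula_transform(y)[:, None],
        )
        assert got == pytest.approx(-0.5 * np.log2(1 - rho**2), abs=0.02)

    def test_conditioning_explains_away_common_driver(self):
        from laminarcfc.cfc import (
            conditional_mutual_information_gaussian as cmi_g,
            gaussian_copula_transform as gct,
        )

        rng = np.random.default_rng(3)
        z = rng.standard_normal(10000)
        x = z + 0.3 * rng.standard_normal(10000)
        y = z + 0.3 * rng.standard_normal(10000)
        xc, yc, zc = (gct(v)[:, None] for v in (x, y, z))
        assert cmi_g(xc, yc, zc) < 0.1 * cmi_g(xc, yc)

    def test_phase_enters_as_circular_block(self):
        from laminarcfc.cfc import copula_columns

        rng = np.random.default_rng(4)
        phase = rng.uniform(-np.pi, np.pi, 300)
        cols = copula_columns(phase, "phase")
        assert cols.shape == (300, 2)
        assert copula_columns(phase, "amplitude").shape == (300, 1)

    def test_cte_detects_phase_to_amplitude_lag(self):
        from laminarcfc.cfc import conditional_transfer_entropy_gaussian

        # amplitude follows cos(phase) with a 3-sample delay
        rng = np.random.default_rng(5)
        phase = np.angle(
            np.exp(1j * np.cumsum(0.2 + 0.05 * rng.standard_normal(4000)))
        )
        amp = 1 + 0.8 * np.cos(np.roll(phase, 3)) + 0.1 * rng.standard_normal(4000)
        forward = conditional_transfer_entropy_gaussian(phase, amp, n_lags=5)
        shuffled = conditional_transfer_entropy_gaussian(
            rng.permutation(phase), amp, n_lags=5
        )
        assert forward > 10 * max(shuffled, 1e-4)

    def test_cte_validation(self):
        from laminarcfc.cfc import conditional_transfer_entropy_gaussian

        with pytest.raises(ValueError):
            conditional_transfer_entropy_gaussian(np.zeros(5), np.zeros(6))
        with pytest.raises(ValueError):
            conditional_transfer_entropy_gaussian(
                np.arange(5.0), np.arange(5.0), n_lags=5
            )
        with pytest.raises(ValueError):
            conditional_transfer_entropy_gaussian(
                np.arange(50.0), np.arange(50.0) % 7, n_lags=10, lag_step=11
            )


class TestTransferEntropy:
    def test_copy_chain_one_bit(self):
        # y[t] = x[t-1] with x iid fair bits: TE(x->y) at lag 1 is H(x) = 1 bit
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, 8192)
        y = np.roll(x, 1)
        te = conditional_transfer_entropy(x, y, None, n_lags=1)
        assert te == pytest.approx(1.0, abs=0.01)

    def test_direction_sensitivity(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, 8192)
        y = np.roll(x, 1)
        forward = conditional_transfer_entropy(x, y, None, n_lags=1)
        backward = conditional_transfer_entropy(y, x, None, n_lags=1)
        assert forward > backward + 0.9

    def test_conditioning_explains_away_copy(self):
        # y is a copy of z's past; conditioning on z removes all information
        rng = np.random.default_rng(2)
        z = rng.integers(0, 2, 4096)
        y = np.roll(z, 1)
        x = z.copy()  # x carries information about y only through z
        unconditioned = conditional_transfer_entropy(x, y, None, n_lags=1)
        conditioned = conditional_transfer_entropy(x, y, [z[:]], n_lags=1)
        assert unconditioned > 0.9
        assert conditioned < 0.02

    def test_lag_average_equals_mean_of_single_lag_cmis(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 3, 600)
        y = rng.integers(0, 3, 600)
        n_lags = 5
        L = x.size - n_lags
        expected = np.mean([
            conditional_mutual_information(x[:L], y[d:d + L])
            for d in range(1, n_lags + 1)
        ])
        assert conditional_transfer_entropy(x, y, None, n_lags) == pytest.approx(
            expected, abs=1e-12
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            conditional_transfer_entropy(np.zeros(5, int), np.zeros(6, int))
        with pytest.raises(ValueError):
            conditional_transfer_entropy(np.zeros(5, int), np.zeros(5, int), None, 5)


class TestModulationIndex:
    def test_uniform_phases_constant_amplitude_is_zero(self):
        phases = np.linspace(-np.pi, np.pi, 64, endpoint=False)
        assert modulation_index(phases, np.ones(64)) == pytest.approx(0.0, abs=1e-9)

    def test_locked_phases_sum_amplitudes(self):
        amp = np.array([1.0, 2.0, 3.0])
        assert modulation_index(np.zeros(3), amp) == pytest.approx(6.0)

    def test_planted_pac_closed_form(self):
        # a = 1 + m cos(phi), phi uniform on a grid:
        # |sum a e^{i phi}| = m * T / 2 exactly
        T, m = 256, 0.5
        phases = np.linspace(-np.pi, np.pi, T, endpoint=False)
        amp = 1 + m * np.cos(phases)
        assert modulation_index(phases, amp) == pytest.approx(m * T / 2, rel=1e-12)
        assert modulation_index(phases, amp, normalized=True) == pytest.approx(m / 2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            modulation_index(np.zeros(5), np.zeros(4))


class TestESC:
    def test_perfect_coupling(self):
        phases = np.linspace(-np.pi, np.pi, 100, endpoint=False)
        assert esc(phases, 2 + np.cos(phases)) == pytest.approx(1.0)

    def test_anti_coupling(self):
        phases = np.linspace(-np.pi, np.pi, 100, endpoint=False)
        assert esc(phases, 2 - np.cos(phases)) == pytest.approx(-1.0)

    def test_quadrature_uncorrelated(self):
        phases = np.linspace(-np.pi, np.pi, 100, endpoint=False)
        assert esc(phases, 2 + np.sin(phases)) == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            esc(np.zeros(10), np.ones(10))


class TestCouplingSpec:
    def test_feature_mapping(self):
        spec = CouplingSpec("PAC", "theta", "gamma")
        assert spec.source_feature == "phase"
        assert spec.target_feature == "amplitude"
        assert spec.label == "PAC_theta-gamma"

    def test_all_types_have_feature_pairs(self):
        for t, pair in COUPLING_FEATURES.items():
            assert pair[0] in {"phase", "amplitude"}
            assert pair[1] in {"phase", "amplitude", "frequency"}
            CouplingSpec(t, "gamma", "gamma") if t.startswith("SFC") else CouplingSpec(
                t, "theta", "gamma"
            )

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError):
            CouplingSpec("XYZ", "theta", "gamma")

    def test_sfc_band_mismatch_rejected(self):
        with pytest.raises(ValueError):
            CouplingSpec("SFC-amp", "theta", "gamma")

    def test_nonpositive_lags_rejected(self):
        with pytest.raises(ValueError):
            CouplingSpec("PAC", "theta", "gamma", n_lags=0)

    def test_scheme_validation(self):
        with pytest.raises(ValueError):
            DiscretizationScheme(n_bins=1)
        assert DiscretizationScheme(8).cond_bins == 8
        assert DiscretizationScheme(8, conditioning_bins=4).cond_bins == 4


@pytest.fixture(scope="module")
def decomp():
    fix = am_coupled(duration=30.0, seed=0)
    bands = (BandDefinition("theta", 4, 8), BandDefinition("gamma", 30, 120))
    return decompose(fix.data, fix.fs, bands, names=["slow", "fast"])


class TestEstimateCFC:
    def test_planted_pac_dominates(self, decomp):
        spec = CouplingSpec("PAC", "theta", "gamma", n_lags=10)
        res = estimate_cfc(decomp, spec, DiscretizationScheme(8),
                           conditioning_policy="none")
        assert res.values.shape == (2, 2)
        # the planted direction slow->fast should carry the most information
        assert res.values[0, 1] == res.values.max()

    def test_band_order_enforced(self, decomp):
        with pytest.raises(ValueError):
            estimate_cfc(decomp, CouplingSpec("PAC", "gamma", "theta"))
        with pytest.raises(ValueError):
            estimate_cfc(decomp, CouplingSpec("APC", "theta", "gamma"))

    def test_missing_band_rejected(self, decomp):
        with pytest.raises(ValueError):
            estimate_cfc(decomp, CouplingSpec("PAC", "delta", "gamma"))

    def test_values_nonnegative(self, decomp):
        spec = CouplingSpec("AAC", "gamma", "gamma", n_lags=5)
        res = estimate_cfc(decomp, spec, DiscretizationScheme(4),
                           conditioning_policy="target_past")
        assert np.all(res.values >= 0)
        assert res.n_clipped >= 0

    def test_gaussian_backend_planted_pac(self, decomp):
        spec = CouplingSpec("PAC", "theta", "gamma", n_lags=10)
        res = estimate_cfc(
            decomp, spec, conditioning_policy="target_past", estimator="gaussian",
            lag_step=2,
        )
        assert res.meta["estimator"] == "gaussian"
        off_diag = [res.values[0, 1], res.values[1, 0]]
        assert res.values[0, 1] == max(off_diag)
        assert res.values[0, 1] > 0.01

    def test_unknown_estimator_rejected(self, decomp):
        with pytest.raises(ValueError):
            estimate_cfc(
                decomp, CouplingSpec("PAC", "theta", "gamma"), estimator="magic"
            )

    def test_conditioning_keys_policies(self):
        from laminarcfc.cfc import conditioning_keys

        spec = CouplingSpec("PAC", "theta", "gamma")
        assert conditioning_keys(spec, 0, 1, "none", 3) == []
        assert conditioning_keys(spec, 0, 1, "target_past", 3) == [
            ("gamma", 1, "amplitude")
        ]
        ex = conditioning_keys(spec, 0, 1, "exclude_source", 3)
        assert ex[0] == ("gamma", 1, "amplitude")
        assert ("theta", 2, "phase") in ex and ("gamma", 2, "amplitude") in ex
        assert all(key[1] != 0 for key in ex)  # nothing from the source pop
        explicit = conditioning_keys(spec, 0, 1, [("theta", 2, "phase")], 3)
        assert explicit == [("gamma", 1, "amplitude"), ("theta", 2, "phase")]

    def test_csv_round_trip(self, decomp, tmp_path):
        import pandas as pd

        spec = CouplingSpec("PAC", "theta", "gamma", n_lags=5)
        res = estimate_cfc(decomp, spec, DiscretizationScheme(4),
                           conditioning_policy="none")
        path = res.to_csv(tmp_path)
        back = pd.read_csv(path, index_col=0)
        assert np.allclose(back.values, res.values)
        assert path.with_suffix(".json").exists()


class TestGaussianSweep:
    """The FFT shift-sweep must reproduce the per-offset naive estimator
    exactly: same copula scores, same lag structure, same conditioning."""

    @staticmethod
    def _pac_series(T=2500, seed=0):
        rng = np.random.default_rng(seed)
        phase = np.angle(np.exp(1j * (
            2 * np.pi * 6 / 1000 * np.arange(T) + rng.normal(0, 0.05, T).cumsum()
        )))
        amp = 1 + 0.4 * np.cos(np.roll(phase, 5)) + 0.3 * rng.standard_normal(T)
        mediator = np.angle(np.exp(1j * (phase + rng.normal(0, 0.5, T))))
        return phase, amp, mediator

    def test_matches_naive_estimator_per_offset(self):
        from laminarcfc.cfc import (
            conditional_transfer_entropy_gaussian,
            conditional_transfer_entropy_gaussian_sweep,
        )

        phase, amp, mediator = self._pac_series()
        cond = [(amp[::-1].copy(), "amplitude"), (mediator, "phase")]
        offsets = np.array([0, 1, 314, 1200, 2499])
        swept = conditional_transfer_entropy_gaussian_sweep(
            phase, amp, offsets, cond, n_lags=20, lag_step=5
        )
        naive = np.array([
            conditional_transfer_entropy_gaussian(
                np.roll(phase, int(o)), amp, cond, n_lags=20, lag_step=5
            )
            for o in offsets
        ])
        assert np.allclose(swept, naive, atol=1e-10)

    def test_matches_naive_without_conditioning_and_amp_source(self):
        from laminarcfc.cfc import (
            conditional_transfer_entropy_gaussian,
            conditional_transfer_entropy_gaussian_sweep,
        )

        phase, amp, _ = self._pac_series(seed=3)
        offsets = np.array([0, 777])
        swept = conditional_transfer_entropy_gaussian_sweep(
            amp, phase[::-1].copy(), offsets, None, n_lags=8, lag_step=2,
            source_feature="amplitude", target_feature="amplitude",
        )
        naive = np.array([
            conditional_transfer_entropy_gaussian(
                np.roll(amp, int(o)), phase[::-1].copy(), None, n_lags=8,
                lag_step=2, source_feature="amplitude",
                target_feature="amplitude",
            )
            for o in offsets
        ])
        assert np.allclose(swept, naive, atol=1e-10)

    def test_offset_zero_is_observed_and_detects_planted_lag(self):
        from laminarcfc.cfc import conditional_transfer_entropy_gaussian_sweep

        phase, amp, _ = self._pac_series(seed=1)
        rng = np.random.default_rng(9)
        offsets = np.concatenate([[0], rng.integers(250, 2250, 50)])
        vals = conditional_transfer_entropy_gaussian_sweep(
            phase, amp, offsets, [(amp, "amplitude")], n_lags=20, lag_step=5
        )
        z = (vals[0] - vals[1:].mean()) / vals[1:].std(ddof=1)
        assert z > 3.0

    def test_input_validation(self):
        from laminarcfc.cfc import conditional_transfer_entropy_gaussian_sweep

        x = np.random.default_rng(0).standard_normal(100)
        with pytest.raises(ValueError, match="equal length"):
            conditional_transfer_entropy_gaussian_sweep(x, x[:50], np.array([0]))
        with pytest.raises(ValueError, match="n_lags"):
            conditional_transfer_entropy_gaussian_sweep(x, x, np.array([0]), n_lags=100)
        with pytest.raises(ValueError, match="lag_step"):
            conditional_transfer_entropy_gaussian_sweep(
                x, x, np.array([0]), n_lags=10, lag_step=11
            )
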
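"""Discrete Laguerre basis, regressor assembly and OLS kernel estimation."""

import numpy as np
import pytest

from cerebropdm import (KernelCoefficients, LaguerreVolterraModel,
                        UniformSeries, build_regressor_matrix, choose_memory,
                        convolve_basis, count_free_parameters,
                        discrete_laguerre_basis, predict_output,
                        reconstruct_kernels)
from cerebropdm.laguerre import IdentifiabilityWarning, triangular_pairs

from conftest import make_subject


class TestMemoryRule:
    def test_working_point_in_expected_range(self):
        assert 40 <= choose_memory(0.5, 5, 1e-4) <= 80

    def test_impulse_limit_hits_floor(self):
        # as alpha -> 0 the functions collapse to shifted impulses at
        # lags 0..L-1, so the decay rule bottoms out at the L+1 floor
        assert choose_memory(1e-12, 3, 1e-4) == 4

    @pytest.mark.parametrize("eps", [0.0, 1.0, -0.1])
    def test_degenerate_threshold_rejected(self, eps):
        with pytest.raises(ValueError):
            choose_memory(0.5, 5, eps)

    def test_memory_exceeds_function_count(self):
        for alpha in (0.2, 0.5, 0.8):
            assert choose_memory(alpha, 5) >= 6


class TestBasis:
    def test_hand_evaluated_values_at_half(self):
        B = discrete_laguerre_basis(0.5, 2).B
        assert B[0, 1] == pytest.approx(0.5, abs=1e-12)          # b_1(0)
        assert B[0, 0] == pytest.approx(np.sqrt(0.5), abs=1e-12)  # b_0(0)
        assert B[1, 0] == pytest.approx(0.5, abs=1e-12)           # b_0(1)

    @pytest.mark.parametrize("alpha,L", [(0.2, 3), (0.5, 5), (0.8, 4)])
    def test_orthonormal_at_decay_rule_memory(self, alpha, L):
        b = discrete_laguerre_basis(alpha, L)
        gram = b.B.T @ b.B
        assert np.abs(gram - np.eye(L)).max() < 1e-8

    def test_invalid_configuration_rejected(self):
        with pytest.raises(ValueError):
            discrete_laguerre_basis(1.2, 5)
        with pytest.raises(ValueError):
            discrete_laguerre_basis(0.5, 10, M=5)


class TestConvolution:
    def test_impulse_reproduces_basis(self, basis):
        x = np.zeros(basis.M + 20)
        x[0] = 1.0
        v = convolve_basis(basis, x)
        assert np.allclose(v[:basis.M], basis.B)
        assert np.allclose(v[basis.M:], 0.0)

    def test_zero_input_zero_output(self, basis):
        assert not convolve_basis(basis, np.zeros(basis.M)).any()

    def test_step_response_reaches_dc_gain(self, basis):
        # sum over b_0(m) = sqrt(0.5)/(1 - sqrt(0.5)) at alpha = 0.5
        v = convolve_basis(basis, np.ones(3 * basis.M))
        assert v[-1, 0] == pytest.approx(np.sqrt(0.5) / (1 - np.sqrt(0.5)),
                                         abs=1e-4)

    def test_short_series_refused(self, basis):
        with pytest.raises(ValueError):
            convolve_basis(basis, np.zeros(basis.M - 1))


class TestParameterCount:
    @pytest.mark.parametrize("L,expected", [(1, 6), (2, 15), (5, 66)])
    def test_counts(self, L, expected):
        assert count_free_parameters(L) == expected

    def test_invalid_L(self):
        with pytest.raises(ValueError):
            count_free_parameters(0)


class TestRegressorMatrix:
    def test_single_function_layout(self):
        T, M = 30, 4
        rng = np.random.default_rng(0)
        vP = rng.standard_normal((T, 1))
        vC = rng.standard_normal((T, 1))
        V = build_regressor_matrix(vP, vC, M)
        assert V.shape == (T - M + 1, 6)
        s = slice(M - 1, None)
        expected = np.column_stack([
            np.ones(T - M + 1), vP[s, 0], vC[s, 0],
            vP[s, 0] ** 2, vC[s, 0] ** 2, vP[s, 0] * vC[s, 0]])
        assert np.array_equal(V, expected)

    def test_full_model_width(self, basis):
        rng = np.random.default_rng(1)
        vP = rng.standard_normal((200, 5))
        vC = rng.standard_normal((200, 5))
        assert build_regressor_matrix(vP, vC, basis.M).shape[1] == 66

    def test_zero_inputs_leave_only_constant(self):
        V = build_regressor_matrix(np.zeros((20, 2)), np.zeros((20, 2)), 3)
        assert np.array_equal(V[:, 0], np.ones(18))
        assert not V[:, 1:].any()


class TestEstimation:
    def test_noise_free_recovery_exact(self, noisefree_subject):
        rec, system = noisefree_subject
        res = LaguerreVolterraModel.from_recording(rec).fit()
        err = np.abs(res.params - system.beta_true.to_flat()).max()
        assert err < 1e-8
        assert res.nmse < 1e-16

    def test_matches_pseudoinverse_oracle(self, noisefree_subject):
        rec, _ = noisefree_subject
        model = LaguerreVolterraModel.from_recording(rec)
        V, y = model._design()
        beta_oracle = np.linalg.pinv(V) @ y
        res = model.fit()
        assert np.abs(res.params - beta_oracle).max() < 1e-8

    def test_constant_flow_gives_constant_term_only(self):
        rng = np.random.default_rng(3)
        T = 360
        bp = UniformSeries(rng.standard_normal(T), label="bp")
        co2 = UniformSeries(rng.standard_normal(T), label="co2")
        flow = UniformSeries(5.0 + 1e-3 * rng.standard_normal(T),
                             label="flow")
        res = LaguerreVolterraModel(flow, bp, co2, alpha=0.5,
                                    n_laguerre=2).fit()
        assert res.coefficients.k0 == pytest.approx(5.0, abs=0.01)
        assert np.abs(res.params[1:]).max() < 0.01
        assert res.nmse == pytest.approx(1.0, abs=0.35)

    def test_linear_truth_kernel_accuracy_at_10db(self):
        """First-order kernel NMSE < 0.1 in >= 90% of noisy replicates for
        a linear-only ground truth at SNR 10 dB, T = 360."""
        basis = discrete_laguerre_basis(0.5, 5)
        rng = np.random.default_rng(42)
        beta_p = np.array([0.3, 0.2, 0.1, 0.4, 0.6])
        kP_true = basis.B @ beta_p
        ok = 0
        n_rep = 100
        for _ in range(n_rep):
            T = 360
            bp = rng.standard_normal(T)
            co2 = rng.standard_normal(T)
            flow = np.convolve(bp, kP_true)[:T]
            flow += flow.std() * 10 ** (-0.5) * rng.standard_normal(T)
            res = LaguerreVolterraModel(flow, bp, co2, memory=basis.M).fit()
            nmse = np.sum((res.kernels.kP - kP_true) ** 2) / np.sum(kP_true ** 2)
            ok += nmse < 0.1
        assert ok >= 0.9 * n_rep

    def test_self_kernels_exactly_symmetric(self, noisefree_subject):
        rec, _ = noisefree_subject
        kn = LaguerreVolterraModel.from_recording(rec).fit().kernels
        assert np.array_equal(kn.kPP, kn.kPP.T)
        assert np.array_equal(kn.kCC, kn.kCC.T)

    def test_nested_linear_model_never_fits_better(self, noisefree_subject):
        rec, _ = noisefree_subject
        model = LaguerreVolterraModel.from_recording(rec)
        V, y = model._design()
        full_nmse = model.fit().nmse
        L = model.basis.L
        lin = np.linalg.lstsq(V[:, :1 + 2 * L], y, rcond=None)[0]
        resid = y - V[:, :1 + 2 * L] @ lin
        lin_nmse = np.sum(resid ** 2) / np.sum((y - y.mean()) ** 2)
        assert full_nmse <= lin_nmse + 1e-12

    def test_too_few_samples_is_an_error(self):
        rng = np.random.default_rng(5)
        T = 100  # S = T - M + 1 < 66
        with pytest.raises(ValueError, match="unidentifiable"):
            LaguerreVolterraModel(rng.standard_normal(T),
                                  rng.standard_normal(T),
                                  rng.standard_normal(T)).fit()

    def test_undersampled_fit_warns(self):
        rng = np.random.default_rng(6)
        T = 360  # S/K ~ 4.5 < 5
        with pytest.warns(IdentifiabilityWarning):
            LaguerreVolterraModel(rng.standard_normal(T),
                                  rng.standard_normal(T),
                                  rng.standard_normal(T)).fit()


class TestPrediction:
    def test_zero_inputs_yield_constant(self, basis):
        coeffs = KernelCoefficients.from_flat(np.zeros(66), 5)
        kernels = reconstruct_kernels(coeffs, basis)
        out = predict_output(kernels, np.zeros(100), np.zeros(100), k0=3.5)
        assert np.allclose(out.predicted.values, 3.5)

    def test_identity_first_order_kernel(self, basis):
        beta = np.zeros(66)
        coeffs = KernelCoefficients.from_flat(beta, 5)
        kernels = reconstruct_kernels(coeffs, basis)
        kernels.kP[:] = 0.0
        kernels.kP[0] = 1.0  # delta at lag 0
        rng = np.random.default_rng(7)
        x = rng.standard_normal(150)
        out = predict_output(kernels, x, np.zeros(150), k0=0.0)
        assert np.allclose(out.predicted.values, x)

    def test_cross_kernel_diagonal_from_dual_impulses(self, basis):
        coeffs = KernelCoefficients.from_flat(np.zeros(66), 5)
        rng = np.random.default_rng(8)
        coeffs.beta_pc[:] = rng.standard_normal(25)
        kernels = reconstruct_kernels(coeffs, basis)
        n = basis.M
        imp = np.zeros(n)
        imp[0] = 1.0
        out = predict_output(kernels, imp, imp, k0=0.0)
        assert np.allclose(out.predicted.values, np.diag(kernels.kPC))

    def test_two_prediction_paths_agree(self, noisefree_subject):
        """The lagged-tensor evaluation and the Laguerre-regressor path
        must produce the same output to numerical precision."""
        rec, _ = noisefree_subject
        res = LaguerreVolterraModel.from_recording(rec).fit()
        direct = res.predict(observed=rec.flow)
        burn = res.model.burn_in
        assert np.abs(direct.predicted.values[burn:]
                      - res.fittedvalues).max() < 1e-8


def test_triangular_ordering_is_lexicographic():
    assert triangular_pairs(3) == [(0, 0), (1, 0), (1, 1),
                                   (2, 0), (2, 1), (2, 2)]
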
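"""Laguerre basis and three-input model estimation against oracles."""

import numpy as np
import pytest

from cortox.exceptions import (
    ConfigurationError,
    DegenerateStatisticError,
    InsufficientDataError,
    ShapeError,
)
from cortox.lek import (
    KernelSet,
    basis_convolve,
    dlf_basis,
    fit_three_input,
    nmse,
    predict,
    select_alpha,
)
from cortox.signals import UniformSignal
from cortox.synthgen import make_latent_input, synthesize_output

from conftest import make_in_span_system, make_io_record


# ------------------------------------------------------------------ basis

class TestBasis:
    def test_b0_closed_form(self):
        b = dlf_basis(0.25, 2, 50)
        assert b.B[0, 0] == pytest.approx(np.sqrt(0.75), abs=1e-12)
        assert b.B[1, 0] == pytest.approx(np.sqrt(0.25) * np.sqrt(0.75), abs=1e-12)
        # geometric series: sum b0(n)^2 = 1 for any alpha
        for alpha in (0.1, 0.5, 0.9):
            b = dlf_basis(alpha, 1, 2000)
            assert np.sum(b.B[:, 0] ** 2) == pytest.approx(1.0, abs=1e-10)

    def test_gram_matrix_identity_brute_force(self):
        """Columns orthonormal over a memory far past the decay time."""
        b = dlf_basis(0.5, 4, 200)
        gram = np.array([[sum(b.B[m, i] * b.B[m, j] for m in range(201))
                          for j in range(4)] for i in range(4)])
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-6)

    def test_memory_covers_decay(self):
        """Tail negligible when M*dt far exceeds the basis decay time."""
        b = dlf_basis(0.8, 4, 200)
        tail = np.abs(b.B[-1, :])
        peak = np.abs(b.B).max(axis=0)
        assert np.all(tail < 0.01 * peak)

    def test_invalid_parameters_rejected(self):
        for alpha in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ConfigurationError):
                dlf_basis(alpha, 4, 200)
        with pytest.raises(ConfigurationError):
            dlf_basis(0.5, 0, 200)
        with pytest.raises(ConfigurationError):
            dlf_basis(0.5, 10, 5)


# ------------------------------------------------------------------ regressors

class TestBasisConvolve:
    def test_impulse_input_returns_basis_functions(self):
        b = dlf_basis(0.6, 4, 50)
        x = np.zeros(200)
        x[0] = 1.0
        V = basis_convolve(x, b)
        np.testing.assert_allclose(V[:51], b.B, atol=1e-14)
        np.testing.assert_allclose(V[51:], 0.0, atol=1e-14)

    def test_step_input_returns_cumulative_sums(self):
        b = dlf_basis(0.6, 3, 50)
        V = basis_convolve(np.ones(200), b)
        expected = np.cumsum(b.B, axis=0)
        np.testing.assert_allclose(V[:51], expected, atol=1e-12)

    def test_matches_direct_convolution_oracle(self, rng):
        b = dlf_basis(0.7, 4, 60)
        x = rng.normal(size=300)
        V = basis_convolve(x, b)
        for j in range(4):
            direct = np.array([
                sum(b.B[m, j] * x[t - m] for m in range(min(t, 60) + 1))
                for t in range(300)])
            np.testing.assert_allclose(V[:, j], direct, atol=1e-10)

    def test_short_input_rejected(self):
        b = dlf_basis(0.5, 4, 200)
        with pytest.raises(InsufficientDataError):
            basis_convolve(np.zeros(100), b)


# ------------------------------------------------------------------ fitting

class TestFit:
    def test_noiseless_in_span_recovery(self, rng):
        """Exact coefficient recovery and ~zero NMSE without noise."""
        basis, coeffs, kernels = make_in_span_system(rng)
        inputs, output = make_io_record(rng, kernels)
        fit = fit_three_input(*inputs, output, basis)
        for name, c in zip(("abp", "co2", "cfv"), coeffs):
            np.testing.assert_allclose(fit.coefficients.coeffs(name), c, atol=1e-8)
        assert fit.nmse_pct < 1e-10
        assert fit.kernels.k0 == pytest.approx(kernels.k0, abs=1e-8)

    def test_constant_output_yields_k0_and_zero_kernels(self, rng):
        inputs = [make_latent_input(300, 0.25, 0.01, 0.15, 1.0, rng)
                  for _ in range(3)]
        y = UniformSignal(0.0, 0.25, np.full(1200, 5.0))
        fit = fit_three_input(*inputs, y, dlf_basis(0.9, 4, 200))
        assert fit.kernels.k0 == pytest.approx(5.0, abs=1e-6)
        for name in ("abp", "co2", "cfv"):
            assert np.abs(fit.kernels.kernel(name)).max() < 1e-6

    def test_residuals_orthogonal_to_regressors(self, rng):
        basis, _, kernels = make_in_span_system(rng)
        inputs, output = make_io_record(rng, kernels, noise_nmse_pct=30.0)
        fit = fit_three_input(*inputs, output, basis)
        y_hat = predict(fit, *inputs)
        M = basis.M
        resid = output.values[M:] - y_hat.values[M:]
        for sig in inputs:
            V = basis_convolve(sig, basis)[M:]
            for j in range(V.shape[1]):
                v = V[:, j]
                assert abs(resid @ v) < 1e-6 * np.linalg.norm(resid) * np.linalg.norm(v)

    def test_full_basis_equals_direct_fir_least_squares(self, rng):
        """With L = M+1 the Laguerre fit equals an unrestricted FIR fit."""
        M, N, dt = 20, 400, 0.25
        raw = dlf_basis(0.5, M + 1, M)
        # orthonormalize over the finite lag window: truncation makes the
        # highest-order functions nearly dependent on 0..M alone
        Q, _ = np.linalg.qr(raw.B)
        from cortox.lek import LaguerreBasis
        basis = LaguerreBasis(alpha=0.5, L=M + 1, M=M, B=Q)
        true_k = rng.normal(size=M + 1) * np.exp(-np.arange(M + 1) / 6)
        kernels = KernelSet(dt=dt, k0=1.0, k_abp=true_k,
                            k_co2=rng.normal(size=M + 1) * 0.2,
                            k_cfv=np.zeros(M + 1))
        inputs = [UniformSignal(0.0, dt, rng.normal(size=N)) for _ in range(3)]
        output = synthesize_output(inputs, kernels, 10.0, rng)
        fit = fit_three_input(*inputs, output, basis)
        # direct FIR regression oracle
        X = [s.values for s in inputs]
        cols = [np.ones(N)]
        for x in X:
            for m in range(M + 1):
                col = np.zeros(N)
                col[m:] = x[:N - m]
                cols.append(col)
        A = np.column_stack(cols)[M:]
        beta, *_ = np.linalg.lstsq(A, output.values[M:], rcond=None)
        fir = beta[1:1 + (M + 1)]
        np.testing.assert_allclose(fit.kernels.k_abp, fir, atol=1e-6)

    def test_recovery_error_decreases_as_noise_vanishes(self, rng):
        basis, _, kernels = make_in_span_system(rng)
        errors = []
        for noise in (40.0, 10.0, 1.0, 0.0):
            err = 0.0
            for seed in range(3):
                r = np.random.default_rng(1000 + seed)
                inputs, output = make_io_record(r, kernels, noise_nmse_pct=noise)
                fit = fit_three_input(*inputs, output, basis)
                err += np.linalg.norm(fit.kernels.k_co2 - kernels.k_co2)
            errors.append(err)
        assert errors == sorted(errors, reverse=True)

    def test_length_mismatch_rejected(self, rng):
        basis = dlf_basis(0.5, 2, 20)
        a = np.zeros(100)
        with pytest.raises(ShapeError):
            fit_three_input(a, a, a, np.zeros(90), basis, dt=0.25)


# ------------------------------------------------------------------ prediction

class TestPredict:
    def test_zero_inputs_give_constant_k0(self, rng):
        _, _, kernels = make_in_span_system(rng, k0=3.5)
        zero = UniformSignal(0.0, 0.25, np.zeros(800))
        out = predict(kernels, zero, zero, zero)
        np.testing.assert_allclose(out.values, 3.5, atol=1e-12)

    def test_linearity_in_inputs(self, rng):
        _, _, kernels = make_in_span_system(rng, k0=2.0)
        inputs, _ = make_io_record(rng, kernels)
        base = predict(kernels, *inputs).values
        doubled = predict(kernels, *[s.with_values(2 * s.values) for s in inputs]).values
        np.testing.assert_allclose(doubled - kernels.k0, 2 * (base - kernels.k0),
                                   atol=1e-10)

    def test_matches_brute_force_convolution(self, rng):
        _, _, kernels = make_in_span_system(rng, M=40)
        inputs, _ = make_io_record(rng, kernels, duration_s=40.0)
        out = predict(kernels, *inputs).values
        arrays = [s.values for s in inputs]
        n = arrays[0].size
        expected = np.full(n, kernels.k0)
        for a, k in zip(arrays, (kernels.k_abp, kernels.k_co2, kernels.k_cfv)):
            for t in range(n):
                expected[t] += sum(k[m] * a[t - m]
                                   for m in range(min(t, k.size - 1) + 1))
        np.testing.assert_allclose(out, expected, atol=1e-10)


# ------------------------------------------------------------------ NMSE

class TestNmse:
    def test_perfect_prediction_zero(self, rng):
        y = rng.normal(size=100)
        assert nmse(y, y) == 0.0

    def test_mean_prediction_is_100(self, rng):
        y = rng.normal(size=100)
        assert nmse(y, np.full(100, y.mean())) == pytest.approx(100.0)

    def test_constructed_error_ratio(self, rng):
        """Error with a quarter of the output's deviation power -> 25%."""
        y = rng.normal(size=500)
        e = rng.normal(size=500)
        dev = np.sum((y - y.mean()) ** 2)
        e *= np.sqrt(0.25 * dev / np.sum(e ** 2))
        assert nmse(y, y + e) == pytest.approx(25.0, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateStatisticError):
            nmse(np.ones(10), np.zeros(10))


# ------------------------------------------------------------------ alpha selection

class TestSelectAlpha:
    def test_single_point_grid_returned(self, rng):
        basis, _, kernels = make_in_span_system(rng, alpha=0.8)
        inputs, output = make_io_record(rng, kernels)
        alpha, _ = select_alpha(*inputs, output, [0.55], L=4, M=200)
        assert alpha == 0.55

    def test_recovers_generating_alpha_noiseless(self, rng):
        basis, _, kernels = make_in_span_system(rng, alpha=0.9)
        inputs, output = make_io_record(rng, kernels)
        alpha, fit = select_alpha(*inputs, output, [0.7, 0.8, 0.9, 0.95], L=4, M=200)
        assert alpha == 0.9
        assert fit.nmse_pct < 1e-10

    def test_argmin_contract(self, rng):
        basis, _, kernels = make_in_span_system(rng)
        inputs, output = make_io_record(rng, kernels, noise_nmse_pct=30.0)
        grid = [0.6, 0.75, 0.9]
        _, best = select_alpha(*inputs, output, grid, L=4, M=200)
        for a in grid:
            fit = fit_three_input(*inputs, output, dlf_basis(a, 4, 200))
            assert best.nmse_pct <= fit.nmse_pct + 1e-12

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            select_alpha(np.zeros(300), np.zeros(300), np.zeros(300),
                         np.zeros(300), [], L=4, M=50, dt=0.25)
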
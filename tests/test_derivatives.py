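import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ratdyn import (DerivativePolicy, apply_policy, benchmark_spec,
                    choose_tvr_alpha, differentiate, estimate_noise_sd,
                    finite_difference, simulate, truncate_edges, tvregdiff)
from ratdyn.models import Dataset


class TestFiniteDifference:
    def test_constant_series_gives_zero(self):
        y = np.full(20, 3.7)
        np.testing.assert_allclose(finite_difference(y, 0.5), 0.0, atol=1e-14)

    def test_linear_ramp_is_exact(self):
        y = 2.0 * np.arange(30) * 0.1
        np.testing.assert_allclose(finite_difference(y, 0.1), 2.0, rtol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(a=st.floats(-5, 5), b=st.floats(-5, 5), c=st.floats(-5, 5))
    def test_exact_on_interior_for_quadratics(self, a, b, c):
        t = 0.2 * np.arange(15)
        y = a * t**2 + b * t + c
        u = finite_difference(y, 0.2)
        np.testing.assert_allclose(u[1:-1], 2 * a * t[1:-1] + b,
                                   rtol=1e-9, atol=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="5 samples"):
            finite_difference(np.ones(4), 0.1)


class TestTVRegDiff:
    def test_constant_series_gives_zero(self):
        u, ys = tvregdiff(np.full(30, 1.5), 0.1, alpha=1e-3)
        np.testing.assert_allclose(u, 0.0, atol=1e-8)
        np.testing.assert_allclose(ys, 1.5, atol=1e-8)

    def test_sine_derivative_on_central_window(self):
        t = np.arange(0, 2 * np.pi, 0.01)
        u, _ = tvregdiff(np.sin(t), 0.01, alpha=1e-6)
        m = len(t)
        lo, hi = int(0.3 * m), int(0.7 * m)
        assert np.max(np.abs(u[lo:hi] - np.cos(t[lo:hi]))) < 5e-3

    def test_invariant_to_constant_offset(self):
        rng = np.random.default_rng(0)
        y = np.cumsum(rng.standard_normal(40)) * 0.1
        u1, _ = tvregdiff(y, 0.1, alpha=1e-2, iterations=50)
        u2, _ = tvregdiff(y + 100.0, 0.1, alpha=1e-2, iterations=50)
        np.testing.assert_allclose(u1, u2, atol=1e-8)

    def test_reconstruction_integrates_the_derivative(self):
        t = np.arange(0, 3, 0.05)
        y = np.exp(-t)
        u, ys = tvregdiff(y, 0.05, alpha=1e-7)
        np.testing.assert_allclose(ys, y, atol=1e-4)
        assert ys[0] == y[0]


class TestAlphaSelection:
    def test_noise_estimate_recovers_sigma(self):
        rng = np.random.default_rng(3)
        t = np.arange(0, 50, 0.1)
        y = np.sin(0.3 * t) + 0.25 * rng.standard_normal(len(t))
        assert abs(estimate_noise_sd(y) - 0.25) < 0.04

    def test_noise_free_signal_gets_minimal_regularisation(self):
        t = np.arange(0, 5, 0.1)
        # second differences of a linear signal vanish: no detectable noise
        assert choose_tvr_alpha(3.0 - 0.4 * t, 0.1) == pytest.approx(1e-8)

    def test_noisy_signal_gets_stronger_regularisation(self):
        rng = np.random.default_rng(1)
        t = np.arange(0, 5, 0.1)
        y = 10 * np.exp(-t) + 0.1 * rng.standard_normal(len(t))
        assert choose_tvr_alpha(y, 0.1) >= 1e-3


class TestDifferentiate:
    def test_policy_dispatch(self):
        t = np.arange(0, 3, 0.1)
        y = t**2
        u_fd = differentiate(y, 0.1, DerivativePolicy(method="finite_difference"))
        np.testing.assert_allclose(u_fd[1:-1], 2 * t[1:-1], rtol=1e-10)
        u_tv = differentiate(y, 0.1, DerivativePolicy(method="tvregdiff", tvr_alpha=1e-4))
        assert np.max(np.abs(u_tv[5:-5] - 2 * t[5:-5])) < 0.05

    def test_exact_rhs_needs_a_model(self):
        with pytest.raises(ValueError, match="exact_rhs"):
            differentiate(np.arange(10.0), 0.1, DerivativePolicy(method="exact_rhs"))

    def test_nonuniform_grid_rejected(self):
        spec = benchmark_spec("mm", n_trajectories=1, ic_values=[[1.0]])
        ds = simulate(spec, seed=0)
        ds.t = ds.t.copy()
        ds.t[3] += 0.2
        with pytest.raises(ValueError, match="uniform"):
            apply_policy(ds, DerivativePolicy(method="finite_difference"))


class TestApplyPolicy:
    def test_finite_difference_approximates_exact_rhs(self):
        spec = benchmark_spec("mm", dt=0.05, t_span=(0.0, 5.0))
        ds = simulate(spec, seed=0)
        fd = apply_policy(ds, DerivativePolicy(method="finite_difference"))
        assert np.max(np.abs(fd.xdot - ds.xdot)) < 1e-3

    def test_tvregdiff_replaces_states_with_reconstruction(self):
        spec = benchmark_spec("mm", dt=0.1, t_span=(0.0, 5.0))
        ds = simulate(spec, seed=0)
        out = apply_policy(ds, DerivativePolicy(method="tvregdiff", tvr_alpha=1e-6))
        assert out.xdot is not None
        assert not np.array_equal(out.X, ds.X)  # denoised reconstruction
        np.testing.assert_allclose(out.X, ds.X, atol=1e-3)


class TestTruncateEdges:
    def _dataset(self, lengths):
        X, t, tix = [], [], []
        for tr, m in enumerate(lengths):
            X.append(np.arange(m, dtype=float)[:, None] + 100 * tr)
            t.append(np.arange(m, dtype=float))
            tix.append(np.full(m, tr))
        return Dataset(X=np.vstack(X), t=np.concatenate(t), xdot=None,
                       trajectory_index=np.concatenate(tix))

    def test_thirty_percent_of_fifty_keeps_twenty(self):
        ds = self._dataset([50])
        out = truncate_edges(ds, 0.3, 0.3)
        assert out.n_samples == 50 - 15 - 15 == 20

    def test_zero_fractions_are_identity(self):
        ds = self._dataset([17, 23])
        out = truncate_edges(ds, 0.0, 0.0)
        np.testing.assert_array_equal(out.X, ds.X)

    def test_per_trajectory_counts_and_order(self):
        ds = self._dataset([10, 20])
        out = truncate_edges(ds, 0.3, 0.3)
        kept = {tr: len(out.rows_of(tr)) for tr in out.trajectories}
        assert kept == {0: 10 - 3 - 3, 1: 20 - 6 - 6}
        # row order preserved: values still increasing within each trajectory
        for tr in out.trajectories:
            rows = out.X[out.rows_of(tr), 0]
            assert np.all(np.diff(rows) > 0)

    def test_invalid_fractions_rejected(self):
        ds = self._dataset([10])
        with pytest.raises(ValueError):
            truncate_edges(ds, 0.6, 0.0)
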
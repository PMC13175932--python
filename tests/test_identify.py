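import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ratdyn import (NullSpaceOptions, NullVector, build_observational_library,
                    gram, identify_library, library_terms, null_vector,
                    null_vector_gram, sparsify, support_by_gap)
from ratdyn.models import Dataset
from ratdyn.obslib import evaluate_monomials


class TestGram:
    def test_orthonormal_columns_give_identity(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((50, 6)))
        np.testing.assert_allclose(gram(Q), np.eye(6), atol=1e-12)

    def test_shape_reduction(self, rng):
        B = rng.standard_normal((10_000, 10))
        assert gram(B).shape == (10, 10)

    def test_eigenvectors_match_right_singular_vectors(self, rng):
        B = rng.standard_normal((50, 6))
        _, _, vt = np.linalg.svd(B)
        w, V = np.linalg.eigh(gram(B))
        for i in range(6):
            cos = abs(np.dot(vt[5 - i], V[:, i]))
            assert cos > 1 - 1e-10

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gram(np.empty((0, 0)))


class TestNullVector:
    def test_planted_two_column_dependence(self, rng):
        c = rng.standard_normal(40)
        B = np.column_stack([c, 2 * c])
        nv = null_vector(B)
        expected = np.array([2.0, -1.0]) / np.sqrt(5.0)
        np.testing.assert_allclose(nv.xi, expected, atol=1e-12)
        assert nv.xi[np.argmax(np.abs(nv.xi))] > 0  # sign convention

    def test_gram_path_agrees_with_svd_path(self, rng):
        # well-separated null space: oracle equivalence of the two routes
        A = rng.standard_normal((60, 5))
        B = np.hstack([A, (A @ rng.standard_normal(5))[:, None]])
        nv_svd = null_vector(B)
        nv_gram = null_vector_gram(gram(B))
        err = min(np.linalg.norm(nv_svd.xi - nv_gram.xi),
                  np.linalg.norm(nv_svd.xi + nv_gram.xi))
        assert err < 1e-8

    def test_scale_invariance_of_rows(self, rng):
        A = rng.standard_normal((60, 5))
        B = np.hstack([A, (A @ rng.standard_normal(5))[:, None]])
        nv1 = null_vector(B)
        nv2 = null_vector(17.3 * B)
        np.testing.assert_allclose(nv1.xi, nv2.xi, atol=1e-10)

    def test_spectrum_is_descending_and_complete(self, rng):
        B = rng.standard_normal((30, 8))
        nv = null_vector(B)
        assert len(nv.singular_values) == 8
        assert np.all(np.diff(nv.singular_values) <= 0)

    def test_asymmetric_gram_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            null_vector_gram(np.array([[1.0, 2.0], [0.0, 1.0]]))


class TestSparsify:
    def _nv(self, xi):
        xi = np.asarray(xi, dtype=float)
        xi = xi / np.linalg.norm(xi)
        return NullVector(xi=xi, singular_values=np.ones(len(xi)),
                          cluster_size=1, chosen_index=len(xi) - 1)

    def test_tiny_entry_is_zeroed_and_renormalised(self):
        out = sparsify(self._nv([1.0, 1e-9, 0.5]))
        assert out.xi[1] == 0.0
        assert np.linalg.norm(out.xi) == pytest.approx(1.0)
        assert out.support_set == {0, 2}

    def test_large_entries_untouched(self):
        nv = self._nv([0.5, -0.3, 1e-3])
        out = sparsify(nv)
        assert out.support_set == {0, 1, 2}

    def test_all_entries_removed_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            sparsify(self._nv([1.0, 1.0]), lam=2.0)


class TestSupportByGap:
    def test_clear_gap_is_found(self):
        xi = np.array([0.7, 0.5, 1e-4, 5e-5])
        assert set(support_by_gap(xi)) == {0, 1}

    def test_no_gap_keeps_everything(self):
        xi = np.array([0.8, 0.4, 0.2, 0.1])
        assert set(support_by_gap(xi)) == {0, 1, 2, 3}


def _planted_library(rng, num, den, degree, n_points=200, x_range=(0.2, 3.0)):
    """Exact (state, derivative) samples of dx/dt = num(x)/den(x), 1-D."""
    x = rng.uniform(*x_range, n_points)
    terms = library_terms(1, degree)
    half = len(terms) // 2
    theta = evaluate_monomials(x[:, None], terms[:half])
    n_val = theta[:, :len(num)] @ num
    d_val = theta[:, :len(den)] @ den
    u = n_val / d_val
    B = np.hstack([theta, u[:, None] * theta])
    return B, terms, x, u


class TestDegenerateNullSpaces:
    """A library richer than the minimal relation has a multi-dimensional
    null space (every in-degree polynomial multiple of the relation is a null
    vector); the pipeline must still isolate the minimal relation."""

    def test_cluster_dimension_matches_multiplier_count(self, rng):
        # num/den of degree 1 inside a degree-4 library: multipliers 1,x,x^2,x^3
        num, den = np.array([0.6, -0.4]), np.array([0.3, 1.0])
        B, terms, _, _ = _planted_library(rng, num, den, degree=4)
        nv = null_vector(B, [t.key for t in terms])
        assert nv.cluster_size == 4

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        n0=st.floats(0.2, 2.0), n1=st.floats(-2.0, -0.2),
        d0=st.floats(0.2, 2.0), d1=st.floats(0.3, 2.0),
        degree=st.integers(2, 5),
    )
    def test_planted_rational_models_are_recovered_exactly(self, n0, n1, d0, d1, degree):
        """Support and coefficients of random degree-1/1 rational laws are
        recovered from rich libraries to near round-off."""
        rng = np.random.default_rng(7)
        num, den = np.array([n0, n1]), np.array([d0, d1])
        B, terms, _, _ = _planted_library(rng, num, den, degree)
        lib = type("L", (), {"B": B, "terms": terms, "keys": [t.key for t in terms],
                             "n_columns": B.shape[1]})()
        nv = identify_library(lib)
        half = len(terms) // 2
        xi_true = np.zeros(2 * half)
        xi_true[0], xi_true[1] = -num
        xi_true[half], xi_true[half + 1] = den
        xi_true /= np.linalg.norm(xi_true)
        if xi_true[np.argmax(np.abs(xi_true))] < 0:
            xi_true = -xi_true
        assert nv.support_set == {0, 1, half, half + 1}
        assert np.linalg.norm(nv.xi - xi_true) < 1e-10

    def test_two_state_planted_model(self, rng):
        # dx1/dt = (1 - x1 x2) / (0.5 + x2), states sampled freely in 2-D
        X = rng.uniform(0.2, 2.0, (300, 2))
        terms = library_terms(2, 4)
        half = len(terms) // 2
        theta = evaluate_monomials(X, terms[:half])
        u = (1.0 - X[:, 0] * X[:, 1]) / (0.5 + X[:, 1])
        B = np.hstack([theta, u[:, None] * theta])
        lib = type("L", (), {"B": B, "terms": terms, "keys": [t.key for t in terms],
                             "n_columns": B.shape[1]})()
        nv = identify_library(lib)
        names = {terms[i].as_string(["x1", "x2"], 0) for i in nv.support_set}
        assert names == {"1", "x1*x2", "dx1", "x2*dx1"}


class TestIdentifyOnBenchmark:
    def test_mm_support_is_the_four_true_terms(self, mm_dataset):
        lib = build_observational_library(mm_dataset, 0, degree=4)
        nv = identify_library(lib)
        assert nv.support_set == {0, 1, 5, 6}
        assert len(nv.support) == 4

    def test_sign_convention_and_unit_norm(self, mm_dataset):
        lib = build_observational_library(mm_dataset, 0, degree=4)
        nv = identify_library(lib)
        assert np.linalg.norm(nv.xi) == pytest.approx(1.0)
        assert nv.xi[np.argmax(np.abs(nv.xi))] > 0

    def test_row_scale_invariance_end_to_end(self, mm_dataset):
        lib = build_observational_library(mm_dataset, 0, degree=4)
        nv1 = identify_library(lib)
        lib.B = 3.5 * lib.B
        nv2 = identify_library(lib)
        np.testing.assert_allclose(nv1.xi, nv2.xi, atol=1e-12)
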
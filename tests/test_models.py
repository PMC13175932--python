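import numpy as np
import pytest

import ratdyn
from ratdyn import (add_noise, benchmark_spec, implicit_truth, rhs, simulate)
from ratdyn.obslib import evaluate_monomials


def glycolysis_oracle(x, p):
    """Independent term-by-term evaluation of the seven rate equations."""
    x1, x2, x3, x4, x5, x6, x7 = x
    hill = x1 * x6 / (1 + p["c3"] * x6**4)
    return np.array([
        p["c1"] + p["c2"] * hill,
        p["d1"] * hill + p["d3"] * x2 + p["d4"] * x2 * x7,
        p["e1"] * x2 + p["e2"] * x3 + p["e3"] * x2 * x7 + p["e4"] * x3 * x6,
        p["f1"] * x3 + p["f2"] * x4 + p["f3"] * x5 + p["f4"] * x3 * x6 + p["f5"] * x4 * x7,
        p["g1"] * x4 + p["g2"] * x5,
        p["h1"] * hill + p["h3"] * x3 + p["h5"] * x6 + p["h4"] * x3 * x6,
        p["j1"] * x2 + p["j2"] * x2 * x7 + p["j3"] * x4 * x7,
    ])


class TestRhs:
    def test_mm_at_zero_substrate_equals_influx(self):
        assert rhs("mm", [0.0])[0] == pytest.approx(0.6, abs=0)

    def test_mm_equilibrium(self):
        # jx = Vmax x/(Km+x)  =>  0.6(0.3+x) = 1.5x  =>  x = 0.18/0.9 = 0.2
        assert rhs("mm", [0.2])[0] == pytest.approx(0.0, abs=1e-15)

    def test_glycolysis_matches_independent_oracle(self, rng):
        p = ratdyn.default_params("glycolysis")
        for _ in range(20):
            x = rng.uniform(0.05, 2.5, 7)
            np.testing.assert_allclose(rhs("glycolysis", x), glycolysis_oracle(x, p),
                                       rtol=1e-14)

    def test_penicillin_volume_zero_with_feed_raises(self):
        with pytest.raises(ZeroDivisionError):
            rhs("penicillin", [0.1, 10.0, 1.0, 0.0], params={"F": 0.5})

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            rhs("lotka", [1.0])


class TestSimulate:
    def test_mm_row_count(self, mm_dataset):
        # 21 samples per trajectory (both endpoints) x 2 initial conditions
        assert mm_dataset.n_samples == 42

    def test_competence_has_twenty_trajectories(self):
        spec = benchmark_spec("competence")
        assert spec.n_trajectories == 20

    def test_exact_rhs_rows_satisfy_the_model(self, mm_dataset):
        expected = np.array([rhs("mm", row) for row in mm_dataset.X])
        np.testing.assert_array_equal(mm_dataset.xdot, expected)

    def test_reproducible_under_seed(self):
        spec = benchmark_spec("competence", n_trajectories=3, t_span=(0.0, 5.0))
        a = simulate(spec, seed=11)
        b = simulate(spec, seed=11)
        np.testing.assert_array_equal(a.X, b.X)
        np.testing.assert_array_equal(a.xdot, b.xdot)

    def test_integration_failure_names_trajectory(self):
        spec = benchmark_spec("mm", ic_values=[[-0.3]], n_trajectories=1)
        with pytest.raises(RuntimeError, match="trajectory 0"):
            simulate(spec, seed=0)


class TestImplicitTruth:
    @pytest.mark.parametrize(
        "model,k,degree,size",
        [("mm", 0, 4, 4), ("competence", 0, 6, 12), ("competence", 1, 6, 10),
         ("penicillin", 0, 3, 7)],
    )
    def test_support_sizes(self, model, k, degree, size):
        assert len(implicit_truth(model, k, degree).support) == size

    def test_mm_support_terms(self):
        truth = implicit_truth("mm", 0, 4)
        strings = {truth.terms[i].as_string(["x"], 0) for i in truth.support}
        assert strings == {"1", "x", "dx1", "x*dx1"}

    def test_insufficient_degree_raises(self):
        with pytest.raises(ValueError, match="degree"):
            implicit_truth("competence", 1, 4)

    @pytest.mark.parametrize("model,n_traj", [("mm", 2), ("competence", 5),
                                              ("penicillin", 3), ("glycolysis", 3)])
    def test_implicit_identity_holds_pointwise(self, model, n_traj):
        """Substituting (x, rhs(x)) into the implicit polynomial gives ~0."""
        spec = benchmark_spec(model, n_trajectories=n_traj)
        ds = simulate(spec, seed=1)
        for k in ([0] if model == "penicillin" else range(ds.n_states)):
            truth = implicit_truth(model, k, spec.degree)
            half = len(truth.terms) // 2
            sub = ds.X[:, spec.library_states]
            theta = evaluate_monomials(sub, truth.terms[:half])
            resid = theta @ truth.coefficients[:half] \
                + ds.xdot[:, k] * (theta @ truth.coefficients[half:])
            scale = np.max(np.abs(theta) * np.max(np.abs(truth.coefficients)))
            assert np.max(np.abs(resid)) < 1e-10 * scale


class TestAddNoise:
    def test_zero_sigma_is_bitwise_identity(self, mm_dataset):
        noisy = add_noise(mm_dataset, 0.0, seed=4)
        np.testing.assert_array_equal(noisy.X, mm_dataset.X)
        assert noisy.xdot is None  # derivatives always invalidated

    def test_sample_sd_matches_sigma(self):
        spec = benchmark_spec("mm", t_span=(0.0, 2000.0), dt=0.1, n_trajectories=1,
                              ic_values=[[2.0]])
        ds = simulate(spec, seed=0)
        assert ds.n_samples >= 10_000
        noisy = add_noise(ds, 0.1, seed=5)
        sd = np.std(noisy.X - ds.X)
        assert abs(sd - 0.1) < 0.005

    def test_determinism(self, mm_dataset):
        a = add_noise(mm_dataset, 0.2, seed=9)
        b = add_noise(mm_dataset, 0.2, seed=9)
        np.testing.assert_array_equal(a.X, b.X)

    def test_negative_sigma_rejected(self, mm_dataset):
        with pytest.raises(ValueError):
            add_noise(mm_dataset, -0.1)


class TestSerialisation:
    def test_dataset_csv_round_trip(self, mm_dataset, tmp_path):
        path = tmp_path / "mm.csv"
        mm_dataset.to_csv(path)
        back = ratdyn.Dataset.from_csv(path)
        np.testing.assert_allclose(back.X, mm_dataset.X, rtol=1e-12)
        np.testing.assert_allclose(back.xdot, mm_dataset.xdot, rtol=1e-12)
        np.testing.assert_array_equal(back.trajectory_index, mm_dataset.trajectory_index)

    def test_spec_json_round_trip(self, tmp_path):
        spec = benchmark_spec("glycolysis")
        path = tmp_path / "spec.json"
        spec.to_json(path)
        back = ratdyn.BenchmarkSpec.from_json(path)
        assert back.model_id == "glycolysis"
        assert back.n_trajectories == spec.n_trajectories
        np.testing.assert_array_equal(back.ic_low, spec.ic_low)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            benchmark_spec("mm", dt=-1.0)
        with pytest.raises(ValueError):
            benchmark_spec("mm", n_trajectories=0)
        with pytest.raises(ValueError):
            benchmark_spec("mm", library_states=[2])
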
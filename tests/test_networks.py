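import numpy as np
import pytest

from chromaflow import (AffineMap, ColorSet, D65LIKE, DegenerateInputError,
                        NetworkSpec, OPPONENT_ATD, ParameterError, UsageError,
                        apply_marginal_maps, cielab, fit_network,
                        fit_pleistochrome, generate_gaussian_set,
                        generate_natural_like, joint_entropy, kld,
                        opponent_transform, run_network, statistical_benchmark,
                        total_correlation, univariate_entropy, von_kries,
                        webster_clifford)
from chromaflow.experiment import rescale_to_cube
from chromaflow.networks import fit_networks_shared
from chromaflow.synthetic import ALIKE

from conftest import correlated_cov


@pytest.fixture(scope="module")
def lms_set():
    return generate_natural_like(6000, D65LIKE, seed=21)


class TestVonKries:
    def test_unit_white_is_identity(self, lms_set):
        out = von_kries(lms_set, np.ones(3))
        np.testing.assert_array_equal(out.samples, lms_set.samples)
        assert out.space == "LMS_adapted"

    def test_white_maps_to_unit(self, lms_set):
        white = np.array([2.0, 3.0, 4.0])
        cs = ColorSet(np.vstack([white, white * 2]), space="LMS_linear")
        out = von_kries(cs, white)
        np.testing.assert_allclose(out.samples[0], 1.0)

    def test_own_white_aligns_condition_means(self):
        d65 = generate_natural_like(20_000, D65LIKE, seed=30)
        alike = generate_natural_like(20_000, ALIKE, seed=31)
        a = von_kries(d65, d65.samples.mean(axis=0))
        b = von_kries(alike, alike.samples.mean(axis=0))
        assert np.allclose(a.samples.mean(axis=0), b.samples.mean(axis=0),
                           atol=0.05)

    def test_nonpositive_white_rejected(self, lms_set):
        with pytest.raises(ParameterError):
            von_kries(lms_set, np.array([1.0, 0.0, 1.0]))


class TestWebsterClifford:
    def test_self_alignment_is_identity(self, lms_set):
        mean = lms_set.samples.mean(axis=0)
        cov = np.cov(lms_set.samples, rowvar=False)
        out = webster_clifford(lms_set, mean, cov)
        np.testing.assert_allclose(out.samples, lms_set.samples, atol=1e-8)

    def test_moments_match_reference_exactly(self, lms_set):
        ref_mean = np.array([1.0, 2.0, 3.0])
        ref_cov = correlated_cov(0.2)
        out = webster_clifford(lms_set, ref_mean, ref_cov)
        assert np.abs(out.samples.mean(axis=0) - ref_mean).max() < 1e-8
        got_cov = np.cov(out.samples, rowvar=False)
        assert np.abs(got_cov - ref_cov).max() / np.abs(ref_cov).max() < 1e-8

    def test_aligned_gaussians_have_zero_population_kld(self):
        from chromaflow import gaussian_oracle_kld
        a = generate_gaussian_set(5000, [0, 0, 0], correlated_cov(0.5), seed=1)
        b = generate_gaussian_set(5000, [3, 1, 2], np.diag([2.0, 1.0, 0.5]),
                                 seed=2)
        ref_mean, ref_cov = np.zeros(3), np.eye(3)
        out_a = webster_clifford(a, ref_mean, ref_cov)
        out_b = webster_clifford(b, ref_mean, ref_cov)
        d = gaussian_oracle_kld(out_a.samples.mean(0),
                                np.cov(out_a.samples, rowvar=False),
                                out_b.samples.mean(0),
                                np.cov(out_b.samples, rowvar=False))
        assert d == pytest.approx(0.0, abs=1e-10)

    def test_adaptation_reduces_estimated_kld(self):
        d65 = generate_natural_like(8000, D65LIKE, seed=33)
        alike = generate_natural_like(8000, ALIKE, seed=34)
        before = kld(d65.samples, alike.samples).value
        ref = (d65.samples.mean(axis=0), np.cov(d65.samples, rowvar=False))
        after = kld(webster_clifford(d65, *ref).samples,
                    webster_clifford(alike, *ref).samples).value
        assert after < before


class TestOpponentTransform:
    def test_identity_map(self, lms_set):
        out = opponent_transform(lms_set, AffineMap(np.eye(3)))
        np.testing.assert_array_equal(out.samples, lms_set.samples)
        assert out.space == "ATD_linear"

    def test_default_matrix_is_invertible(self):
        assert abs(np.linalg.det(OPPONENT_ATD)) > 1e-3

    def test_rotation_preserves_joint_entropy(self, gaussian_rho06):
        from scipy.stats import special_ortho_group
        cs = gaussian_rho06
        rot = AffineMap(special_ortho_group.rvs(3, random_state=5))
        cs_lms = ColorSet(cs.samples, space="LMS_adapted")
        h0 = joint_entropy(cs.samples)
        h1 = joint_entropy(opponent_transform(cs_lms, rot).samples)
        assert h1.value == pytest.approx(h0.value, abs=0.15)

    def test_pca_rotation_decorrelates_gaussian(self, gaussian_rho06):
        cov = np.cov(gaussian_rho06.samples, rowvar=False)
        _, vecs = np.linalg.eigh(cov)
        cs = ColorSet(gaussian_rho06.samples, space="LMS_adapted")
        out = opponent_transform(cs, AffineMap(vecs.T))
        assert abs(total_correlation(out.samples).value) < 0.1


class TestPleistochrome:
    def test_empirical_cdf_equalizes(self, lms_set):
        from scipy import stats
        atd = opponent_transform(
            ColorSet(lms_set.samples, space="LMS_adapted"))
        m = fit_pleistochrome(atd, "empirical_cdf")
        out = apply_marginal_maps(atd, m)
        for j in range(3):
            d = stats.kstest(out.samples[:, j], "uniform").statistic
            assert d <= 2 / np.sqrt(atd.n)

    def test_uniform_marginals_give_affine_map(self, rng):
        u = ColorSet(rng.uniform(2.0, 5.0, size=(5000, 3)), space="ATD_linear")
        m = fit_pleistochrome(u, "empirical_cdf")
        grid = np.linspace(2.1, 4.9, 100)
        mapped = m.forward(np.column_stack([grid] * 3))
        expected = (grid - 2.0) / 3.0
        assert np.abs(mapped - expected[:, None]).max() <= 3 / np.sqrt(5000)

    def test_exponential_family_recovers_rate(self, rng):
        lam = 2.0
        cs = ColorSet(rng.exponential(1 / lam, size=(5000, 3)),
                      space="ATD_linear")
        m = fit_pleistochrome(cs, "exponential_fit")
        for p in m.params["per_dim"]:
            assert p["tau"] == pytest.approx(1 / lam, rel=0.1)

    def test_equalized_marginals_reach_cube_entropy(self, rng):
        cs = ColorSet(rng.exponential(size=(5000, 3)), space="ATD_linear")
        out = apply_marginal_maps(cs, fit_pleistochrome(cs, "empirical_cdf"))
        flat = rescale_to_cube(out, 10.0)
        for j in range(3):
            h = univariate_entropy(flat.samples[:, j])
            assert h == pytest.approx(np.log2(10), abs=0.1)

    def test_constant_dimension_rejected(self, rng):
        data = rng.random((2000, 3))
        data[:, 1] = 1.0
        with pytest.raises(DegenerateInputError):
            fit_pleistochrome(ColorSet(data, space="ATD_linear"),
                              "empirical_cdf")


class TestApplyMarginalMaps:
    def test_roundtrip_within_domain(self, rng):
        cs = ColorSet(rng.exponential(size=(5000, 3)), space="ATD_linear")
        m = fit_pleistochrome(cs, "empirical_cdf")
        inner = np.clip(cs.samples, np.quantile(cs.samples, 0.01, axis=0),
                        np.quantile(cs.samples, 0.99, axis=0))
        back = m.inverse(m.forward(inner))
        assert np.abs(back - inner).max() < 1e-6

    def test_space_mismatch_rejected(self, rng):
        cs = ColorSet(rng.exponential(size=(2000, 3)), space="ATD_linear")
        m = fit_pleistochrome(cs, "empirical_cdf")
        with pytest.raises(UsageError):
            apply_marginal_maps(ColorSet(cs.samples, space="LMS_adapted"), m)

    def test_total_correlation_invariant(self, gaussian_rho06):
        cs = ColorSet(gaussian_rho06.samples, space="ATD_linear")
        out = apply_marginal_maps(cs, fit_pleistochrome(cs, "empirical_cdf"))
        t0 = total_correlation(cs.samples).value
        t1 = total_correlation(out.samples).value
        assert t1 == pytest.approx(t0, abs=0.15)

    def test_out_of_domain_clamped_and_flagged(self, rng):
        cs = ColorSet(rng.random((2000, 3)), space="ATD_linear")
        m = fit_pleistochrome(cs, "empirical_cdf")
        wild = ColorSet(cs.samples * 10.0, space="ATD_linear")
        out = apply_marginal_maps(wild, m)
        assert out.meta["clamped_rows"] > 0
        assert out.samples.max() <= 1.0 + 1e-12


class TestCielab:
    def test_white_maps_to_L100(self, lms_set):
        white = lms_set.samples.mean(axis=0)
        cs = ColorSet(np.vstack([white, white]), space="LMS_linear")
        out = cielab(cs, white)
        np.testing.assert_allclose(out.samples, [[100, 0, 0]] * 2, atol=1e-9)

    def test_neutral_axis_is_achromatic(self, lms_set):
        white = lms_set.samples.mean(axis=0)
        mults = np.array([0.2, 0.5, 1.0, 1.7])[:, None] * white
        out = cielab(ColorSet(mults, space="LMS_linear"), white)
        np.testing.assert_allclose(out.samples[:, 1:], 0.0, atol=1e-9)

    def test_lightness_monotone_in_luminance(self, lms_set):
        white = lms_set.samples.mean(axis=0)
        mults = np.linspace(0.01, 1.0, 50)[:, None] * white
        out = cielab(ColorSet(mults, space="LMS_linear"), white)
        assert np.all(np.diff(out.samples[:, 0]) > 0)

    def test_nonpositive_white_rejected(self, lms_set):
        with pytest.raises(ParameterError):
            cielab(lms_set, np.zeros(3))


class TestStatisticalBenchmark:
    def test_gaussian_input_decorrelated_and_uniform(self, gaussian_rho06):
        from scipy import stats
        train = ColorSet(gaussian_rho06.samples[:6000], space="LMS_adapted")
        test = ColorSet(gaussian_rho06.samples[6000:], space="LMS_adapted")
        out = statistical_benchmark(train, test)
        assert out.space == "BENCHMARK"
        assert abs(total_correlation(out.samples).value) < 0.1
        for j in range(3):
            d = stats.kstest(out.samples[:, j], "uniform").statistic
            assert d < 3 / np.sqrt(out.n)

    def test_natural_input_entropy_increases(self):
        train = generate_natural_like(8000, D65LIKE, seed=40)
        test = generate_natural_like(4000, D65LIKE, seed=41)
        adapted_train = ColorSet(train.samples, space="LMS_adapted")
        adapted_test = ColorSet(test.samples, space="LMS_adapted")
        out = statistical_benchmark(adapted_train, adapted_test)
        h_in = joint_entropy(rescale_to_cube(adapted_test).samples).value
        h_out = joint_entropy(rescale_to_cube(out).samples).value
        assert h_out > h_in


class TestRunNetwork:
    def test_identity_spec_returns_input_everywhere(self, lms_set):
        spec = NetworkSpec(adaptation="none",
                           opponent_matrix=AffineMap(np.eye(3)),
                           nonlinearity="none")
        train = generate_natural_like(5000, D65LIKE, seed=50)
        layers = run_network(train, lms_set, spec)
        for name in ("r1", "x1", "r2", "x2"):
            np.testing.assert_array_equal(layers[name].samples,
                                          lms_set.samples)

    def test_layers_and_space_tags(self, lms_set):
        train = generate_natural_like(5000, D65LIKE, seed=51)
        layers = run_network(train, lms_set, NetworkSpec())
        assert list(layers) == ["r1", "x1", "r2", "x2"]
        assert [c.space for c in layers.values()] == [
            "LMS_linear", "LMS_adapted", "ATD_linear", "ATD_nonlinear"]

    def test_opponency_reduces_total_correlation(self):
        train = generate_natural_like(20_000, D65LIKE, seed=52)
        test = generate_natural_like(5000, D65LIKE, seed=53)
        layers = run_network(train, test, NetworkSpec(adaptation="von_kries"))
        t_r1 = total_correlation(layers["r1"].samples).value
        t_r2 = total_correlation(layers["r2"].samples).value
        assert t_r2 < t_r1

    def test_train_test_separation(self, lms_set):
        """Perturbing the test set must not change any fitted parameter."""
        train = generate_natural_like(5000, D65LIKE, seed=54)
        net_a = fit_network(train, NetworkSpec())
        net_b = fit_network(train, NetworkSpec())
        np.testing.assert_array_equal(net_a.white, net_b.white)
        for xa, xb in zip(net_a.pleistochrome.x_knots,
                          net_b.pleistochrome.x_knots):
            np.testing.assert_array_equal(xa, xb)
        # responses to different test sets use identical fitted maps
        out_a = net_a.responses(lms_set)["x2"]
        out_b = net_a.responses(
            ColorSet(lms_set.samples * 1.5, space="LMS_linear"))["x2"]
        assert out_a.samples.shape == out_b.samples.shape


def test_shared_stage_fit_gives_identical_nonlinearity():
    trains = {"D65like": generate_natural_like(5000, D65LIKE, seed=60),
              "Alike": generate_natural_like(5000, ALIKE, seed=61)}
    nets = fit_networks_shared(trains, NetworkSpec(adaptation="von_kries"))
    assert nets["D65like"].pleistochrome is nets["Alike"].pleistochrome
    assert not np.allclose(nets["D65like"].white, nets["Alike"].white)
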
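"""Evaluation metrics against hand computations and loop oracles."""

import numpy as np
import pytest

from attnfnet.metrics import (MetricReport, deviation_maps, estimate_weight,
                              evaluate, frechet_distance, mse, posture_iou,
                              ppa, psnr, random_projection_embedder)
from attnfnet.synthetic import (DEFAULT_SENSOR_AREA_M2, generate_dataset)


class TestScalarMetrics:
    def test_ppa_hand_example(self):
        y = np.array([0.0, 1.0, 2.0, 3.0])
        g = np.array([0.0, 1.4, 2.0, 10.0])
        assert ppa(y, g, tol=0.5) == pytest.approx(0.75)

    def test_ppa_extremes(self, rng):
        y = rng.random((10, 10))
        assert ppa(y, y, 0.1) == 1.0
        assert ppa(y, y + 0.2, 0.1 - 1e-12) == 0.0

    def test_mse_hand_example(self):
        assert mse([1.0, 2.0, 3.0], [2.0, 2.0, 5.0]) == pytest.approx(5 / 3)

    def test_psnr_values(self):
        y = np.zeros((10, 10))
        g = np.full((10, 10), 0.1)   # mse 0.01, max_val 1 -> 20 dB
        assert psnr(y, g, 1.0) == pytest.approx(20.0)
        assert psnr(y, g / np.sqrt(2), 1.0) == \
            pytest.approx(20.0 + 10 * np.log10(2))
        assert psnr(y, np.full((10, 10), 1.0), 1.0) == pytest.approx(0.0)
        assert psnr(y, y, 1.0) == np.inf

    @pytest.mark.parametrize("metric", ["ppa", "mse"])
    def test_loop_oracle_agreement(self, metric, rng):
        for _ in range(20):
            y, g = rng.random((10, 10)), rng.random((10, 10))
            if metric == "ppa":
                tol = 0.2
                naive = sum(abs(y[i, j] - g[i, j]) <= tol
                            for i in range(10) for j in range(10)) / 100
                assert abs(ppa(y, g, tol) - naive) < 1e-12
            else:
                naive = sum((y[i, j] - g[i, j]) ** 2
                            for i in range(10) for j in range(10)) / 100
                assert abs(mse(y, g) - naive) < 1e-12


class TestPostureIOU:
    def test_identical_nonempty_is_one(self, rng):
        y = rng.random((10, 10)) + 0.5
        assert posture_iou(y, y, threshold=1.0) == 1.0

    def test_shifted_square_hand_count(self):
        y = np.zeros((6, 6))
        g = np.zeros((6, 6))
        y[2:4, 2:4] = 2.0
        g[2:4, 3:5] = 2.0   # overlap 2 cells, union 6
        assert posture_iou(y, g, 1.0) == pytest.approx(1 / 3)

    def test_disjoint_components_zero(self):
        y = np.zeros((6, 6)); y[0, 0] = 2.0
        g = np.zeros((6, 6)); g[5, 5] = 2.0
        assert posture_iou(y, g, 1.0) == 0.0

    def test_keeps_only_largest_component(self):
        y = np.zeros((6, 6))
        y[0:3, 0] = 2.0       # large component (3 cells)
        y[5, 5] = 2.0         # small distractor
        g = np.zeros((6, 6))
        g[0:3, 0] = 2.0
        assert posture_iou(y, g, 1.0) == 1.0

    def test_empty_conventions(self):
        z = np.zeros((4, 4))
        assert posture_iou(z, z, 1.0) == 1.0
        y = np.zeros((4, 4)); y[1, 1] = 2.0
        assert posture_iou(y, z, 1.0) == 0.0

    def test_invariant_to_monotone_rescale(self, rng):
        y, g = rng.random((12, 12)) * 3, rng.random((12, 12)) * 3
        a = posture_iou(y, g, 1.0)
        b = posture_iou(y ** 3, g ** 3, 1.0)   # threshold crossing preserved
        assert a == b


class TestFrechet:
    def test_identical_sets_zero_and_symmetry(self, rng):
        imgs = [rng.random((8, 8)) for _ in range(10)]
        other = [rng.random((8, 8)) for _ in range(10)]
        embed = random_projection_embedder((8, 8), n_features=6, seed=0)
        assert frechet_distance(imgs, imgs, embed) < 1e-6
        a = frechet_distance(imgs, other, embed)
        b = frechet_distance(other, imgs, embed)
        assert a == pytest.approx(b, rel=1e-9)
        assert a > 0

    def test_one_dimensional_closed_form(self, rng):
        s1 = rng.normal(0.0, 1.0, size=4000)
        s2 = rng.normal(1.0, 1.0, size=4000)
        fd = frechet_distance(s1, s2, lambda v: np.atleast_1d(v))
        # ||0-1||^2 + (1 + 1 - 2) = 1 up to sampling error
        assert fd == pytest.approx(1.0, abs=0.1)

    def test_gaussian_moment_oracle(self, rng):
        # diagonal covariances: closed form sum over dims
        f1 = rng.normal(0.0, 1.0, size=(3000, 2))
        f2 = rng.normal([1.0, 0.0], [2.0, 1.0], size=(3000, 2))
        fd = frechet_distance(f1, f2, lambda v: v)
        # per-dim: ||mu1-mu2||^2 + s1^2 + s2^2 - 2 s1 s2
        want = (1.0 + 1 + 4 - 2 * 2.0) + (0.0 + 1 + 1 - 2 * 1.0)
        assert fd == pytest.approx(want, abs=0.3)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            frechet_distance([np.ones((2, 2))], [np.ones((2, 2))],
                             lambda v: v.ravel())


class TestWeightEstimation:
    def test_uniform_pressure_worked_example(self):
        p = np.ones((27, 64))
        got = estimate_weight(p, sensor_area_m2=0.001)
        assert got == pytest.approx(1728 * 1.0 * 1000 * 0.001 / 9.81, rel=1e-9)
        assert got == pytest.approx(176.1468, abs=0.001)

    def test_zero_map_and_linearity(self, rng):
        assert estimate_weight(np.zeros((27, 64)), 0.001) == 0.0
        p = rng.random((27, 64))
        assert estimate_weight(2 * p, 0.001) == \
            pytest.approx(2 * estimate_weight(p, 0.001))

    def test_recovers_synthetic_subject_mass(self):
        ds = generate_dataset(5, 3, seed=6, grid_shape=(64, 56))
        for s in ds.samples:
            mass = ds.subjects[s.subject_id].mass_kg
            got = estimate_weight(s.pressure_kpa, DEFAULT_SENSOR_AREA_M2)
            assert got == pytest.approx(mass, rel=1e-6)

    def test_negative_pressure_rejected(self):
        with pytest.raises(ValueError):
            estimate_weight(np.array([[-1.0]]), 0.001)


class TestDeviationAndEvaluate:
    def test_deviation_map_mean_of_two(self, rng):
        y = rng.random((5, 5))
        d = 0.3 * np.ones((5, 5))
        maps = deviation_maps({"supine": [(y, y + d), (y, y)]})
        np.testing.assert_allclose(maps["supine"], d / 2)

    def test_empty_group_omitted_with_warning(self):
        with pytest.warns(UserWarning, match="omitted"):
            maps = deviation_maps({"supine": []})
        assert maps == {}

    def test_identity_oracle_reaches_perfect_scores(self, small_dataset):
        test = small_dataset.subset("test")
        report = evaluate(lambda s: s.pressure, test, DEFAULT_SENSOR_AREA_M2)
        assert report.aggregates["MPPA"] == 1.0
        assert report.aggregates["MSSIM"] == pytest.approx(1.0)
        assert report.aggregates["MSE_kpa2"] == 0.0
        assert report.aggregates["MIOU"] == 1.0
        assert report.aggregates["MFID"] == pytest.approx(0.0, abs=1e-6)
        assert report.notes["n_infinite_psnr_excluded"] == len(test)

    def test_aggregates_equal_means_and_row_count(self, small_dataset):
        test = small_dataset.subset("test")
        rng = np.random.default_rng(0)
        report = evaluate(lambda s: s.pressure * rng.uniform(0.9, 1.1),
                          test, DEFAULT_SENSOR_AREA_M2)
        assert len(report.per_sample) == len(test)
        assert report.aggregates["MSSIM"] == \
            pytest.approx(report.per_sample["ssim"].mean())
        assert report.aggregates["MSE_kpa2"] == \
            pytest.approx(report.per_sample["mse_kpa2"].mean())
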
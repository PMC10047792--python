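import numpy as np
import pytest
from scipy import stats as sps

from eitshape.forward import MeasurementVector
from eitshape.phantoms import (
    CONDUCTIVITY_DEAD_ZONE,
    Circle,
    DatasetConfig,
    NoiseSpec,
    NormalizationStats,
    Phantom,
    add_noise,
    apply_normalization,
    build_dataset,
    fit_normalization,
    label_point,
    label_points,
    normalize_points,
    rasterize,
    sample_phantom,
    sample_point_cloud,
)


class TestSamplePhantom:
    def test_containment_and_contrast(self, rng):
        for n in (1, 2, 3, 4):
            for _ in range(25):
                ph = sample_phantom(rng, n)
                assert ph.n_anomalies == n
                for c in ph.circles:
                    assert np.hypot(*c.center) + c.radius <= 0.95 + 1e-9
                    assert 0.1 <= c.radius <= 0.35
                    assert 0.2 <= c.conductivity <= 5.0
                    lo, hi = CONDUCTIVITY_DEAD_ZONE
                    assert not lo < c.conductivity < hi

    def test_empty_phantom_is_homogeneous(self, coarse_mesh):
        field = rasterize(Phantom(circles=[]), coarse_mesh)
        assert np.all(field.sigma == 1.0)

    def test_deterministic_given_rng_state(self):
        a = sample_phantom(np.random.default_rng(7), 3)
        b = sample_phantom(np.random.default_rng(7), 3)
        assert a.to_dict() == b.to_dict()


class TestRasterize:
    def test_covering_circle_sets_everything(self, coarse_mesh):
        ph = Phantom(circles=[Circle((0.0, 0.0), 0.95, 2.0)])
        assert np.all(rasterize(ph, coarse_mesh).sigma == 2.0)

    def test_area_fraction_matches_circle_area(self, training_mesh):
        ph = Phantom(circles=[Circle((0.0, 0.0), 0.3, 2.0)])
        field = rasterize(ph, training_mesh)
        areas = training_mesh.signed_areas()
        frac = areas[field.sigma == 2.0].sum() / areas.sum()
        assert frac == pytest.approx(0.09, abs=0.01)

    def test_later_circle_overrides(self, training_mesh):
        ph = Phantom(
            circles=[
                Circle((0.0, 0.0), 0.3, 2.0),
                Circle((0.0, 0.0), 0.2, 0.5),
            ]
        )
        field = rasterize(ph, training_mesh)
        from eitshape.mesh import triangle_centroids

        cent = triangle_centroids(training_mesh)
        d = np.hypot(cent[:, 0], cent[:, 1])
        assert np.all(field.sigma[d < 0.19] == 0.5)


class TestLabelPoint:
    def test_center_and_far_boundary(self):
        ph = Phantom(circles=[Circle((0.3, 0.0), 0.2, 2.0)])
        assert label_point(ph, (0.3, 0.0)) == 1
        assert label_point(ph, (-0.9, 0.0)) == 0

    def test_outside_disk_rejected(self):
        with pytest.raises(ValueError):
            label_point(Phantom(circles=[]), (1.5, 0.0))

    def test_monte_carlo_area_fraction(self, rng):
        ph = Phantom(circles=[Circle((0.2, 0.1), 0.3, 2.0)])
        rho = np.sqrt(rng.uniform(size=20000))
        ang = rng.uniform(0, 2 * np.pi, 20000)
        pts = np.c_[rho * np.cos(ang), rho * np.sin(ang)]
        frac = label_points(ph, pts).mean()
        assert frac == pytest.approx(0.3**2, abs=0.01)


class TestPointCloud:
    def test_balanced_and_consistent(self, rng):
        ph = sample_phantom(rng, 2)
        cloud = sample_point_cloud(ph, 512, rng)
        assert len(cloud) == 1024
        assert cloud.labels.sum() == 512
        assert np.array_equal(label_points(ph, cloud.points), cloud.labels)

    def test_empty_anomaly_region_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_point_cloud(Phantom(circles=[]), 16, rng)

    def test_background_angular_uniformity(self, rng):
        """Chi-square over 8 angular sectors must not reject uniformity."""
        ph = Phantom(circles=[Circle((0.0, 0.0), 0.25, 2.0)])
        cloud = sample_point_cloud(ph, 10000, rng)
        bg = cloud.points[cloud.labels == 0]
        ang = np.arctan2(bg[:, 1], bg[:, 0])
        counts, _ = np.histogram(ang, bins=8, range=(-np.pi, np.pi))
        p = sps.chisquare(counts).pvalue
        assert p > 0.01

    def test_anomaly_points_uniform_over_union(self, rng):
        """Two circles of different area receive samples proportionally."""
        ph = Phantom(
            circles=[
                Circle((-0.4, 0.0), 0.3, 2.0),
                Circle((0.5, 0.0), 0.15, 3.0),
            ]
        )
        cloud = sample_point_cloud(ph, 4000, rng)
        an = cloud.points[cloud.labels == 1]
        in_small = np.hypot(an[:, 0] - 0.5, an[:, 1]) < 0.15
        expect = 0.15**2 / (0.3**2 + 0.15**2)
        assert in_small.mean() == pytest.approx(expect, abs=0.03)


class TestNoise:
    def test_zero_delta_identity(self, rng):
        m = MeasurementVector(np.linspace(-1, 1, 208), 16)
        out = add_noise(m, NoiseSpec(0.0), rng)
        assert np.array_equal(out.values, m.values)

    def test_noise_standard_deviation(self, rng):
        m = MeasurementVector(np.linspace(-0.2, -0.01, 208), 16)
        scale = np.abs(m.values).max()
        draws = np.stack(
            [add_noise(m, NoiseSpec(1.0), rng).values - m.values for _ in range(10000)]
        )
        assert draws.std() == pytest.approx(scale / 100, rel=0.03)
        assert abs(draws.mean()) < 3 * scale / 100 / np.sqrt(draws.size)

    def test_noise_independence_across_channels(self, rng):
        m = MeasurementVector(np.linspace(-0.2, -0.01, 208), 16)
        draws = np.stack(
            [add_noise(m, NoiseSpec(1.0), rng).values for _ in range(10000)]
        )
        C = np.corrcoef(draws[:, :12].T)
        off = C[~np.eye(12, dtype=bool)]
        assert np.abs(off).max() < 0.05


class TestNormalization:
    def test_endpoint_mapping(self):
        stats = NormalizationStats(m_min=-2.0, m_max=3.0)
        assert apply_normalization(np.array([3.0]), stats)[0] == 1.0
        assert apply_normalization(np.array([-2.0]), stats)[0] == 0.0

    def test_point_center_maps_to_half(self):
        stats = NormalizationStats(m_min=0.0, m_max=1.0)
        assert np.allclose(normalize_points(np.array([[0.0, 0.0]]), stats), 0.5)

    def test_out_of_range_not_clipped(self):
        stats = NormalizationStats(m_min=0.0, m_max=1.0)
        assert apply_normalization(np.array([2.0]), stats)[0] == 2.0
        assert apply_normalization(np.array([-1.0]), stats)[0] == -1.0

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            NormalizationStats(m_min=1.0, m_max=1.0)


class TestDataset:
    def test_composition_and_determinism(self, training_mesh):
        cfg = DatasetConfig(n_train_per_class=2, n_val=4, master_seed=5)
        a = build_dataset(cfg, training_mesh, "train")
        b = build_dataset(cfg, training_mesh, "train")
        assert len(a) == 8
        counts = [r.phantom.n_anomalies for r in a.records]
        assert counts == [1, 1, 2, 2, 3, 3, 4, 4]
        assert np.array_equal(a.measurement_matrix(), b.measurement_matrix())
        v = build_dataset(cfg, training_mesh, "val")
        assert len(v) == 4
        # validation stream differs from training stream
        assert not np.array_equal(
            a.measurement_matrix()[:4], v.measurement_matrix()
        )

    def test_default_composition_sizes(self):
        cfg = DatasetConfig()
        assert 4 * cfg.n_train_per_class == 16384
        assert cfg.n_val == 1024
        small = DatasetConfig.small()
        assert 4 * small.n_train_per_class == 2000
        assert small.n_val == 200
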
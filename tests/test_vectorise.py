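import math

import numpy as np
import pytest
from scipy.stats import norm

from celltda import (
    ImageParams,
    PointCloud,
    WeightingSpec,
    alpha_filtration,
    betti_curve,
    betti_oracle,
    build_descriptor_matrix,
    compute_persistence,
    default_registry,
    estimate_scale_s,
    p0_for_degree,
    percentile_stats,
    persistence_image,
)
from celltda.persistence import PersistenceDiagram, PersistenceFeature
from celltda.vectorise import EQUILATERAL_LOOP_PERSISTENCE, betti_grid
from conftest import random_cloud


def feature(b, d, degree=1):
    ds = None if math.isinf(d) else (0, 1, 2)[: degree + 2]
    return PersistenceFeature(degree, b, d, (0, 1)[: degree + 1],
                              death_simplex=ds)


class TestScaleEstimation:
    def test_unit_grid_has_scale_one(self):
        xs, ys = np.meshgrid(np.arange(3.0), np.arange(3.0))
        cloud = PointCloud(np.column_stack([xs.ravel(), ys.ravel()]), "s", "A")
        assert estimate_scale_s([cloud]) == pytest.approx(1.0)

    def test_mean_of_per_sample_means(self):
        a = PointCloud(np.array([[0.0, 0], [1.0, 0]]), "a", "A")
        b = PointCloud(np.array([[0.0, 0], [2.0, 0]]), "b", "A")
        assert estimate_scale_s([a, b]) == pytest.approx(1.5)

    def test_single_point_cloud_skipped(self, caplog):
        a = PointCloud(np.array([[0.0, 0], [1.0, 0]]), "a", "A")
        single = PointCloud(np.array([[5.0, 5.0]]), "b", "A")
        with caplog.at_level("WARNING"):
            assert estimate_scale_s([a, single]) == pytest.approx(1.0)
        assert "excluded" in caplog.text


class TestP0:
    def test_degree0_is_half_scale(self):
        assert p0_for_degree(1.0, 0) == 0.5
        assert p0_for_degree(3.0, 0) == 1.5

    def test_degree1_is_equilateral_loop_persistence(self):
        assert p0_for_degree(1.0, 1) == pytest.approx(1 / math.sqrt(3) - 0.5)
        assert p0_for_degree(2.0, 1) == pytest.approx(2 * p0_for_degree(1.0, 1))

    def test_degree1_value_matches_alpha_pipeline_on_equilateral_triangle(self):
        s = 1.0
        pts = s * np.array(
            [[0.0, 0.0], [1.0, 0.0], [0.5, math.sqrt(3) / 2]]
        )
        # tiny jitter keeps the circumcentre generic without moving values
        pts = pts + 1e-9 * np.array([[1, 0], [0, 1], [1, 1]])
        dgm = compute_persistence(
            alpha_filtration(PointCloud(pts, "s", "A"))
        )
        (loop,) = dgm[1].features
        assert loop.persistence == pytest.approx(
            EQUILATERAL_LOOP_PERSISTENCE * s, abs=1e-6
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            p0_for_degree(0.0, 0)
        with pytest.raises(ValueError):
            p0_for_degree(1.0, 2)


class TestBettiCurve:
    def test_direct_counting(self):
        dgm = PersistenceDiagram(1, [feature(1, 3), feature(2, 6)])
        values = betti_curve(dgm, np.array([2.5, 4.0]))
        np.testing.assert_allclose(values, [1.0, 0.5])

    def test_degree0_all_alive_at_zero(self):
        cloud = random_cloud(0, n=12)
        dgm = compute_persistence(alpha_filtration(cloud))[0]
        assert betti_curve(dgm, np.array([0.0, 1e6]))[0] == 1.0
        # the essential component stays alive forever
        assert betti_curve(dgm, np.array([1e6]))[0] == pytest.approx(1 / 12)

    def test_area_under_unnormalised_curve_is_total_persistence(self):
        cloud = random_cloud(1, n=20)
        dgm = compute_persistence(alpha_filtration(cloud))[1]
        total = sum(f.persistence for f in dgm.finite())
        top = max(f.death for f in dgm.finite())
        for n in (2000, 20000):
            grid = np.linspace(0, top, n)
            area = np.trapezoid(betti_curve(dgm, grid, normalise=False), grid)
            if abs(area - total) <= 0.01 * total:
                break
        assert area == pytest.approx(total, rel=0.01)

    def test_unnormalised_curve_matches_betti_oracle(self):
        for seed in range(3):
            cloud = random_cloud(seed, n=14)
            fc = alpha_filtration(cloud)
            dgms = compute_persistence(fc)
            grid = np.linspace(1e-9, 0.9, 13)
            for degree in (0, 1):
                counts = betti_curve(dgms[degree], grid, normalise=False)
                oracle = [betti_oracle(fc, t)[degree] for t in grid]
                np.testing.assert_array_equal(counts, oracle)

    def test_empty_diagram_zero_curve_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            values = betti_curve(PersistenceDiagram(1, []), np.array([0.5]))
        np.testing.assert_array_equal(values, [0.0])


class TestPercentileStats:
    def test_linear_interpolation_oracle(self):
        dgm = PersistenceDiagram(
            1, [feature(0, p) for p in (1, 2, 3, 4, 5)]
        )
        np.testing.assert_allclose(
            percentile_stats(dgm, "persistence"), [1.4, 2.0, 3.0, 4.0, 4.6]
        )

    def test_single_feature_collapses_all_percentiles(self):
        dgm = PersistenceDiagram(1, [feature(1.0, 3.5)])
        np.testing.assert_allclose(percentile_stats(dgm, "death"), 3.5)

    def test_degree0_births_all_zero(self):
        dgm = compute_persistence(alpha_filtration(random_cloud(0, n=10)))[0]
        np.testing.assert_array_equal(percentile_stats(dgm, "birth"), 0.0)

    def test_infinite_features_excluded_from_death_included_in_birth(self):
        dgm = PersistenceDiagram(
            0, [feature(0, 1.0, degree=0), feature(0, math.inf, degree=0)]
        )
        np.testing.assert_allclose(percentile_stats(dgm, "death"), 1.0)
        assert len(percentile_stats(dgm, "birth")) == 5

    def test_nothing_to_summarise_gives_missing_marker(self, caplog):
        dgm = PersistenceDiagram(0, [feature(0, math.inf, degree=0)])
        with caplog.at_level("WARNING"):
            out = percentile_stats(dgm, "death")
        assert np.isnan(out).all()


class TestWeightings:
    def test_all_weightings_vanish_at_zero_persistence(self):
        for name in ("flat", "w1", "w2", "w3", "w4"):
            w = WeightingSpec(name, p0=0.5 if name == "flat" else None)
            assert w(np.array([3.0]), np.array([0.0]))[0] == 0.0

    def test_flat_ramp_and_plateau(self):
        w = WeightingSpec("flat", p0=2.0)
        np.testing.assert_allclose(
            w(np.zeros(3), np.array([1.0, 2.0, 5.0])), [0.5, 1.0, 1.0]
        )

    def test_monotone_in_persistence_and_birth(self):
        p = np.linspace(0, 3, 50)
        b = np.linspace(0, 3, 50)
        for name in ("flat", "w1", "w2", "w3", "w4"):
            w = WeightingSpec(name, p0=0.7 if name == "flat" else None)
            along_p = w(np.full_like(p, 2.0), p)
            assert np.all(np.diff(along_p) >= 0)
            if name in ("w3", "w4"):
                along_b = w(b, np.full_like(b, 1.5))
                assert np.all(np.diff(along_b) >= 0)


class TestPersistenceImage:
    def params(self, **kw):
        defaults = dict(resolution=(1, 1), gaussian_sd=0.5,
                        birth_range=(0.0, 4.0), pers_range=(0.0, 4.0))
        defaults.update(kw)
        return ImageParams(**defaults)

    def test_empty_diagram_gives_zero_matrix(self):
        img = persistence_image(
            PersistenceDiagram(1, []), WeightingSpec("w1"), self.params()
        )
        np.testing.assert_array_equal(img, 0.0)

    def test_zero_persistence_diagram_zero_under_every_weighting(self):
        dgm = PersistenceDiagram(1, [feature(1.5, 1.5)])
        for name in ("flat", "w1", "w2", "w3", "w4"):
            w = WeightingSpec(name, p0=0.5 if name == "flat" else None)
            np.testing.assert_array_equal(
                persistence_image(dgm, w, self.params()), 0.0
            )

    def test_single_feature_matches_cdf_product_oracle(self):
        dgm = PersistenceDiagram(1, [feature(1.0, 3.0)])  # (b, p) = (1, 2)
        img = persistence_image(dgm, WeightingSpec("w1"), self.params())
        expected = (
            2.0
            * (norm.cdf((4 - 1) / 0.5) - norm.cdf((0 - 1) / 0.5))
            * (norm.cdf((4 - 2) / 0.5) - norm.cdf((0 - 2) / 0.5))
        )
        assert img[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_additivity_over_disjoint_union(self):
        d1 = PersistenceDiagram(1, [feature(0.5, 1.5), feature(1.0, 1.2)])
        d2 = PersistenceDiagram(1, [feature(2.0, 3.7)])
        union = PersistenceDiagram(1, d1.features + d2.features)
        p = self.params(resolution=(8, 8))
        w = WeightingSpec("w2")
        np.testing.assert_allclose(
            persistence_image(union, w, p),
            persistence_image(d1, w, p) + persistence_image(d2, w, p),
            rtol=0, atol=1e-15,
        )

    def test_total_mass_conserved_on_wide_grid(self):
        feats = [feature(0.5, 1.5), feature(1.0, 3.0), feature(2.0, 2.4)]
        dgm = PersistenceDiagram(1, feats)
        sd = 0.3
        p = ImageParams(resolution=(40, 40), gaussian_sd=sd,
                        birth_range=(-6 * sd + 0.0, 2.0 + 6 * sd),
                        pers_range=(-6 * sd + 0.0, 2.0 + 6 * sd))
        for name in ("w1", "w3"):
            w = WeightingSpec(name)
            total_weight = sum(
                float(w(np.array([f.birth]), np.array([f.persistence]))[0])
                for f in feats
            )
            assert persistence_image(dgm, w, p).sum() == pytest.approx(
                total_weight, rel=1e-3
            )

    def test_flat_image_converges_to_unweighted_as_p0_shrinks(self):
        dgm = PersistenceDiagram(1, [feature(0.5, 1.5), feature(1.0, 2.0)])
        p = self.params(resolution=(5, 5))
        # all persistences > 0, so p/p0 saturates at 1 for small p0
        small = persistence_image(dgm, WeightingSpec("flat", p0=1e-9), p)
        ones = persistence_image(
            dgm, WeightingSpec("flat", p0=min(f.persistence for f in dgm.features)), p
        )
        np.testing.assert_allclose(small, ones, rtol=1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ImageParams(resolution=(0, 5))
        with pytest.raises(ValueError):
            ImageParams(gaussian_sd=0.0)
        with pytest.raises(ValueError):
            ImageParams(birth_range=(1.0, 1.0))
        with pytest.raises(ValueError):
            WeightingSpec("flat")  # p0 missing


class TestDescriptorMatrix:
    @pytest.fixture()
    def cohort(self):
        clouds = [random_cloud(seed, n=20) for seed in range(4)]
        return (
            {
                c.sample_id: compute_persistence(alpha_filtration(c))
                for c in clouds
            },
            estimate_scale_s(clouds),
        )

    def test_registry_counts_nine_plus_five(self):
        assert len(default_registry((1,))) == 9
        assert len(default_registry((0,))) == 5
        assert len(default_registry((0, 1))) == 14

    def test_matrix_shapes_and_alignment(self, cohort):
        diagrams, s = cohort
        mats = build_descriptor_matrix(diagrams, s, betti_grid_size=50,
                                       resolution=(10, 10))
        assert len(mats) == 14
        for name, df in mats.items():
            assert list(df.index) == list(diagrams)
            if "pct" in name:
                assert df.shape[1] == 5
            elif "betti" in name:
                assert df.shape[1] == 50
            else:
                assert df.shape[1] == 100

    def test_shared_grid_makes_rows_comparable(self, cohort):
        diagrams, s = cohort
        mats = build_descriptor_matrix(diagrams, s, betti_grid_size=50)
        curves = mats["deg1_betti_curve"]
        assert curves.notna().all().all()
        assert (curves.to_numpy() <= 1.0).all()
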
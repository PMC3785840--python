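import math

import numpy as np
import pytest
from scipy import stats

from osteorisk import classifier as clf
from osteorisk import kde

from conftest import make_record, two_class_records


class TestFeatureSpec:
    def test_default_transforms(self):
        spec = clf.FeatureSpec.of("annual_wear", "age_at_surgery")
        assert spec.transforms == ("log_then_standardize", "standardize")

    def test_wear_must_be_logged(self):
        with pytest.raises(ValueError):
            clf.FeatureSpec(names=("annual_wear",), transforms=("standardize",))

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            clf.FeatureSpec.of("bmi", "bmi")

    def test_unknown_feature_rejected(self):
        with pytest.raises(ValueError, match="allowed"):
            clf.FeatureSpec.of("shoe_size")


class TestFitTransform:
    def test_log_wear_hand_example(self, wear_spec):
        recs = two_class_records(
            [math.e**0, math.e**1], [math.e**2]
        )
        Z, params = clf.fit_transform(recs, wear_spec)
        # log gives {0,1,2}: mean 1, sample sd 1 -> standardized {-1,0,+1}
        np.testing.assert_allclose(Z[:, 0], [-1.0, 0.0, 1.0], atol=1e-12)
        assert params.mean[0] == pytest.approx(1.0, abs=1e-12)
        assert params.sd[0] == pytest.approx(1.0, abs=1e-12)

    def test_fitted_columns_are_zero_mean_unit_sd(self, default_cohort, wear_age_spec):
        Z, _ = clf.fit_transform(default_cohort, wear_age_spec)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(Z.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_params_reproduce_training_matrix(self, default_cohort, wear_age_spec):
        Z, params = clf.fit_transform(default_cohort, wear_age_spec)
        X = clf.extract_matrix(default_cohort, wear_age_spec)
        np.testing.assert_allclose(
            clf.apply_transform(params, wear_age_spec, X), Z, atol=1e-12
        )

    def test_held_out_point_uses_training_params(self, wear_spec):
        recs = two_class_records([0.1, 0.2, 0.3], [0.4, 0.5])
        _, params = clf.fit_transform(recs, wear_spec)
        z = clf.apply_transform(params, wear_spec, [[0.25]])
        assert z[0, 0] != 0.0  # must not standardize against itself

    def test_inverse_round_trip(self, default_cohort, wear_age_spec):
        Z, params = clf.fit_transform(default_cohort, wear_age_spec)
        X = clf.extract_matrix(default_cohort, wear_age_spec)
        np.testing.assert_allclose(
            clf.inverse_transform(params, wear_age_spec, Z), X, rtol=1e-9
        )

    def test_nonpositive_wear_rejected(self, wear_spec):
        recs = two_class_records([0.1, 0.2], [0.3])
        _, params = clf.fit_transform(recs, wear_spec)
        with pytest.raises(ValueError, match="positive"):
            clf.apply_transform(params, wear_spec, [[-0.5]])


class TestEstimatePriors:
    CLASSES = ("control", "osteolysis")

    def test_published_cohort_counts(self):
        labels = ["control"] * 283 + ["osteolysis"] * 180
        p = clf.estimate_priors(labels, self.CLASSES)
        np.testing.assert_allclose(p, [283 / 463, 180 / 463], rtol=1e-15)
        assert p.sum() == 1.0
        # rounds to within one unit in the third decimal of the printed pair
        assert p[0] == pytest.approx(0.612, abs=1e-3)
        assert p[1] == pytest.approx(0.388, abs=1e-3)

    def test_equal_counts(self):
        p = clf.estimate_priors(["control", "osteolysis"] * 5, self.CLASSES)
        np.testing.assert_array_equal(p, [0.5, 0.5])

    def test_one_three(self):
        p = clf.estimate_priors(
            ["control"] + ["osteolysis"] * 3, self.CLASSES
        )
        np.testing.assert_array_equal(p, [0.25, 0.75])

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            clf.estimate_priors(["control"] * 4, self.CLASSES)


class TestFit:
    def test_default_cohort_wear_age(self, default_cohort, wear_age_spec):
        model = clf.fit(default_cohort, wear_age_spec, 0.7)
        assert model.d == 2
        assert model.h == 0.7
        assert [m.n for m in model.densities] == [283, 180]
        np.testing.assert_allclose(model.priors, [283 / 463, 180 / 463])

    def test_fixed_priors(self, default_cohort, wear_age_spec):
        model = clf.fit(default_cohort, wear_age_spec, 0.7, priors=[0.5, 0.5])
        np.testing.assert_array_equal(model.priors, [0.5, 0.5])

    def test_deterministic_refit(self, default_cohort, wear_age_spec):
        a = clf.fit(default_cohort, wear_age_spec, 0.7)
        b = clf.fit(default_cohort, wear_age_spec, 0.7)
        assert clf.model_to_dict(a) == clf.model_to_dict(b)

    def test_missing_class_rejected(self, wear_age_spec):
        recs = [make_record(id=f"C{i}") for i in range(4)]
        with pytest.raises(ValueError, match="absent"):
            clf.fit(recs, wear_age_spec, 0.7)


def simple_model(points_a=(0.0,), points_b=(2.0,), h=1.0, priors=(0.5, 0.5)):
    return clf.ClassifierModel.from_arrays(
        [np.asarray(points_a)[:, None], np.asarray(points_b)[:, None]],
        classes=("control", "osteolysis"),
        h=h,
        priors=priors,
    )


class TestPosterior:
    def test_hand_computed_example(self):
        model = simple_model()
        p = clf.posterior(model, [0.0])
        # oracle: phi(0) / (phi(0) + phi(2)) = 1 / (1 + exp(-2))
        want = stats.norm.pdf(0.0) / (stats.norm.pdf(0.0) + stats.norm.pdf(2.0))
        assert p[0] == pytest.approx(want, rel=1e-12)
        assert p[0] == pytest.approx(0.8808, abs=1e-4)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_point(self):
        model = simple_model(points_a=(-1.0,), points_b=(1.0,))
        np.testing.assert_allclose(clf.posterior(model, [0.0]), [0.5, 0.5], atol=1e-12)

    def test_huge_h_returns_priors(self, default_cohort, wear_age_spec):
        model = clf.fit(default_cohort, wear_age_spec, 1e6)
        for r in default_cohort[::100]:
            p = clf.posterior(model, [r.annual_wear, r.age_at_surgery])
            np.testing.assert_allclose(p, model.priors, atol=1e-3)

    def test_no_support_falls_back_to_priors(self):
        model = simple_model(priors=(0.7, 0.3))
        probs, supported = clf.posterior_with_support(model, [1e5])
        assert not supported
        np.testing.assert_array_equal(probs, model.priors)

    def test_supported_inside_data(self):
        _, supported = clf.posterior_with_support(simple_model(), [1.0])
        assert supported

    def test_wear_nonpositive_rejected(self, default_cohort, wear_age_spec):
        model = clf.fit(default_cohort, wear_age_spec, 0.7)
        with pytest.raises(ValueError):
            clf.posterior(model, [-0.1, 60.0])

    def test_prior_sensitivity_monotone(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=8), rng.normal(size=6) + 1
        x = [0.4]
        prev = 0.0
        for p1 in (0.1, 0.3, 0.5, 0.7, 0.9):
            model = simple_model(a, b, priors=(1 - p1, p1))
            post1 = clf.posterior(model, x)[1]
            assert post1 >= prev
            prev = post1

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=8), rng.normal(size=6) + 1
        m1 = clf.ClassifierModel.from_arrays(
            [a[:, None], b[:, None]], ("control", "osteolysis"), 1.0, (0.6, 0.4)
        )
        m2 = clf.ClassifierModel.from_arrays(
            [b[:, None], a[:, None]], ("osteolysis", "control"), 1.0, (0.4, 0.6)
        )
        x = [0.3]
        np.testing.assert_allclose(
            clf.posterior(m1, x), clf.posterior(m2, x)[::-1], rtol=1e-12
        )

    def test_random_models_properties(self):
        """Normalization and the large-h prior limit on random instances."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            d = int(rng.integers(1, 4))
            a = rng.normal(size=(int(rng.integers(2, 20)), d))
            b = rng.normal(size=(int(rng.integers(2, 20)), d)) + rng.normal(size=d)
            p1 = float(rng.uniform(0.05, 0.95))
            model = clf.ClassifierModel.from_arrays(
                [a, b], ("control", "osteolysis"), float(rng.uniform(0.2, 3.0)),
                (1 - p1, p1),
            )
            x = rng.normal(size=d)
            post = clf.posterior(model, x)
            assert post.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(post >= 0)
            big = clf.ClassifierModel.from_arrays(
                [a, b], ("control", "osteolysis"), 1e6, (1 - p1, p1)
            )
            np.testing.assert_allclose(
                clf.posterior(big, x), big.priors, atol=1e-3
            )


class TestClassify:
    def test_map_labels(self):
        model = simple_model(priors=(0.9, 0.1))
        assert clf.classify(model, [0.0]) == "control"
        model = simple_model(priors=(0.1, 0.9))
        assert clf.classify(model, [2.0]) == "osteolysis"

    def test_tie_breaks_to_control(self):
        model = simple_model(points_a=(-1.0,), points_b=(1.0,))
        assert clf.classify(model, [0.0]) == "control"


class TestBayesConsistency:
    def test_error_near_analytic_bayes_rate(self):
        """N(0,1) vs N(2,1), equal priors: test error ~ Phi(-1) = 0.1587."""
        rng = np.random.default_rng(2024)
        n = 2000
        a = rng.normal(0.0, 1.0, size=n)
        b = rng.normal(2.0, 1.0, size=n)
        h = kde.bandwidth_normal_reference(np.concatenate([a, b]))
        model = clf.ClassifierModel.from_arrays(
            [a[:, None], b[:, None]], ("control", "osteolysis"), h, (0.5, 0.5)
        )
        m = 4000
        xa = rng.normal(0.0, 1.0, size=m)
        xb = rng.normal(2.0, 1.0, size=m)
        X = np.concatenate([xa, xb])[:, None]
        truth = np.array(["control"] * m + ["osteolysis"] * m)
        probs, _ = clf.posterior_batch(model, X)
        pred = np.asarray(model.classes)[np.argmax(probs, axis=1)]
        err = float(np.mean(pred != truth))
        assert err == pytest.approx(stats.norm.cdf(-1.0), abs=0.02)


@pytest.fixture(scope="module")
def wear_model(default_cohort, wear_spec):
    return clf.fit(default_cohort, wear_spec, 0.7)


@pytest.fixture(scope="module")
def surface_model(default_cohort, wear_age_spec):
    return clf.fit(default_cohort, wear_age_spec, 0.7)


class TestPosteriorCurve:

    def test_rows_sum_to_one(self, wear_model):
        curve = clf.posterior_curve(wear_model, n_points=64)
        total = curve["posterior_control"] + curve["posterior_osteolysis"]
        np.testing.assert_allclose(total, 1.0, atol=1e-12)

    def test_back_transformed_wear_positive(self, wear_model):
        curve = clf.posterior_curve(wear_model, n_points=64)
        assert (curve["annual_wear"] > 0).all()

    def test_pointwise_matches_posterior(self, wear_model):
        curve = clf.posterior_curve(wear_model, n_points=32)
        for _, row in curve.iloc[::7].iterrows():
            p = clf.posterior(wear_model, [row["annual_wear"]])
            assert row["posterior_control"] == pytest.approx(p[0], rel=1e-9)

    def test_requires_univariate(self, default_cohort, wear_age_spec):
        model = clf.fit(default_cohort, wear_age_spec, 0.7)
        with pytest.raises(ValueError):
            clf.posterior_curve(model)


class TestPosteriorSurface:

    def test_cells_match_posterior(self, surface_model):
        res = clf.posterior_surface(surface_model, resolution=12)
        for i in (0, 5, 11):
            for j in (2, 9):
                p = clf.posterior(surface_model, [res.raw1[i], res.raw2[j]])
                assert res.posteriors[0, i, j] == pytest.approx(p[0], rel=1e-9)

    def test_density_integrates_to_one(self, surface_model):
        res = clf.posterior_surface(surface_model, resolution=160, padding=6.0)
        integral = np.trapezoid(
            np.trapezoid(res.density, res.z2, axis=1), res.z1
        )
        assert integral == pytest.approx(1.0, abs=5e-3)

    def test_requires_bivariate(self, default_cohort, wear_spec):
        model = clf.fit(default_cohort, wear_spec, 0.7)
        with pytest.raises(ValueError):
            clf.posterior_surface(model)

    def test_osteolysis_risk_decreases_with_age(self, surface_model):
        """At a fixed wear rate in the dense region, later surgery means
        lower osteolysis posterior over ages 55-70."""
        for wear in (0.1, 0.2, 0.4):
            ages = np.linspace(55.0, 70.0, 16)
            post = np.array(
                [clf.posterior(surface_model, [wear, a])[1] for a in ages]
            )
            assert np.all(np.diff(post) <= 1e-12)

    def test_long_frame_shape(self, surface_model):
        res = clf.posterior_surface(surface_model, resolution=10)
        frame = res.to_frame()
        assert len(frame) == 100
        assert set(frame.columns) == {
            "annual_wear", "age_at_surgery",
            "posterior_control", "posterior_osteolysis", "density",
        }


class TestSerialization:
    def test_round_trip_preserves_posteriors(self, default_cohort, wear_age_spec,
                                             tmp_path):
        model = clf.fit(default_cohort, wear_age_spec, 0.7)
        path = tmp_path / "model.json"
        clf.save_model(model, path)
        loaded = clf.load_model(path)
        x = [0.2, 60.0]
        np.testing.assert_allclose(
            clf.posterior(loaded, x), clf.posterior(model, x), rtol=1e-12
        )
        assert loaded.classes == model.classes
        np.testing.assert_allclose(loaded.priors, model.priors)

    def test_round_trip_matrix_model(self, tmp_path):
        model = simple_model(priors=(0.3, 0.7))
        path = tmp_path / "m.json"
        clf.save_model(model, path)
        loaded = clf.load_model(path)
        assert loaded.standardization is None
        np.testing.assert_allclose(
            clf.posterior(loaded, [0.5]), clf.posterior(model, [0.5]), rtol=1e-12
        )
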
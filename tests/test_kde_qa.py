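"""HU extraction, KDE fitting, baselines, agreement values and the QA tool."""

import numpy as np
import pytest

from contourqa import (
    BaselineKDE,
    DegenerateInputError,
    GeometryError,
    HUSample,
    ImageVolume,
    KDEBaselineQA,
    KDECurve,
    KDEGrid,
    agreement_value,
    build_baseline,
    extract_hu,
    fit_kde,
    load_baselines,
    qa_contour_set,
    save_baselines,
)
from conftest import make_mask


def normal_pdf(x, mu, var):
    return np.exp(-0.5 * (x - mu) ** 2 / var) / np.sqrt(2 * np.pi * var)


class TestExtractHU:
    def test_constant_image(self, small_image):
        m = np.zeros((6, 6, 6), bool)
        m.flat[:10] = True
        sample = extract_hu(small_image, make_mask(m, spacing=(1, 1, 1.5)))
        assert len(sample) == 10
        assert np.all(sample.values == 40.0)

    def test_known_multiset(self):
        img = np.zeros((3, 3, 3))
        img[0, 0, 0], img[1, 1, 1], img[2, 2, 2] = -700, -650, -720
        m = np.zeros((3, 3, 3), bool)
        m[0, 0, 0] = m[1, 1, 1] = m[2, 2, 2] = True
        sample = extract_hu(ImageVolume(voxels=img), make_mask(m))
        assert sorted(sample.values) == [-720, -700, -650]

    def test_grid_mismatch_and_empty(self, small_image):
        with pytest.raises(GeometryError):
            extract_hu(small_image, make_mask(np.ones((3, 3, 3), bool)))
        with pytest.raises(DegenerateInputError):
            extract_hu(small_image, make_mask(np.zeros((6, 6, 6), bool), spacing=(1, 1, 1.5)))

    def test_sample_length_matches_mask(self, rng, small_image):
        m = rng.random((6, 6, 6)) < 0.5
        m[0, 0, 0] = True
        sample = extract_hu(small_image, make_mask(m, spacing=(1, 1, 1.5)))
        assert len(sample) == int(m.sum())


class TestFitKDE:
    def test_gaussian_closed_form(self, rng):
        """A Gaussian KDE of a Gaussian sample is the variance-inflated
        Gaussian: sup-norm agreement with the closed form below 0.004."""
        n, mu, sd = 10_000, 40.0, 10.0
        sample = HUSample(values=rng.normal(mu, sd, n))
        grid = KDEGrid.from_range(-20, 100, 0.5)
        curve = fit_kde(sample, grid, bandwidth="auto")
        oracle = normal_pdf(grid.points, mu, sd**2 + curve.bandwidth**2)
        assert np.max(np.abs(curve.density - oracle)) < 0.004

    def test_scott_bandwidth(self, rng):
        x = rng.normal(0, 10, 500)
        curve = fit_kde(HUSample(values=x), KDEGrid.from_range(-60, 60, 1.0))
        assert curve.bandwidth == pytest.approx(np.std(x, ddof=1) * 500 ** (-0.2))

    def test_zero_variance_fallback(self):
        grid = KDEGrid.from_range(0, 80, 0.5)
        with pytest.warns(UserWarning, match="zero-variance"):
            curve = fit_kde(HUSample(values=np.full(50, 40.0)), grid)
        assert curve.bandwidth == 1.0
        assert grid.points[np.argmax(curve.density)] == pytest.approx(40.0)
        assert curve.integral == pytest.approx(1.0, abs=0.02)

    def test_normalization_invariant(self, rng):
        """Density >= 0 with unit trapezoidal area when the grid covers the
        sample's +/-4-bandwidth support."""
        for _ in range(5):
            x = rng.normal(rng.uniform(-200, 200), rng.uniform(5, 50), 400)
            lo, hi = x.min() - 60, x.max() + 60
            curve = fit_kde(HUSample(values=x), KDEGrid.from_range(lo, hi, (hi - lo) / 400))
            assert np.all(curve.density >= 0)
            assert 0.98 <= curve.integral <= 1.02

    def test_narrow_grid_warns(self, rng):
        with pytest.warns(UserWarning, match="does not cover"):
            fit_kde(HUSample(values=rng.normal(0, 10, 100)), KDEGrid.from_range(-5, 5, 0.5))

    def test_matches_scipy_reference(self, rng):
        """Independent cross-check against scipy's Gaussian KDE."""
        from scipy.stats import gaussian_kde

        x = rng.normal(40, 10, 800)
        grid = KDEGrid.from_range(-20, 100, 1.0)
        curve = fit_kde(HUSample(values=x), grid, bandwidth="auto")
        ref = gaussian_kde(x, bw_method="scott")(grid.points)
        np.testing.assert_allclose(curve.density, ref, atol=2e-4)


class TestBaseline:
    def _curves(self, densities, grid):
        return [
            KDECurve(grid=grid, density=d, bandwidth=2.0, n_samples=100)
            for d in densities
        ]

    def test_identical_curves(self):
        grid = KDEGrid.from_range(0, 15, 1.0)
        d = np.full(16, 1 / 15)
        base = build_baseline(self._curves([d, d, d], grid), organ="brain")
        assert np.all(base.sd_density == 0)
        np.testing.assert_array_equal(base.lower, base.mean_density)
        np.testing.assert_array_equal(base.upper, base.mean_density)

    def test_two_curve_sd_closed_form(self, rng):
        grid = KDEGrid.from_range(0, 15, 1.0)
        a, b = rng.random(16) * 0.1, rng.random(16) * 0.1
        base = build_baseline(self._curves([a, b], grid), organ="brain")
        np.testing.assert_allclose(base.sd_density, np.abs(a - b) / np.sqrt(2))
        np.testing.assert_allclose(base.mean_density, (a + b) / 2)

    def test_bounds_definition(self, rng):
        grid = KDEGrid.from_range(0, 15, 1.0)
        ds = [rng.random(16) * 0.1 for _ in range(5)]
        base = build_baseline(self._curves(ds, grid), organ="brain")
        np.testing.assert_allclose(base.lower, np.maximum(base.mean_density - 2 * base.sd_density, 0))
        np.testing.assert_allclose(base.upper, base.mean_density + 2 * base.sd_density)
        assert np.all(base.lower <= base.mean_density) and np.all(base.mean_density <= base.upper)

    def test_fewer_than_two_rejected(self):
        grid = KDEGrid.from_range(0, 15, 1.0)
        with pytest.raises(DegenerateInputError):
            build_baseline(self._curves([np.zeros(16)], grid), organ="brain")

    def test_serialization_roundtrip_bit_identical(self, tmp_path, rng):
        grid = KDEGrid.from_range(-100, 100, 2.0)
        ds = [rng.random(101) * 0.02 for _ in range(4)]
        base = build_baseline(self._curves(ds, grid), organ="kidney_L")
        save_baselines({"kidney_L": base}, tmp_path / "b.json")
        back = load_baselines(tmp_path / "b.json")["kidney_L"]
        np.testing.assert_array_equal(back.mean_density, base.mean_density)
        np.testing.assert_array_equal(back.sd_density, base.sd_density)
        np.testing.assert_array_equal(back.grid.points, base.grid.points)
        assert back.n_reference == base.n_reference


class TestAgreement:
    def _baseline_from_bounds(self, lower, upper, grid):
        # reconstruct mean/sd giving exactly these bounds (no clipping active)
        mean = (np.asarray(lower) + np.asarray(upper)) / 2
        sd = (np.asarray(upper) - mean) / 2
        return BaselineKDE(organ="brain", grid=grid, mean_density=mean,
                           sd_density=sd, n_reference=2)

    def test_mean_curve_agrees_fully(self, rng):
        grid = KDEGrid.from_range(0, 15, 1.0)
        ds = [rng.random(16) * 0.1 for _ in range(5)]
        base = build_baseline(
            [KDECurve(grid=grid, density=d, bandwidth=2.0, n_samples=10) for d in ds],
            organ="brain",
        )
        test = KDECurve(grid=grid, density=base.mean_density, bandwidth=2.0, n_samples=10)
        assert agreement_value(test, base) == 1.0

    def test_hand_worked_indicator_sum(self):
        grid = KDEGrid(points=np.arange(16.0), step=1.0)
        lower = np.zeros(16)
        upper = np.full(16, 1.0)
        lower[:5] = [0.08, 0.18, 0.38, 0.18, 0.08]
        upper[:5] = [0.12, 0.22, 0.42, 0.22, 0.12]
        test = np.zeros(16)
        test[:5] = [0.10, 0.25, 0.40, 0.20, 0.10]
        # grid point 1 is above its upper bound; on the trailing 11 points
        # lower = 0 <= 0 <= upper, which agrees trivially -> 15/16
        base = self._baseline_from_bounds(lower, upper, grid)
        curve = KDECurve(grid=grid, density=test, bandwidth=1.0, n_samples=10)
        assert agreement_value(curve, base) == pytest.approx(15 / 16)

    def test_grid_mismatch(self, rng):
        g1 = KDEGrid.from_range(0, 15, 1.0)
        g2 = KDEGrid.from_range(0, 30, 2.0)
        base = self._baseline_from_bounds(np.zeros(16), np.ones(16), g1)
        curve = KDECurve(grid=g2, density=np.zeros(16), bandwidth=1.0, n_samples=5)
        with pytest.raises(GeometryError):
            agreement_value(curve, base)

    def test_support_restricted_mode(self):
        grid = KDEGrid(points=np.arange(20.0), step=1.0)
        mean = np.zeros(20)
        mean[5:10] = 0.2
        base = BaselineKDE(organ="brain", grid=grid, mean_density=mean,
                           sd_density=np.full(20, 0.01), n_reference=3)
        dens = np.zeros(20)
        dens[5:10] = 0.5  # far outside the envelope on all 5 support points
        curve = KDECurve(grid=grid, density=dens, bandwidth=1.0, n_samples=5)
        assert agreement_value(curve, base) == pytest.approx(15 / 20)
        assert agreement_value(curve, base, support_only=True) == 0.0

    def test_size_invariance(self, rng):
        """Doubling the sample (same distribution) barely moves agreement:
        the KDE comparison is normalized, hence organ-size independent."""
        grid = KDEGrid.from_range(0, 80, 1.0)
        curves = [
            fit_kde(HUSample(values=rng.normal(40, 10, 4000)), grid)
            for _ in range(30)
        ]
        base = build_baseline(curves, organ="brain")
        shifts = []
        for _ in range(8):
            x = rng.normal(40, 10, 4000)
            a1 = agreement_value(fit_kde(HUSample(values=x), grid), base)
            a2 = agreement_value(fit_kde(HUSample(values=np.concatenate([x, x])), grid), base)
            shifts.append(abs(a1 - a2))
        assert np.mean(shifts) < 0.05

    def test_monotone_in_contamination(self, rng):
        """Mixing contaminant HU values shifted by >= 5 baseline SDs yields
        nonincreasing mean agreement in the contamination fraction."""
        grid = KDEGrid.from_range(-50, 80, 1.0)
        curves = [
            fit_kde(HUSample(values=rng.normal(40, 10, 3000)), grid)
            for _ in range(25)
        ]
        base = build_baseline(curves, organ="kidney_L")
        n = 3000
        means = []
        for phi in (0.0, 0.2, 0.5, 0.8):
            vals = []
            for _ in range(4):
                k = int(phi * n)
                x = np.concatenate([
                    rng.normal(40, 10, n - k),
                    rng.normal(40 - 50, 10, k),  # 5 SD shift
                ])
                vals.append(agreement_value(fit_kde(HUSample(values=x), grid), base))
            means.append(np.mean(vals))
        assert all(b <= a + 1e-9 for a, b in zip(means, means[1:]))
        assert means[-1] < means[0]  # degradation is actually visible


class TestQAContourSet:
    def _setup(self, rng):
        grid = KDEGrid.from_range(-60, 100, 1.0)
        curves = [
            fit_kde(HUSample(values=rng.normal(40, 10, 2000)), grid)
            for _ in range(20)
        ]
        return {"kidney_L": build_baseline(curves, organ="kidney_L")}

    def _patient(self, rng, shift=0.0):
        img = rng.normal(40 + shift, 10, (8, 8, 8))
        m = np.zeros((8, 8, 8), bool)
        m[1:7, 1:7, 1:7] = True
        return ImageVolume(voxels=img), make_mask(m, organ="kidney_L", role="test")

    def test_matched_contour_passes_loose_threshold(self, rng):
        baselines = self._setup(rng)
        image, mask = self._patient(rng)
        rep = qa_contour_set(image, [mask], baselines, threshold=0.75)
        row = rep.rows.iloc[0]
        assert row.verdict == "pass" and row.agreement >= 0.75

    def test_contaminated_contour_flagged(self, rng):
        """A mask spilling into tissue ~100 HU away scores lower than the
        matched case and is flagged at the strict threshold."""
        baselines = self._setup(rng)
        img_ok, mask = self._patient(rng)
        img_bad, _ = self._patient(rng, shift=-100.0)
        a_ok = qa_contour_set(img_ok, [mask], baselines, threshold=1.0).rows.iloc[0]
        a_bad = qa_contour_set(img_bad, [mask], baselines, threshold=1.0).rows.iloc[0]
        assert a_bad.agreement < a_ok.agreement
        assert a_bad.verdict == "review"

    def test_missing_baseline_reported_not_raised(self, rng):
        baselines = self._setup(rng)
        image, _ = self._patient(rng)
        m = np.zeros((8, 8, 8), bool)
        m[2:5, 2:5, 2:5] = True
        rep = qa_contour_set(image, [make_mask(m, organ="brain")], baselines)
        assert list(rep.rows["verdict"]) == ["no_baseline"]


class TestEstimator:
    def test_sklearn_contract(self, rng):
        from sklearn.base import clone

        est = KDEBaselineQA(grid_min=0, grid_max=80, grid_step=1.0, organ="brain")
        params = est.get_params()
        assert params["threshold"] == 1.0
        clone(est)  # get_params/set_params round-trip
        ref = [rng.normal(40, 10, 2000) for _ in range(20)]
        est.fit(ref)
        assert est.baseline_.n_reference == 20
        a = est.score_samples([rng.normal(40, 10, 2000)])
        assert a.shape == (1,) and 0 <= a[0] <= 1
        verdicts = est.set_params(threshold=0.5).predict([rng.normal(40, 10, 2000)])
        assert verdicts[0] in ("pass", "review")

    def test_unfitted_raises(self):
        with pytest.raises(RuntimeError):
            KDEBaselineQA().score_samples([np.zeros(5) + 40])
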
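"""Measurement statistics: geometric means, histograms, fits, regression."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lipocurv.occlusion import BinnedSeries
from lipocurv.stats import (
    MeasurementRecord,
    aspect_ratio,
    binding_fraction_summary,
    build_histogram,
    fit_polynomial,
    geometric_mean_diameter,
    linear_regression,
    mean_count_by_diameter,
)


class TestGeometricMeanAndAspect:
    def test_known_value(self):
        assert geometric_mean_diameter(10.0, 14.4) == pytest.approx(12.0)

    def test_circle_identity(self):
        assert geometric_mean_diameter(9.3, 9.3) == pytest.approx(9.3)
        assert aspect_ratio(9.3, 9.3) == pytest.approx(1.0)

    @given(
        a=st.floats(min_value=0.1, max_value=1000),
        b=st.floats(min_value=0.1, max_value=1000),
    )
    @settings(max_examples=100, deadline=None)
    def test_geometric_mean_between_inputs(self, a, b):
        g = geometric_mean_diameter(a, b)
        assert min(a, b) - 1e-9 <= g <= max(a, b) + 1e-9

    def test_aspect_ratio_sorts_inputs(self):
        assert aspect_ratio(14.4, 10.0) == pytest.approx(1.44)
        assert aspect_ratio(10.0, 14.4) == pytest.approx(1.44)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            geometric_mean_diameter(0.0, 5.0)
        with pytest.raises(ValueError):
            aspect_ratio(5.0, -1.0)


class TestHistogram:
    def test_half_open_bin_rule(self):
        # 1 and 1 fall in [0, 2.17); 2.9 falls in [2.17, 4.34)
        series = build_histogram([1.0, 1.0, 2.9], step=2.17, origin=0.0)
        assert series.n_per_bin.tolist() == [2, 1]
        assert series.bin_centers[0] == pytest.approx(2.17 / 2)

    def test_mass_conservation(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(50, 10, size=10_000)
        series = build_histogram(vals, step=2.17)
        assert series.n_per_bin.sum() == 10_000

    def test_origin_shift_preserves_count_multiset(self):
        vals = [1.0, 3.0, 5.0, 7.2, 9.9]
        a = build_histogram(vals, step=2.0, origin=0.0)
        b = build_histogram([v + 2.0 for v in vals], step=2.0, origin=2.0)
        assert sorted(a.n_per_bin.tolist()) == sorted(b.n_per_bin.tolist())

    def test_empty_input(self):
        series = build_histogram([], step=1.0)
        assert len(series) == 0

    def test_boundary_value_goes_to_upper_bin(self):
        series = build_histogram([2.17], step=2.17, origin=0.0)
        assert series.n_per_bin.tolist() == [0, 1]


class TestPolynomialFit:
    def _series_from_xy(self, x, y):
        x = np.asarray(x, dtype=float)
        return BinnedSeries(
            bin_centers=x, values=np.asarray(y, dtype=float),
            bin_step=float(x[1] - x[0]), n_per_bin=np.ones(len(x), dtype=int),
        )

    def test_exact_line_recovered(self):
        x = np.arange(10, dtype=float)
        fit = fit_polynomial(self._series_from_xy(x, 2 * x + 1), degree=1)
        assert fit.coefficients == pytest.approx([2.0, 1.0])
        assert fit.residual_norm < 1e-10

    def test_degree6_coefficients_recovered(self):
        coeffs = np.array([0.3, -1.2, 0.5, 2.0, -0.7, 0.1, 4.0])
        x = np.linspace(1, 3, 25)
        y = np.polyval(coeffs, x)
        fit = fit_polynomial(self._series_from_xy(x, y), degree=6)
        np.testing.assert_allclose(fit.coefficients, coeffs, rtol=1e-8)

    def test_underdetermined_rejected(self):
        x = np.arange(8, dtype=float)
        with pytest.raises(ValueError):
            fit_polynomial(self._series_from_xy(x, x), degree=9)

    def test_evaluation_outside_domain_rejected(self):
        x = np.arange(10, dtype=float)
        fit = fit_polynomial(self._series_from_xy(x, x**2), degree=2)
        with pytest.raises(ValueError):
            fit(11.0)


class TestMeanCountByDiameter:
    def test_identical_counts_give_flat_means(self):
        recs = [MeasurementRecord(diameter=d, shape=1.0, n_visible=3) for d in (1.0, 2.5, 7.0)]
        series = mean_count_by_diameter(recs, step=2.0)
        vals = series.values[series.n_per_bin > 0]
        assert np.all(vals == 3.0)

    def test_two_bin_means(self):
        recs = [
            MeasurementRecord(diameter=0.5, shape=1.0, n_visible=1),
            MeasurementRecord(diameter=0.7, shape=1.0, n_visible=3),
            MeasurementRecord(diameter=1.5, shape=1.0, n_visible=2),
        ]
        series = mean_count_by_diameter(recs, step=1.0)
        assert series.values.tolist() == [2.0, 2.0]

    def test_empty_bins_are_nan(self):
        recs = [
            MeasurementRecord(diameter=0.5, shape=1.0, n_visible=1),
            MeasurementRecord(diameter=4.5, shape=1.0, n_visible=1),
        ]
        series = mean_count_by_diameter(recs, step=1.0)
        assert np.isnan(series.values[1]) and np.isnan(series.values[2])

    def test_poisson_mean_recovery(self):
        """Bin means recover the generating Poisson rate within 3 SE."""
        rng = np.random.default_rng(42)
        lam = lambda d: np.maximum(0.0, 8.4 - 0.2 * d)
        d = rng.uniform(8, 40, size=30_000)
        recs = [
            MeasurementRecord(diameter=float(di), shape=1.0, n_visible=int(rng.poisson(lam(di))))
            for di in d
        ]
        series = mean_count_by_diameter(recs, step=2.17)
        for c, m, n in zip(series.bin_centers, series.values, series.n_per_bin):
            if n >= 500:
                se = np.sqrt(lam(c) / n) + 1e-9
                # lambda varies within the bin; compare at bin center with 3 SE + linearization slack
                assert abs(m - lam(c)) < 3 * se + 0.02


class TestBindingFractions:
    def test_all_zero_counts(self):
        recs = [MeasurementRecord(diameter=10, shape=1.0, n_visible=0)] * 5
        out = binding_fraction_summary(recs)
        assert out.loc["0", "fraction"] == 1.0
        assert out["fraction"].sum() == pytest.approx(1.0)

    def test_known_fractions(self):
        counts = [1, 1, 2, 0]
        recs = [MeasurementRecord(diameter=10, shape=1.0, n_visible=c) for c in counts]
        out = binding_fraction_summary(recs)
        assert out["fraction"].tolist() == pytest.approx([0.25, 0.5, 0.25, 0.0])

    def test_grouped_mean_and_sd(self):
        recs = [
            MeasurementRecord(diameter=10, shape=1.0, n_visible=0, group="a"),
            MeasurementRecord(diameter=10, shape=1.0, n_visible=1, group="a"),
            MeasurementRecord(diameter=10, shape=1.0, n_visible=0, group="b"),
            MeasurementRecord(diameter=10, shape=1.0, n_visible=0, group="b"),
        ]
        out = binding_fraction_summary(recs)
        assert out.loc["0", "fraction"] == pytest.approx(0.75)  # mean of 0.5 and 1.0
        assert out.loc["0", "sd"] == pytest.approx(np.std([0.5, 1.0], ddof=1))

    def test_thinned_poisson_binding_fraction(self):
        """Fraction with >=1 visible protrusion matches 1 - exp(-lambda * P̄)."""
        from lipocurv.field import NoiseModel, ParticleClassSpec, project_particle, sample_population
        from lipocurv.occlusion import visibility_probability

        lam, D = 0.85, 12.7
        spec = ParticleClassSpec(
            label="hdl2",
            diameter_law=("normal", D, 1e-9),
            diameter_bounds=(D - 0.1, D + 0.1),
            protrusion_length_law=(8.5, 0.0),
            beta0=lam + 0.2 * D,
            beta1=0.2,
        )
        n = 20_000
        particles = sample_population(spec, n, seed=5)
        rng = np.random.default_rng(6)
        axes = rng.normal(size=(n, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        obs = [
            project_particle(p, axes[i], noise=NoiseModel.none(), seed=0)
            for i, p in enumerate(particles)
        ]
        frac_bound = np.mean([o.n_visible >= 1 for o in obs])
        # visible protrusions are a thinned Poisson with rate lambda * P(D, l)
        p_vis = visibility_probability(D, 8.5)
        expected = 1.0 - np.exp(-lam * p_vis)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac_bound - expected) < 3 * se


class TestLinearRegression:
    def test_exact_line(self):
        x = np.arange(10, dtype=float)
        res = linear_regression(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-12

    def test_null_correlation_small(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=10_000)
        y = rng.normal(size=10_000)
        res = linear_regression(x, y)
        assert abs(res.r) < 0.05

    def test_p_uniform_under_null(self):
        """Across seeded replicates the null p-value is uniform (KS check)."""
        from scipy import stats as sps

        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(500):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            pvals.append(linear_regression(x, y).p)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_p_agrees_with_permutation_test(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=12)
        y = 0.8 * x + rng.normal(size=12)
        res = linear_regression(x, y)
        n_perm = 10_000
        r_obs = abs(np.corrcoef(x, y)[0, 1])
        exceed = sum(
            abs(np.corrcoef(x, rng.permutation(y))[0, 1]) >= r_obs for _ in range(n_perm)
        )
        p_perm = (exceed + 1) / (n_perm + 1)
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(res.p - p_perm) < max(4 * se, 0.01)

    def test_affine_invariance_of_r(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        y = 1.5 * x + rng.normal(size=50)
        r1 = linear_regression(x, y).r
        r2 = linear_regression(3.0 * x - 7.0, 0.5 * y + 11.0).r
        assert r1 == pytest.approx(r2)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            linear_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            linear_regression([1.0, 2.0], [1.0, 2.0])
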
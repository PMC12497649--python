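import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from craave.abundance import (
    MeanVarianceFit,
    NormalizedMatrix,
    filter_low_coverage,
    fit_mean_variance,
    guide_phenotypes,
    median_normalize,
    nb_pvalues,
    screen_guides,
)
from tests.conftest import make_count_matrix


def two_sample_matrix(library, a, b, roles=("control", "treatment")):
    return make_count_matrix(library, {"s1": a, "s2": b}, roles)


class TestMedianNormalize:
    def test_identical_samples_unchanged(self, tiny_library):
        col = [100, 200, 300, 400, 500, 600, 700, 800]
        m = two_sample_matrix(tiny_library, col, col)
        norm = median_normalize(m, threshold=0)
        np.testing.assert_allclose(norm.size_factors, 1.0)
        np.testing.assert_allclose(norm.values["s1"], col)

    def test_doubled_sample_gets_double_size_factor(self, tiny_library):
        """Median-of-ratios: B = 2A gives size factors in ratio 1:2 and
        identical normalized columns."""
        a = np.array([100, 200, 300, 400, 150, 250, 350, 450])
        m = two_sample_matrix(tiny_library, a, 2 * a)
        norm = median_normalize(m, threshold=0)
        sf = norm.size_factors
        assert sf["s2"] / sf["s1"] == pytest.approx(2.0)
        # geometric mean of size factors fixed to 1
        assert np.exp(np.log(sf).mean()) == pytest.approx(1.0)
        np.testing.assert_allclose(norm.values["s1"], norm.values["s2"])

    def test_zero_guide_excluded_from_median_but_normalized(self, tiny_library):
        """A guide with one zero drops out of the size-factor median; the
        oracle is the explicit median over the qualifying subset."""
        a = np.array([100, 200, 300, 400, 150, 250, 350, 0])
        b = np.array([200, 400, 600, 800, 300, 500, 700, 90])
        m = two_sample_matrix(tiny_library, a, b)
        norm = median_normalize(m, threshold=0)
        qual = (a > 0) & (b > 0)
        geo = np.sqrt(a[qual] * b[qual])
        raw_sf = np.array([np.median(a[qual] / geo), np.median(b[qual] / geo)])
        expected = raw_sf / np.exp(np.mean(np.log(raw_sf)))
        np.testing.assert_allclose(norm.size_factors, expected)
        # the zero-carrying guide is still normalized
        assert norm.values.loc["ntc_sg1", "s2"] == pytest.approx(90 / expected[1])

    def test_idempotent(self, tiny_library):
        a = np.array([100, 200, 300, 400, 150, 250, 350, 450])
        m = two_sample_matrix(tiny_library, a, 3 * a + 10)
        norm = median_normalize(m, threshold=0)
        renorm_sf = _size_factors_of(norm.values)
        np.testing.assert_allclose(renorm_sf, 1.0, atol=1e-12)

    def test_scale_equivariance(self, tiny_library):
        """Multiplying one sample's raw counts by c leaves the normalized
        matrix unchanged up to a single global factor (the per-guide
        geometric-mean reference shifts by c**(1/K), so exact invariance
        is not attainable under median-of-ratios); all between-sample
        ratios are invariant."""
        a = np.array([100, 200, 300, 400, 150, 250, 350, 450])
        m1 = two_sample_matrix(tiny_library, a, a + 37)
        m2 = two_sample_matrix(tiny_library, a, 5 * (a + 37))
        n1 = median_normalize(m1, threshold=0)
        n2 = median_normalize(m2, threshold=0)
        ratio = n2.values.to_numpy() / n1.values.to_numpy()
        np.testing.assert_allclose(ratio, ratio.flat[0])
        np.testing.assert_allclose(
            n1.values["s2"] / n1.values["s1"], n2.values["s2"] / n2.values["s1"]
        )

    def test_all_zero_sample_errors(self, tiny_library):
        with pytest.raises(ValueError, match="all-zero"):
            median_normalize(two_sample_matrix(tiny_library, [1] * 8, [0] * 8))

    def test_no_common_nonzero_guide_errors(self, tiny_library):
        a = [1, 0, 1, 0, 1, 0, 1, 0]
        b = [0, 1, 0, 1, 0, 1, 0, 1]
        with pytest.raises(ValueError, match="pseudo-reference"):
            median_normalize(two_sample_matrix(tiny_library, a, b))


def _size_factors_of(values: pd.DataFrame) -> np.ndarray:
    arr = values.to_numpy(dtype=float)
    ref = (arr > 0).all(axis=1)
    geo = np.exp(np.log(arr[ref]).mean(axis=1, keepdims=True))
    sf = np.median(arr[ref] / geo, axis=0)
    return sf / np.exp(np.mean(np.log(sf)))


class TestFilterLowCoverage:
    def test_99_reads_excluded_100_retained(self, tiny_library):
        """'Fewer than 100 reads across the control AAV samples' is an
        inclusive >= 100 retention rule on the control sum."""
        a = [60, 100, 0, 100, 100, 100, 100, 100]
        b = [39, 0, 0, 100, 100, 100, 100, 100]
        m = make_count_matrix(
            tiny_library, {"c1": a, "c2": b, "t": [1] * 8},
            ["control", "control", "treatment"],
        )
        mask = filter_low_coverage(m, threshold=100)
        assert not mask["geneA_sg0"]  # 60 + 39 = 99 -> excluded
        assert mask["geneA_sg1"]  # 100 + 0 -> retained
        assert not mask["geneB_sg0"]

    def test_threshold_zero_keeps_all(self, tiny_library):
        m = two_sample_matrix(tiny_library, [0] * 7 + [1], [1] * 8)
        assert filter_low_coverage(m, threshold=0).all()

    def test_treatment_counts_ignored(self, tiny_library):
        m = two_sample_matrix(tiny_library, [99] * 8, [10**6] * 8)
        assert not filter_low_coverage(m, threshold=100).any()

    def test_requires_controls(self, tiny_library):
        m = make_count_matrix(
            tiny_library, {"t1": [5] * 8, "t2": [5] * 8}, ["treatment", "treatment"]
        )
        with pytest.raises(ValueError, match="control"):
            filter_low_coverage(m)


def normalized_from_controls(values: np.ndarray, guide_ids=None) -> NormalizedMatrix:
    n, k = values.shape
    idx = guide_ids or [f"g{i}" for i in range(n)]
    cols = [f"c{j}" for j in range(k)]
    df = pd.DataFrame(values, index=idx, columns=cols)
    return NormalizedMatrix(
        values=df,
        size_factors=pd.Series(1.0, index=cols),
        samples=pd.DataFrame({"role": "control"}, index=pd.Index(cols, name="sample_id")),
        filter_mask=pd.Series(True, index=df.index),
        filter_reason=pd.Series("", index=df.index),
    )


class TestFitMeanVariance:
    def test_exact_line_recovered(self):
        """Guides placed exactly on log v = -1 + 1.5 log m fit (a,b)=(-1,1.5)."""
        means = np.geomspace(100, 10_000, 40)
        variances = np.exp(-1 + 1.5 * np.log(means))
        half = np.sqrt(variances / 2)  # two-point sample with exact mean/variance
        values = np.column_stack([means - half, means + half])
        fit = fit_mean_variance(normalized_from_controls(values))
        assert fit.intercept == pytest.approx(-1.0, abs=1e-8)
        assert fit.slope == pytest.approx(1.5, abs=1e-8)
        assert fit.weighted_r2 == pytest.approx(1.0)

    def test_poisson_counts_give_unit_slope(self):
        """Poisson data have variance = mean: slope ~ 1, intercept ~ 0."""
        rng = np.random.default_rng(7)
        means = np.geomspace(100, 10_000, 400)
        values = rng.poisson(means[:, None], size=(400, 10)).astype(float)
        fit = fit_mean_variance(normalized_from_controls(values))
        assert fit.slope == pytest.approx(1.0, abs=0.1)
        assert abs(fit.intercept) < 0.5

    def test_zero_variance_guide_excluded_but_predicted(self):
        means = np.geomspace(100, 10_000, 20)
        variances = np.exp(0.5 + 1.2 * np.log(means))
        half = np.sqrt(variances / 2)
        values = np.column_stack([means - half, means + half])
        values[0] = [500.0, 500.0]  # zero-variance guide
        fit = fit_mean_variance(normalized_from_controls(values))
        assert fit.n_points == 19
        assert np.isfinite(fit.predict_variance(500.0))

    def test_single_control_errors(self):
        with pytest.raises(ValueError, match="2 control samples"):
            fit_mean_variance(normalized_from_controls(np.ones((5, 1)) * 100))

    def test_variance_floor(self):
        fit = MeanVarianceFit(intercept=-10.0, slope=1.0, n_points=10, weighted_r2=1.0)
        mean = 200.0
        assert fit.predict_variance(mean) > mean  # floored above the mean


def nb_tail_oracle(k, mean, variance):
    """Brute-force NB lower tail by explicit pmf summation (log-gamma form)."""
    r = mean**2 / (variance - mean)
    p = r / (r + mean)
    total = 0.0
    for x in range(int(k) + 1):
        log_pmf = (
            math.lgamma(x + r) - math.lgamma(r) - math.lgamma(x + 1)
            + r * math.log(p) + x * math.log(1 - p)
        )
        total += math.exp(log_pmf)
    return total


class TestNbPvalues:
    def test_poisson_limit(self):
        """With variance floored to the mean, the NB tail approaches the
        Poisson CDF computed by brute-force summation."""
        mean = 50.0
        for k in [20, 50, 80]:
            p_under, _ = nb_pvalues(float(k), mean, fit=None)
            poisson_cdf = sum(
                math.exp(-mean + x * math.log(mean) - math.lgamma(x + 1))
                for x in range(k + 1)
            )
            assert p_under == pytest.approx(poisson_cdf, rel=1e-4)

    def test_zero_observed_equals_pmf_at_zero(self):
        fit = MeanVarianceFit(intercept=0.0, slope=0.0, n_points=2, weighted_r2=1.0)
        # fitted variance exp(0)=1 < mean -> supply explicit line through var=100
        mean, var = 50.0, 100.0
        fit = MeanVarianceFit(
            intercept=math.log(var) - math.log(mean), slope=1.0, n_points=2, weighted_r2=1.0
        )
        p_under, p_over = nb_pvalues(0.0, mean, fit)
        assert p_under == pytest.approx(nb_tail_oracle(0, mean, var), rel=1e-12)
        assert p_over == pytest.approx(1.0)

    def test_both_tails_cover_observed_point(self):
        fit = MeanVarianceFit(intercept=1.0, slope=1.0, n_points=2, weighted_r2=1.0)
        p_under, p_over = nb_pvalues(200.0, 200.0, fit)
        assert p_under + p_over >= 1.0
        assert 0 < p_under <= 1 and 0 < p_over <= 1

    def test_monotone_in_observed(self):
        fit = MeanVarianceFit(intercept=0.7, slope=1.1, n_points=2, weighted_r2=1.0)
        ks = np.arange(0, 400, dtype=float)
        p_under, p_over = nb_pvalues(ks, np.full_like(ks, 150.0), fit)
        assert (np.diff(p_under) >= 0).all()
        assert (np.diff(p_over) <= 0).all()

    def test_rounding_half_up(self):
        fit = MeanVarianceFit(intercept=1.0, slope=1.0, n_points=2, weighted_r2=1.0)
        a = nb_pvalues(10.5, 100.0, fit)
        b = nb_pvalues(11.0, 100.0, fit)
        assert a == b

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            nb_pvalues(float("nan"), 100.0, None)

    def test_null_calibration_near_uniform(self):
        """Treatment drawn from the control NB: p_under is near-uniform
        (Kolmogorov distance < 0.1 at 5,000 guides, counts >= 100)."""
        rng = np.random.default_rng(21)
        n_guides = 5000
        means = rng.uniform(100, 5000, size=n_guides)
        var = 2.0 * means  # true trend: a=ln 2, b=1
        r = means**2 / (var - means)
        p_param = r / (r + means)
        controls = rng.negative_binomial(r[:, None], p_param[:, None], size=(n_guides, 10))
        treatment = rng.negative_binomial(r, p_param)
        norm = normalized_from_controls(controls.astype(float))
        fit = fit_mean_variance(norm)
        p_under, _ = nb_pvalues(
            treatment.astype(float), controls.mean(axis=1), fit
        )
        d = stats.kstest(p_under, "uniform").statistic
        assert d < 0.1


class TestGuidePhenotypes:
    def _norm(self, tiny_library, control, treatment):
        m = two_sample_matrix(tiny_library, control, treatment)
        return median_normalize(m, threshold=0)

    def test_equal_means_zero_phi(self, tiny_library):
        col = [100, 200, 300, 400, 500, 600, 700, 800]
        norm = self._norm(tiny_library, col, col)
        np.testing.assert_allclose(guide_phenotypes(norm, pseudocount=0.0), 0.0)

    def test_fourfold_change_without_pseudocount(self, tiny_library):
        values = pd.DataFrame(
            {"c": [100.0] * 8, "t": [400.0] * 8},
            index=tiny_library.guide_ids,
        )
        norm = NormalizedMatrix(
            values=values,
            size_factors=pd.Series(1.0, index=["c", "t"]),
            samples=pd.DataFrame(
                {"role": ["control", "treatment"]},
                index=pd.Index(["c", "t"], name="sample_id"),
            ),
            filter_mask=pd.Series(True, index=values.index),
            filter_reason=pd.Series("", index=values.index),
        )
        np.testing.assert_allclose(guide_phenotypes(norm, pseudocount=0.0), 2.0)

    def test_full_depletion_stays_finite(self, tiny_library):
        values = pd.DataFrame(
            {"c": [100.0] * 8, "t": [0.0] * 8}, index=tiny_library.guide_ids
        )
        norm = NormalizedMatrix(
            values=values,
            size_factors=pd.Series(1.0, index=["c", "t"]),
            samples=pd.DataFrame(
                {"role": ["control", "treatment"]},
                index=pd.Index(["c", "t"], name="sample_id"),
            ),
            filter_mask=pd.Series(True, index=values.index),
            filter_reason=pd.Series("", index=values.index),
        )
        phi = guide_phenotypes(norm, pseudocount=0.5)
        np.testing.assert_allclose(phi, np.log2(0.5 / 100.5))
        assert np.isfinite(phi).all()


class TestScreenGuides:
    def test_depleted_guide_flagged(self, tiny_library):
        rng = np.random.default_rng(3)
        base = rng.integers(800, 1200, size=8)
        c1, c2 = rng.poisson(base), rng.poisson(base)
        t = rng.poisson(base)
        t[0] = base[0] // 20  # strong depletion of geneA_sg0
        m = make_count_matrix(
            tiny_library,
            {"c1": c1, "c2": c2, "t1": t},
            ["control", "control", "treatment"],
        )
        res = screen_guides(m, filter_threshold=100)
        assert res.loc["geneA_sg0", "p_under"] < 1e-6
        assert res.loc["geneA_sg0", "phi"] < -2
        assert res["p_under"].between(0, 1).all()

    def test_per_mouse_mode_single_column(self, tiny_library):
        rng = np.random.default_rng(4)
        base = rng.integers(800, 1200, size=8)
        m = make_count_matrix(
            tiny_library,
            {
                "c1": rng.poisson(base),
                "c2": rng.poisson(base),
                "m1": rng.poisson(base),
                "m2": rng.poisson(base // 10),
            },
            ["control", "control", "treatment", "treatment"],
        )
        res_m1 = screen_guides(m, treatment_sample="m1")
        res_m2 = screen_guides(m, treatment_sample="m2")
        # normalization absorbs the depth difference between mice
        assert (res_m1["observed"] > 0).all()
        assert not res_m1["observed"].equals(res_m2["observed"])
        with pytest.raises(ValueError, match="not a treatment sample"):
            screen_guides(m, treatment_sample="c1")
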
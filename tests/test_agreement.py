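"""Agreement battery: gating logic, Bland-Altman identities, and
cross-validation of every statistic against R (the stats package), run
once in batch over random samples."""

import subprocess

import numpy as np
import pytest
from hypothesis import given, strategies as st

from strainpost import (
    PairedMeasurements,
    compare_methods,
    generate_paired_gls,
    qq_data,
    shapiro_wilk,
)
from strainpost.errors import DegenerateSampleError, UsageError


def _pairs(a, b):
    return PairedMeasurements(labels=[str(i) for i in range(len(a))], a=a, b=b)


class TestShapiroWilk:
    def test_table_differences_with_repair_are_normal(self):
        from strainpost import load_gls_validation_pairs

        p = load_gls_validation_pairs("published")
        res = shapiro_wilk(p.a - p.b)
        assert res.normal and res.p_value > 0.05

    def test_skewed_sample_rejected(self, rng):
        res = shapiro_wilk(rng.lognormal(0, 1, 100))
        assert not res.normal

    def test_affine_invariance_of_w(self, rng):
        x = rng.normal(0, 1, 40)
        w1 = shapiro_wilk(x).statistic
        w2 = shapiro_wilk(3.5 * x - 7.0).statistic
        assert w1 == pytest.approx(w2, rel=1e-9)

    def test_constant_sample_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            shapiro_wilk(np.full(10, 2.0))

    def test_n_bounds(self):
        with pytest.raises(UsageError):
            shapiro_wilk(np.array([1.0, 2.0]))


class TestQQ:
    def test_points_of_own_quantiles_are_collinear(self):
        from scipy.stats import norm

        n = 25
        x = norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        qq = qq_data(x)
        # the points themselves sit exactly on y = x ...
        np.testing.assert_allclose(qq.ordered, qq.theoretical, atol=1e-12)
        # ... while the quartile-anchored line (which interpolates order
        # statistics) is near, not exactly, the identity
        assert qq.slope == pytest.approx(1.0, rel=0.06)
        assert qq.intercept == pytest.approx(0.0, abs=1e-9)

    def test_location_shifts_intercept_not_slope(self, rng):
        x = rng.normal(0, 2, 50)
        q1, q2 = qq_data(x), qq_data(x + 5.0)
        assert q2.slope == pytest.approx(q1.slope)
        assert q2.intercept == pytest.approx(q1.intercept + 5.0)

    def test_slope_tracks_sample_spread(self, rng):
        x = rng.normal(0, 3.0, 2000)
        qq = qq_data(x)
        assert qq.slope == pytest.approx(3.0, rel=0.1)


class TestCompareMethods:
    def test_identity_comparison_degenerate(self, rng):
        a = rng.normal(-15, 4, 30)
        report = compare_methods(_pairs(a, a.copy()))
        assert report.bland_altman.bias == 0
        assert report.bland_altman.sd_diff == 0
        assert report.r == pytest.approx(1.0)
        assert report.p_value == 1.0
        assert report.verdict.equivalent
        assert any("zero" in w for w in report.warnings)

    def test_two_point_loa_hand_computed(self, rng):
        # differences {+1, -1} repeated: sd with n-1 denominator, LoA = ±1.96 sd
        a = np.array([0.0, 0.0, 10.0, 10.0])
        b = a - np.array([1.0, -1.0, 1.0, -1.0])
        report = compare_methods(_pairs(a, b))
        ba = report.bland_altman
        assert ba.bias == pytest.approx(0.0)
        assert ba.sd_diff == pytest.approx(np.sqrt(4 / 3))
        assert ba.loa_high - ba.loa_low == pytest.approx(2 * ba.dispersion)

    @given(st.integers(0, 500))
    def test_bland_altman_identity(self, seed):
        pairs = generate_paired_gls(20, bias=0.3, sd_diff=1.0, seed=seed)
        report = compare_methods(pairs)
        ba = report.bland_altman
        assert ba.loa_high - ba.bias == pytest.approx(1.96 * ba.sd_diff)
        assert ba.bias - ba.loa_low == pytest.approx(1.96 * ba.sd_diff)

    @given(st.integers(0, 200))
    def test_gate_consistency(self, seed):
        """Pearson only when both marginals normal; t only when d normal."""
        rng = np.random.default_rng(seed)
        # mix of normal and lognormal marginals to exercise both gates
        if seed % 2:
            a = rng.lognormal(2.5, 0.6, 30)
        else:
            a = rng.normal(-15, 4, 30)
        b = a - 0.4 + rng.normal(0, 0.6, 30) ** (3 if seed % 3 == 0 else 1)
        report = compare_methods(_pairs(a, b))
        if report.correlation_method == "pearson":
            assert report.normal_a.normal and report.normal_b.normal
        if report.test_method == "t_paired":
            assert report.normal_diff is None or report.normal_diff.normal
        if report.normal_diff is not None and not report.normal_diff.normal:
            assert report.test_method == "wilcoxon"

    def test_large_constructed_bias_fails_verdict(self):
        pairs = generate_paired_gls(200, bias=3.0, sd_diff=0.3, seed=4)
        report = compare_methods(pairs)
        assert not report.verdict.bias_ok
        assert not report.verdict.equivalent

    def test_bland_altman_points_orientation(self, gls_pairs):
        from strainpost import bland_altman_points

        pts = bland_altman_points(gls_pairs)
        assert pts.shape == (48, 2)
        assert pts[0, 0] == pytest.approx(-17.89)
        assert pts[0, 1] == pytest.approx(-0.02)


# ---------------------------------------------------------------------------
# independent oracle: R's stats package (the toolchain the battery mirrors);
# the batch fixture lives in conftest.py


class TestROracleEquivalence:
    """Every statistic and both gates agree with R to 6 significant figures."""

    def test_full_battery_matches_r(self, r_battery_oracle):
        samples, expected = r_battery_oracle
        assert len(expected) == 100
        for sid, (a, b) in samples.items():
            ref = expected[sid]
            sw = shapiro_wilk(a)
            assert sw.statistic == pytest.approx(ref["sw_w"], rel=1e-6)
            assert sw.p_value == pytest.approx(ref["sw_p"], rel=1e-6)
            report = compare_methods(_pairs(a, b))
            assert report.correlation_method == ref["corr_method"]
            assert report.r == pytest.approx(ref["r"], rel=1e-6)
            assert report.test_method == ref["test_method"]
            assert report.p_value == pytest.approx(ref["p"], rel=1e-6)

    def test_qq_matches_r_qqnorm_qqline(self, gls_pairs):
        """Q-Q points and the quartile line reproduce R's qqnorm/qqline."""
        d = gls_pairs.a - gls_pairs.b
        qq = qq_data(d)
        script = (
            "x <- c(%s); q <- qqnorm(x, plot.it=FALSE); "
            "o <- order(q$x); "
            "y4 <- quantile(x, c(0.25, 0.75), names=FALSE); "
            "x4 <- qnorm(c(0.25, 0.75)); "
            "slope <- diff(y4)/diff(x4); int <- y4[1] - slope*x4[1]; "
            "cat(sprintf('%%.12g', c(q$x[o], q$y[o], slope, int)), sep=',')"
            % ",".join(f"{v:.12g}" for v in d)
        )
        res = subprocess.run(
            ["Rscript", "--vanilla", "-e", script],
            check=True, capture_output=True, text=True, timeout=120,
        )
        vals = np.array([float(v) for v in res.stdout.split(",")])
        n = d.size
        np.testing.assert_allclose(qq.theoretical, vals[:n], rtol=1e-6)
        np.testing.assert_allclose(qq.ordered, vals[n : 2 * n], rtol=1e-6)
        assert qq.slope == pytest.approx(vals[-2], rel=1e-6)
        assert qq.intercept == pytest.approx(vals[-1], rel=1e-6)
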
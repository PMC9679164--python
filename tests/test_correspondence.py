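import numpy as np
import pandas as pd
import pytest

from photoprf.correspondence import (
    CorrespondenceResult,
    PairedAngleSample,
    aic_weight_identity,
    correspondence_analysis,
    fisher_lee_correlation,
    linear_correspondence,
    normative_range,
    orthogonal_regression,
    pair_maps,
    permutation_test_cc,
    wrap_angle,
)


def fisher_lee_bruteforce(theta_deg, phi_deg):
    """Independent double-loop oracle for the circular correlation."""
    t = np.deg2rad(theta_deg)
    p = np.deg2rad(phi_deg)
    n = len(t)
    num = s1 = s2 = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            st, sp = np.sin(t[i] - t[j]), np.sin(p[i] - p[j])
            num += st * sp
            s1 += st * st
            s2 += sp * sp
    return num / np.sqrt(s1 * s2)


class TestWrapAngle:
    def test_maps_into_half_open_interval(self):
        a = np.array([-540.0, -180.0, -179.9, 0.0, 179.9, 180.0, 360.0, 541.0])
        w = wrap_angle(a)
        assert np.all((w > -180) & (w <= 180))

    def test_boundary_maps_to_plus_180(self):
        assert wrap_angle(-180.0) == 180.0
        assert wrap_angle(180.0) == 180.0


class TestOrthogonalRegression:
    def test_identity_line_recovered_exactly(self):
        th = np.linspace(-170, 170, 50)
        slope, intercept = orthogonal_regression(PairedAngleSample(th, th))
        assert np.isclose(slope, 1.0)
        assert np.isclose(intercept, 0.0, atol=1e-10)

    def test_exact_affine_line(self):
        th = np.linspace(-80, 80, 40)
        slope, intercept = orthogonal_regression(
            PairedAngleSample(th, 2 * th + 10)
        )
        assert np.isclose(slope, 2.0)
        assert np.isclose(intercept, 10.0)

    def test_tls_unattenuated_where_ols_shrinks(self):
        # symmetric noise on both axes: TLS stays near slope 1, OLS dips below
        rng = np.random.default_rng(1)
        base = rng.uniform(-150, 150, 4000)
        th = base + rng.normal(0, 30, base.size)
        ph = base + rng.normal(0, 30, base.size)
        slope, _ = orthogonal_regression(PairedAngleSample(th, ph))
        ols = np.polyfit(th, ph, 1)[0]
        assert abs(slope - 1.0) < 0.05
        assert ols < 0.95

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            orthogonal_regression(PairedAngleSample(np.zeros(5), np.zeros(5)))


class TestAICWeight:
    def test_near_identity_data_strongly_supports_correspondence(self):
        rng = np.random.default_rng(2)
        th = rng.uniform(-180, 180, 500)
        ph = th + rng.normal(0, 5, 500)
        assert aic_weight_identity(PairedAngleSample(th, ph)) > 0.999

    def test_independent_angles_reject_correspondence(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(50):
            th = rng.uniform(-180, 180, 500)
            ph = rng.uniform(-180, 180, 500)
            if aic_weight_identity(PairedAngleSample(th, ph)) < 0.01:
                hits += 1
        assert hits >= 48  # >= 95% of replicates

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(4)
        th = rng.uniform(-180, 180, 30)
        ph = rng.uniform(-180, 180, 30)
        sample = PairedAngleSample(th, ph)
        n = sample.n

        def rss(r):
            return float(r @ r)

        aics = {
            "identity": n * np.log(rss(ph - th) / n) + 2,
            "horizontal": n * np.log(rss(ph - ph.mean()) / n) + 4,
            "vertical": n * np.log(rss(th - th.mean()) / n) + 4,
        }
        amin = min(aics.values())
        rel = {m: np.exp(-0.5 * (a - amin)) for m, a in aics.items()}
        expected = rel["identity"] / sum(rel.values())
        assert np.isclose(aic_weight_identity(sample), expected, atol=1e-12)

    def test_perfect_identity_handled_by_rss_floor(self):
        th = np.linspace(-90, 90, 20)
        w = aic_weight_identity(PairedAngleSample(th, th.copy()))
        assert 0.999 < w <= 1.0

    def test_wrapped_variant_available(self):
        rng = np.random.default_rng(5)
        th = rng.uniform(-180, 180, 300)
        ph = wrap_angle(th + rng.normal(0, 5, 300))
        assert aic_weight_identity(PairedAngleSample(th, ph), wrap=True) > 0.999


class TestFisherLee:
    def test_identity_gives_one(self):
        th = np.linspace(-170, 170, 30)
        assert np.isclose(fisher_lee_correlation(PairedAngleSample(th, th)), 1.0)

    def test_reflection_gives_minus_one(self):
        th = np.linspace(-170, 170, 30)
        assert np.isclose(fisher_lee_correlation(PairedAngleSample(th, -th)), -1.0)

    def test_matches_bruteforce_oracle_on_random_samples(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = rng.integers(5, 15)
            th = rng.uniform(-180, 180, n)
            ph = rng.uniform(-180, 180, n)
            got = fisher_lee_correlation(PairedAngleSample(th, ph))
            assert np.isclose(got, fisher_lee_bruteforce(th, ph), atol=1e-12)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(7)
        th = rng.uniform(-180, 180, 40)
        ph = rng.uniform(-180, 180, 40)
        base = fisher_lee_correlation(PairedAngleSample(th, ph))
        rotated = fisher_lee_correlation(
            PairedAngleSample(wrap_angle(th + 73.0), wrap_angle(ph - 141.0))
        )
        assert np.isclose(base, rotated, atol=1e-12)

    def test_degenerate_map_returns_nan(self):
        th = np.full(10, 30.0)
        ph = np.linspace(-90, 90, 10)
        assert np.isnan(fisher_lee_correlation(PairedAngleSample(th, ph)))


class TestPermutationTest:
    def test_identity_sample_gets_minimum_pvalue(self):
        rng = np.random.default_rng(8)
        th = rng.uniform(-180, 180, 200)
        p = permutation_test_cc(PairedAngleSample(th, th), n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(9)
        th = rng.uniform(-180, 180, 50)
        ph = rng.uniform(-180, 180, 50)
        s = PairedAngleSample(th, ph)
        assert permutation_test_cc(s, 199, seed=5) == permutation_test_cc(
            s, 199, seed=5
        )

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(10)
        pvals = []
        for i in range(100):
            th = rng.uniform(-180, 180, 30)
            ph = rng.uniform(-180, 180, 30)
            pvals.append(
                permutation_test_cc(PairedAngleSample(th, ph), 199, seed=i)
            )
        frac = np.mean(np.array(pvals) < 0.05)
        assert 0.0 <= frac <= 0.12  # ~0.05 within binomial error


class TestPairMaps:
    def test_requires_threshold_in_both_maps(self):
        rod = pd.DataFrame(
            {"vertex": [0, 1, 2, 3], "polar": [10.0, 20, 30, 40],
             "r2": [0.5, 0.01, 0.5, 0.5]}
        )
        cone = pd.DataFrame(
            {"vertex": [0, 1, 2, 3], "polar": [11.0, 21, 31, 41],
             "r2": [0.5, 0.5, 0.02, 0.5]}
        )
        sample = pair_maps(rod, cone, r2_min=0.03)
        assert list(sample.vertex_ids) == [0, 3]


class TestCorrespondenceAnalysis:
    def test_small_sample_yields_nan_statistics(self):
        res = correspondence_analysis(
            PairedAngleSample(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        )
        assert np.isnan(res.aic_w) and np.isnan(res.cc_fl)
        assert res.n == 2

    def test_linear_variant_uses_pearson(self):
        rng = np.random.default_rng(11)
        th = rng.uniform(0.5, 8.6, 100)  # e.g. eccentricity
        ph = th + rng.normal(0, 0.2, 100)
        res = linear_correspondence(PairedAngleSample(th, ph))
        assert np.isclose(
            res.cc_fl, np.corrcoef(th, ph)[0, 1], atol=1e-12
        )
        assert res.aic_w > 0.99


class TestNormativeRange:
    @staticmethod
    def make_controls(rng, n=20):
        pts = rng.multivariate_normal([1.0, 0.0], [[0.01, 0], [0, 25.0]], size=n)
        return [
            CorrespondenceResult(s, i, 1.0, rng.uniform(0.3, 0.9), 0.001, 500)
            for s, i in pts
        ]

    def test_mean_point_is_inside(self):
        rng = np.random.default_rng(12)
        controls = self.make_controls(rng)
        env = normative_range(controls)
        assert env.contains_ellipse(*env.mean)

    def test_distant_point_is_outside(self):
        rng = np.random.default_rng(13)
        env = normative_range(self.make_controls(rng))
        far = env.mean + 10 * np.sqrt(np.diag(env.cov))
        assert not env.contains_ellipse(*far)

    def test_nan_result_classifies_outside(self):
        rng = np.random.default_rng(14)
        env = normative_range(self.make_controls(rng))
        res = CorrespondenceResult(np.nan, np.nan, np.nan, np.nan, np.nan, 0)
        assert env.classify(res) == {"ellipse": False, "cc_fl": False}

    def test_too_few_controls_error(self):
        rng = np.random.default_rng(15)
        with pytest.raises(ValueError, match="three"):
            normative_range(self.make_controls(rng, n=2))
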
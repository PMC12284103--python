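import numpy as np
import pytest
from scipy import stats

from microcort.spatial_inference import (
    anova_oneway,
    class_adjusted_r2,
    fdr_bh,
    spin_assignment,
    spin_permutations,
    spin_test_correlation,
    tertile_contrast,
    tukey_hsd,
)
from microcort.synthetic_cortex import (
    ClassAtlas,
    RegionMap,
    SmoothMapSampler,
    gen_class_atlas,
    gen_smooth_map,
)


class TestSpinPermutations:
    def test_identity_rotation_identity_assignment(self, std_geom):
        perm = spin_assignment(std_geom, np.eye(3))
        assert np.array_equal(perm, np.arange(std_geom.n_parcels))

    def test_rotation_times_inverse_is_identity(self, std_geom, rng):
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        perm = spin_assignment(std_geom, q @ q.T)
        assert np.array_equal(perm, np.arange(std_geom.n_parcels))

    def test_rows_are_valid_parcel_indices_within_hemisphere(self, std_geom):
        null = spin_permutations(std_geom, 20, seed=3)
        hemi = std_geom.hemisphere
        for row in null.permutations:
            assert (hemi[row] == hemi).all()
            assert row.min() >= 0 and row.max() < std_geom.n_parcels

    def test_duplication_rate_bounded(self, std_geom):
        null = spin_permutations(std_geom, 100, seed=3)
        assert null.duplication_rate < 0.15

    def test_null_mean_unbiased(self, std_geom):
        # per-parcel null means match the parcel's own hemisphere mean (the
        # spin's exchangeability class); with 1000 spins the worst of 360
        # parcels carries ~3 sigma of Monte-Carlo noise (~0.1 SD), so the
        # systematic-bias check uses the mean |bias|
        null = spin_permutations(std_geom, 1000, seed=4)
        x = gen_smooth_map(std_geom, 0.4, seed=5).values
        hemi_mean = np.where(
            std_geom.hemisphere == "L",
            x[std_geom.hemisphere == "L"].mean(),
            x[std_geom.hemisphere == "R"].mean(),
        )
        bias = (null.apply(x).mean(axis=0) - hemi_mean) / x.std()
        assert np.abs(bias).mean() < 0.05
        assert np.abs(bias).max() < 0.15

    def test_nperm_required(self, std_geom):
        with pytest.raises(ValueError):
            spin_permutations(std_geom, 0, seed=1)

    def test_seed_determinism(self, std_geom):
        a = spin_permutations(std_geom, 5, seed=9)
        b = spin_permutations(std_geom, 5, seed=9)
        assert np.array_equal(a.permutations, b.permutations)


class TestSpinTestCorrelation:
    def test_self_correlation_minimum_p(self, std_geom):
        null = spin_permutations(std_geom, 100, seed=1)
        x = gen_smooth_map(std_geom, 0.4, seed=2)
        res = spin_test_correlation(x, x, null, "greater")
        assert res.p == pytest.approx(1.0 / 101.0)

    def test_observed_statistic_is_plain_pearson(self, std_geom):
        null = spin_permutations(std_geom, 50, seed=1)
        x = gen_smooth_map(std_geom, 0.4, seed=2)
        y = gen_smooth_map(std_geom, 0.4, seed=3)
        res = spin_test_correlation(x, y, null)
        assert res.statistic == pytest.approx(
            np.corrcoef(x.values, y.values)[0, 1]
        )

    def test_add_one_rule_lower_bound(self, std_geom):
        null = spin_permutations(std_geom, 37, seed=1)
        x = gen_smooth_map(std_geom, 0.4, seed=2)
        y = gen_smooth_map(std_geom, 0.4, seed=3)
        for alt in ("greater", "less", "two-sided"):
            assert spin_test_correlation(x, y, null, alt).p >= 1.0 / 38.0

    def test_zero_variance_errors(self, std_geom):
        null = spin_permutations(std_geom, 10, seed=1)
        x = RegionMap(np.ones(std_geom.n_parcels), "c")
        y = gen_smooth_map(std_geom, 0.4, seed=3)
        with pytest.raises(ValueError):
            spin_test_correlation(x, y, null)


class TestFdrBh:
    def test_printed_example_all_rejected(self):
        reject, _ = fdr_bh(np.array([0.01, 0.02, 0.03, 0.04]), q=0.05)
        assert reject.all()

    def test_all_ones_none_rejected(self):
        reject, adj = fdr_bh(np.ones(10), q=0.05)
        assert not reject.any()
        assert np.allclose(adj, 1.0)

    def test_bruteforce_maxk_oracle(self, rng):
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 30))
            q = 0.05
            reject, adj = fdr_bh(p, q)
            # independent oracle: largest k with p_(k) <= k q / m
            order = np.argsort(p)
            ks = np.flatnonzero(p[order] <= q * np.arange(1, p.size + 1) / p.size)
            expected = np.zeros(p.size, dtype=bool)
            if ks.size:
                expected[order[: ks.max() + 1]] = True
            assert np.array_equal(reject, expected)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=50)
        reject, adj = fdr_bh(p, 0.05)
        sm_rej, sm_adj, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert np.array_equal(reject, sm_rej)
        assert np.allclose(adj, sm_adj)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            fdr_bh(np.array([]))


def _atlas(labels, names=None):
    labels = np.asarray(labels)
    n = labels.max() + 1
    return ClassAtlas(labels, names or [f"c{i}" for i in range(n)])


class TestAnovaOneway:
    def test_two_classes_f_equals_t_squared(self, rng):
        vals = rng.standard_normal(30)
        labels = np.repeat([0, 1], 15)
        res = anova_oneway(RegionMap(vals, "m"), _atlas(labels))
        t, p = stats.ttest_ind(vals[:15], vals[15:], equal_var=True)
        assert res.statistic == pytest.approx(t**2)
        assert res.p == pytest.approx(p)

    def test_calibration_uniform_p(self, rng):
        ps = []
        labels = np.repeat([0, 1, 2], 10)
        for _ in range(1000):
            vals = rng.standard_normal(30)
            ps.append(anova_oneway(RegionMap(vals, "m"), _atlas(labels)).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_zero_variance(self):
        res = anova_oneway(RegionMap(np.ones(10), "m"), _atlas(np.repeat([0, 1], 5)))
        assert np.isnan(res.statistic) and res.flag is not None

    def test_small_class_excluded(self, rng):
        vals = rng.standard_normal(11)
        labels = np.array([0] * 5 + [1] * 5 + [2])
        with pytest.warns(RuntimeWarning, match="excluded"):
            res = anova_oneway(RegionMap(vals, "m"), _atlas(labels))
        assert np.isfinite(res.statistic)


class TestTukeyHsd:
    def test_two_classes_matches_t_test(self, rng):
        vals = rng.standard_normal(40)
        labels = np.repeat([0, 1], 20)
        table = tukey_hsd(RegionMap(vals, "m"), _atlas(labels))
        _, p = stats.ttest_ind(vals[:20], vals[20:], equal_var=True)
        assert table.p_adjusted[0] == pytest.approx(p, abs=1e-6)
        # q = sqrt(2) t identity
        t = abs(stats.ttest_ind(vals[:20], vals[20:], equal_var=True).statistic)
        assert table.q_statistics[0] == pytest.approx(np.sqrt(2) * t)

    def test_familywise_calibration(self, rng):
        labels = np.repeat([0, 1, 2], 50)
        hits = 0
        n_sim = 400
        for _ in range(n_sim):
            vals = rng.standard_normal(150)
            table = tukey_hsd(RegionMap(vals, "m"), _atlas(labels))
            hits += (table.p_adjusted < 0.05).any()
        assert abs(hits / n_sim - 0.05) < 0.03

    def test_degenerate_no_rejections(self):
        table = tukey_hsd(RegionMap(np.ones(12), "m"), _atlas(np.repeat([0, 1, 2], 4)))
        assert (table.p_adjusted == 1.0).all()

    def test_single_class_errors(self, rng):
        with pytest.raises(ValueError):
            tukey_hsd(RegionMap(rng.standard_normal(5), "m"),
                      _atlas(np.zeros(5, dtype=int), ["a", "b"]))


class TestClassAdjustedR2:
    def test_exact_class_means_full_r2(self):
        labels = np.repeat([0, 1, 2], 10)
        vals = np.asarray([0.0, 5.0, -2.0])[labels]
        assert class_adjusted_r2(RegionMap(vals, "m"), _atlas(labels)) == pytest.approx(100.0)

    def test_independent_map_near_zero(self, rng):
        labels = np.repeat([0, 1, 2, 3], 25)
        vals_r2 = [
            class_adjusted_r2(RegionMap(rng.standard_normal(100), "m"), _atlas(labels))
            for _ in range(300)
        ]
        assert abs(np.mean(vals_r2)) < 2.0

    def test_matches_ols_dummies_oracle(self, rng):
        import statsmodels.api as sm

        labels = rng.integers(0, 4, 60)
        vals = rng.standard_normal(60) + labels * 0.5
        mine = class_adjusted_r2(RegionMap(vals, "m"), _atlas(labels))
        X = sm.add_constant(np.column_stack([(labels == c).astype(float)
                                             for c in (1, 2, 3)]))
        fit = sm.OLS(vals, X).fit()
        assert mine == pytest.approx(100 * fit.rsquared_adj)

    def test_may_be_negative(self, rng):
        labels = np.repeat(np.arange(10), 2)
        vals = rng.standard_normal(20)
        out = class_adjusted_r2(RegionMap(vals, "m"), _atlas(labels))
        assert out < 100.0  # reported as-is, possibly negative


class TestTertileContrast:
    def test_identical_map_degenerate(self, std_geom):
        m = RegionMap(np.ones(std_geom.n_parcels), "m")
        axis = gen_smooth_map(std_geom, 0.4, seed=1)
        res = tertile_contrast(m, axis, 60)
        assert res.statistic == 0.0 and res.flag is not None

    def test_power_for_planted_shift(self, std_geom, rng):
        axis = gen_smooth_map(std_geom, 0.4, seed=1)
        order = np.argsort(axis.values, kind="stable")
        rejections = 0
        n_sim = 100
        for _ in range(n_sim):
            vals = rng.standard_normal(std_geom.n_parcels)
            vals[order[-60:]] += 1.0  # one-SD shift in the top tertile
            res = tertile_contrast(RegionMap(vals, "m"), axis, 60)
            rejections += res.p < 0.05
        assert rejections / n_sim > 0.9

    def test_antisymmetry(self, std_geom, rng):
        axis = gen_smooth_map(std_geom, 0.4, seed=1)
        m = RegionMap(rng.standard_normal(std_geom.n_parcels), "m")
        flipped = RegionMap(-axis.values, "axis")
        a = tertile_contrast(m, axis, 60).statistic
        b = tertile_contrast(m, flipped, 60).statistic
        assert a == pytest.approx(-b)

    def test_size_bound(self, std_geom, rng):
        axis = gen_smooth_map(std_geom, 0.4, seed=1)
        m = RegionMap(rng.standard_normal(std_geom.n_parcels), "m")
        with pytest.raises(ValueError):
            tertile_contrast(m, axis, std_geom.n_parcels // 2 + 1)


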
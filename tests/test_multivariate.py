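import math

import numpy as np
import pytest

from microcort.multivariate import (
    distance_cv,
    dominance_analysis,
    mediation,
    multilinear_predict,
    pls_correlation,
)
from microcort.spatial_inference import spin_permutations
from microcort.synthetic_cortex import (
    RegionMap,
    gen_linear_target,
    gen_smooth_map,
    gen_two_block,
)


def _maps(geom, p, seeds=None):
    seeds = seeds or range(p)
    return [gen_smooth_map(geom, 0.4, seed=s, metric_name=f"x{s}") for s in seeds]


class TestMultilinearPredict:
    def test_exact_linear_r_one(self, small_geom):
        X = _maps(small_geom, 3)
        y = gen_linear_target(X, [1.0, -0.4, 0.2], 0.0, 0.4, small_geom, seed=7)
        res, fitted = multilinear_predict(X, y)
        assert res.statistic == pytest.approx(1.0)
        assert np.allclose(fitted.values, y.values, atol=1e-10)

    def test_affine_predictor_invariance(self, small_geom):
        X = _maps(small_geom, 3)
        y = gen_linear_target(X, [1.0, -0.4, 0.2], 0.5, 0.4, small_geom, seed=7)
        r1, _ = multilinear_predict(X, y)
        X2 = [RegionMap(3.0 * X[0].values - 1.0, "x0r"), X[1], X[2]]
        r2, _ = multilinear_predict(X2, y)
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_spin_p_for_self_prediction(self, std_geom):
        X = _maps(std_geom, 2)
        y = gen_linear_target(X, [1.0, 1.0], 0.0, 0.4, std_geom, seed=3)
        null = spin_permutations(std_geom, 200, seed=1)
        res, _ = multilinear_predict(X, y, null, "greater")
        assert res.p <= 0.05

    def test_too_many_predictors_errors(self, small_geom):
        X = _maps(small_geom, small_geom.n_parcels + 1)
        y = gen_smooth_map(small_geom, 0.4, seed=99)
        with pytest.raises(ValueError):
            multilinear_predict(X, y)

    def test_collinear_errors(self, small_geom):
        x0 = gen_smooth_map(small_geom, 0.4, seed=0)
        X = [x0, RegionMap(2.0 * x0.values, "dup")]
        y = gen_smooth_map(small_geom, 0.4, seed=9)
        with pytest.raises(ValueError, match="collinear"):
            multilinear_predict(X, y)


def _shapley_oracle(Z, yv):
    """Independent Shapley-value oracle with factorial weights."""
    from itertools import combinations

    p = Z.shape[1]

    def r2(cols):
        if not cols:
            return 0.0
        A = np.column_stack([np.ones(len(yv)), Z[:, list(cols)]])
        coef, *_ = np.linalg.lstsq(A, yv, rcond=None)
        resid = yv - A @ coef
        return 1 - (resid**2).sum() / ((yv - yv.mean()) ** 2).sum()

    out = np.zeros(p)
    for i in range(p):
        others = [j for j in range(p) if j != i]
        for size in range(p):
            w = math.factorial(size) * math.factorial(p - size - 1) / math.factorial(p)
            for s in combinations(others, size):
                out[i] += w * (r2(s + (i,)) - r2(s))
    return out


class TestDominanceAnalysis:
    def test_single_predictor(self, small_geom):
        X = _maps(small_geom, 1)
        y = gen_linear_target(X, [1.0], 0.5, 0.4, small_geom, seed=3)
        res = dominance_analysis(X, y)
        assert res.contributions[0] == pytest.approx(res.r2_full)
        assert res.shares_pct[0] == pytest.approx(100 * res.r2_full / res.adj_r2_full)

    def test_additivity_and_shapley_oracle(self, small_geom):
        X = _maps(small_geom, 5)
        y = gen_linear_target(X, [1.0, 0.5, -0.3, 0.2, 0.0], 0.8, 0.4,
                              small_geom, seed=4)
        res = dominance_analysis(X, y)
        assert abs(res.contributions.sum() - res.r2_full) < 1e-10
        Z = np.column_stack([m.zscored().values for m in X])
        oracle = _shapley_oracle(Z, y.values)
        assert np.allclose(res.contributions, oracle, atol=1e-10)

    def test_orthogonal_predictors_marginal_r2(self, rng):
        # exactly orthogonal design columns: contributions = marginal R^2
        n, p = 64, 4
        # columns orthogonal to each other AND to the intercept, so
        # centering/z-scoring preserves orthogonality
        Q, _ = np.linalg.qr(
            np.column_stack([np.ones(n), rng.standard_normal((n, p + 1))])
        )
        cols = Q[:, 1 : p + 1]
        X = [RegionMap(cols[:, j], f"x{j}") for j in range(p)]
        yv = cols @ np.array([1.0, 0.5, 0.3, -0.2]) + 0.1 * Q[:, p + 1]
        y = RegionMap(yv, "y")
        res = dominance_analysis(X, y)
        Z = np.column_stack([m.zscored().values for m in X])
        for j in range(p):
            A = np.column_stack([np.ones(n), Z[:, j]])
            coef, *_ = np.linalg.lstsq(A, yv, rcond=None)
            marginal = 1 - ((yv - A @ coef) ** 2).sum() / ((yv - yv.mean()) ** 2).sum()
            assert res.contributions[j] == pytest.approx(marginal, abs=1e-8)

    def test_duplicated_predictors_equal_contributions(self, small_geom):
        x0 = gen_smooth_map(small_geom, 0.4, seed=0)
        noise = gen_smooth_map(small_geom, 0.4, seed=5)
        dup = RegionMap(x0.values + 1e-9 * noise.values, "dup")  # break exact collinearity
        X = [x0, dup, gen_smooth_map(small_geom, 0.4, seed=1)]
        y = gen_linear_target([x0, X[2]], [1.0, 0.5], 0.5, 0.4, small_geom, seed=2)
        res = dominance_analysis(X, y)
        assert abs(res.contributions[0] - res.contributions[1]) < 1e-6

    def test_predictor_limit(self, small_geom):
        X = _maps(small_geom, 21)
        y = gen_smooth_map(small_geom, 0.4, seed=30)
        with pytest.raises(ValueError, match="2\\^p"):
            dominance_analysis(X, y)


class TestDistanceCv:
    def test_noiseless_linear_test_r_one(self, small_geom):
        X = _maps(small_geom, 3)
        y = gen_linear_target(X, [1.0, 0.5, -0.2], 0.0, 0.4, small_geom, seed=5)
        res = distance_cv(X, y, small_geom, n_reps=20, seed=1)
        assert np.all(res.test_r > 1 - 1e-8)
        assert np.all(res.train_r > 1 - 1e-8)

    def test_smooth_noise_centered_near_zero(self, std_geom):
        # outcome with little long-range structure: test r centers near 0
        # (a long-range smooth outcome would extrapolate with negative bias)
        X = _maps(std_geom, 3)
        y = gen_smooth_map(std_geom, 0.1, seed=77)
        res = distance_cv(X, y, std_geom, n_reps=200, seed=2)
        assert abs(np.median(res.test_r)) < 0.1

    def test_train_test_distance_separation(self, small_geom, rng):
        from microcort.synthetic_cortex import great_circle_distance

        X = _maps(small_geom, 2)
        y = gen_smooth_map(small_geom, 0.4, seed=9)
        n = small_geom.n_parcels
        n_train = int(round(0.75 * n))
        res = distance_cv(X, y, small_geom, n_reps=10, seed=3)
        for s in res.seed_regions:
            d = great_circle_distance(
                small_geom.parcel_centroid, small_geom.parcel_centroid[int(s)]
            )
            order = np.argsort(d, kind="stable")
            assert d[order[:n_train]].max() <= d[order[n_train:]].min()

    def test_train_set_size_guard(self, small_geom):
        X = _maps(small_geom, 2)
        y = gen_smooth_map(small_geom, 0.4, seed=9)
        with pytest.raises(ValueError):
            distance_cv(X, y, small_geom, train_frac=0.05, n_reps=2, seed=0)


class TestPlsCorrelation:
    def test_identical_blocks_scores_correlate_at_one(self, small_geom, rng):
        X = rng.standard_normal((small_geom.n_parcels, 4))
        res = pls_correlation(X, X.copy())
        r = np.corrcoef(res.x_scores[:, 0], res.y_scores[:, 0])[0, 1]
        assert r == pytest.approx(1.0)

    def test_covariance_fractions_sum_to_one(self, small_geom, rng):
        X = rng.standard_normal((small_geom.n_parcels, 4))
        Y = rng.standard_normal((small_geom.n_parcels, 6))
        res = pls_correlation(X, Y)
        assert res.covariance_explained.sum() == pytest.approx(1.0, abs=1e-10)

    def test_planted_rank_one_recovery(self, std_geom):
        # the fit is on z-scored columns, so the planted weights must be
        # mapped into the z-scored space (w_j -> w_j / sd_j) for comparison
        blk = gen_two_block(std_geom, 5, 6, strength=3.0, noise=0.3, seed=4)
        res = pls_correlation(blk.X, blk.Y)

        def planted_z(block, w):
            wz = w / block.std(axis=0, ddof=0)
            return wz / np.linalg.norm(wz)

        assert abs(res.x_weights[:, 0] @ planted_z(blk.X, blk.x_weights)) > 0.95
        assert abs(res.y_weights[:, 0] @ planted_z(blk.Y, blk.y_weights)) > 0.95

    def test_planted_latent_significant(self, std_geom):
        blk = gen_two_block(std_geom, 5, 6, strength=3.0, noise=0.3, seed=4)
        null = spin_permutations(std_geom, 300, seed=5)
        res = pls_correlation(blk.X, blk.Y, null)
        assert res.p_spin_lv1 < 0.05

    def test_column_permutation_equivariance(self, small_geom, rng):
        X = rng.standard_normal((small_geom.n_parcels, 5))
        Y = rng.standard_normal((small_geom.n_parcels, 4))
        res = pls_correlation(X, Y)
        perm = rng.permutation(5)
        res_p = pls_correlation(X[:, perm], Y)
        assert np.allclose(
            np.abs(res_p.x_weights[:, 0]), np.abs(res.x_weights[perm, 0]), atol=1e-8
        )
        assert res_p.singular_values[0] == pytest.approx(res.singular_values[0])

    def test_zero_cross_covariance_errors(self, small_geom):
        X = np.zeros((small_geom.n_parcels, 3))
        with pytest.raises(ValueError):
            pls_correlation(X, X)


class TestMediation:
    def _indicator(self, geom):
        return RegionMap((np.arange(geom.n_parcels) < geom.n_parcels // 2).astype(float), "x")

    def test_full_mediation(self, std_geom, rng):
        x = self._indicator(std_geom)
        m = RegionMap(x.values + 0.3 * rng.standard_normal(std_geom.n_parcels), "m")
        y = RegionMap(2.0 * m.values, "y")
        res = mediation(x, m, y)
        assert abs(res.proportion_mediated_pct - 100.0) < 5.0

    def test_independent_mediator(self, std_geom, rng):
        x = self._indicator(std_geom)
        m = RegionMap(rng.standard_normal(std_geom.n_parcels), "m")
        y = RegionMap(x.values + 0.1 * rng.standard_normal(std_geom.n_parcels), "y")
        res = mediation(x, m, y)
        assert abs(res.proportion_mediated_pct) < 5.0

    def test_ols_identity(self, std_geom, rng):
        x = self._indicator(std_geom)
        m = RegionMap(rng.standard_normal(std_geom.n_parcels) + x.values, "m")
        y = RegionMap(rng.standard_normal(std_geom.n_parcels) + m.values, "y")
        res = mediation(x, m, y)
        assert abs(res.c - (res.c_prime + res.a * res.b)) < 1e-10

    def test_suppression_flagged(self, std_geom, rng):
        # direct and indirect paths of opposite sign
        x = self._indicator(std_geom)
        noise = rng.standard_normal(std_geom.n_parcels)
        m = RegionMap(2.0 * x.values + 0.2 * noise, "m")
        y = RegionMap(-1.5 * x.values + 1.0 * m.values
                      + 0.05 * rng.standard_normal(std_geom.n_parcels), "y")
        res = mediation(x, m, y)
        assert res.proportion_mediated_pct > 100.0 or res.proportion_mediated_pct < 0.0
        assert res.flag == "competitive mediation or suppression"

    def test_zero_total_effect_nan(self, std_geom):
        x = self._indicator(std_geom)
        m = RegionMap(np.ones(std_geom.n_parcels), "m")
        y = RegionMap(np.ones(std_geom.n_parcels), "y")
        res = mediation(x, m, y)
        assert np.isnan(res.proportion_mediated_pct)
        assert res.flag is not None
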
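import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from rrgamma import (
    DegenerateGroups,
    FeatureMatrix,
    FeatureName,
    InsufficientData,
    InsufficientGroups,
    exhaustive_subset_search,
    fit_ellipsoid,
    gamma_metric,
    pair_distance,
    univariate_gamma,
)
from rrgamma.gamma import GroupEllipsoid


def ray_surface_radius(S, u):
    """Oracle: root-find t > 0 with (t u)' S^-1 (t u) = 1 (ray hits surface)."""
    Sinv = np.linalg.inv(S)

    def f(t):
        p = t * u
        return float(p @ Sinv @ p) - 1.0

    hi = 10.0 * math.sqrt(float(np.max(np.linalg.eigvalsh(S))))
    return brentq(f, 1e-12, hi, xtol=1e-14)


def random_ellipsoid(rng, dim):
    A = rng.normal(size=(dim, dim))
    S = A @ A.T + 0.1 * np.eye(dim)
    return GroupEllipsoid(center=rng.normal(scale=3, size=dim), covariance=S, n=50)


class TestFitEllipsoid:
    def test_two_point_1d(self):
        e = fit_ellipsoid(np.array([[0.0], [2.0]]))
        assert e.center[0] == pytest.approx(1.0)
        assert e.covariance[0, 0] == pytest.approx(2.0)

    def test_recovers_known_gaussian(self):
        rng = np.random.default_rng(12)
        mu = np.array([1.0, -2.0])
        S = np.array([[2.0, 0.6], [0.6, 0.5]])
        X = rng.multivariate_normal(mu, S, size=10_000)
        e = fit_ellipsoid(X)
        # 3 standard errors: SE(mean) = sqrt(diag(S)/n)
        assert np.all(np.abs(e.center - mu) < 3 * np.sqrt(np.diag(S) / 10_000))
        assert np.allclose(e.covariance, S, atol=0.1)

    def test_constant_samples_get_strictly_pd_ridge(self):
        e = fit_ellipsoid(np.full((5, 2), 3.0))
        assert np.all(np.linalg.eigvalsh(e.covariance) > 0)

    def test_single_sample_raises(self):
        with pytest.raises(InsufficientData):
            fit_ellipsoid(np.array([[1.0, 2.0]]))


class TestPairDistance:
    def test_one_dimensional_groups_from_published_summaries(self):
        # NSR 0.00 +/- 0.01 vs AF 0.75 +/- 0.40 -> (0.75 - 0.41)/0.41
        e1 = GroupEllipsoid(center=[0.0], covariance=[[0.01**2]], n=100)
        e2 = GroupEllipsoid(center=[0.75], covariance=[[0.40**2]], n=100)
        d = pair_distance(e1, e2)
        assert d == pytest.approx((0.75 - 0.41) / 0.41, abs=1e-12)
        assert round(d, 2) == 0.83

    def test_identical_centers_give_minus_one(self):
        rng = np.random.default_rng(1)
        for dim in (1, 2, 4):
            e1 = random_ellipsoid(rng, dim)
            e2 = GroupEllipsoid(
                center=e1.center, covariance=random_ellipsoid(rng, dim).covariance, n=10
            )
            assert pair_distance(e1, e2) == -1.0

    def test_spherical_2d(self):
        e1 = GroupEllipsoid(center=[0.0, 0.0], covariance=np.eye(2), n=10)
        e2 = GroupEllipsoid(center=[4.0, 0.0], covariance=np.eye(2), n=10)
        assert pair_distance(e1, e2) == pytest.approx(1.0, abs=1e-14)

    def test_matches_ray_intersection_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            dim = int(rng.integers(2, 4))
            e1, e2 = random_ellipsoid(rng, dim), random_ellipsoid(rng, dim)
            gap = np.linalg.norm(e2.center - e1.center)
            u = (e2.center - e1.center) / gap
            r1 = ray_surface_radius(e1.covariance, u)
            r2 = ray_surface_radius(e2.covariance, u)
            expected = (gap - r1 - r2) / (r1 + r2)
            assert pair_distance(e1, e2) == pytest.approx(expected, abs=1e-8)

    def test_symmetry_exact(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            e1, e2 = random_ellipsoid(rng, 3), random_ellipsoid(rng, 3)
            assert pair_distance(e1, e2) == pair_distance(e2, e1)

    def test_degenerate_pair_raises(self):
        z = GroupEllipsoid(center=[1.0], covariance=[[0.0]], n=5)
        with pytest.raises(DegenerateGroups):
            pair_distance(z, z)

    def test_zero_radii_distinct_centers_is_infinite(self):
        e1 = GroupEllipsoid(center=[0.0], covariance=[[0.0]], n=5)
        e2 = GroupEllipsoid(center=[1.0], covariance=[[0.0]], n=5)
        assert pair_distance(e1, e2) == math.inf


class TestGammaMetric:
    def test_two_groups_equals_pair_distance(self):
        rng = np.random.default_rng(2)
        e1, e2 = random_ellipsoid(rng, 2), random_ellipsoid(rng, 2)
        res = gamma_metric([e1, e2])
        assert res.gamma == pair_distance(e1, e2)
        assert res.K == 2

    def test_three_identical_groups_sum_to_minus_three(self):
        e = GroupEllipsoid(center=[1.0, 2.0], covariance=np.eye(2), n=10)
        es = [GroupEllipsoid(center=e.center, covariance=e.covariance, n=10, group_id=g)
              for g in "abc"]
        res = gamma_metric(es)
        assert res.gamma == pytest.approx(-3.0)
        assert len(res.pair_distances) == 3

    def test_three_collinear_groups_equal_hand_sum(self):
        centers = [0.0, 5.0, 12.0]
        sds = [0.5, 1.0, 0.8]
        es = [
            GroupEllipsoid(center=[c], covariance=[[s**2]], n=10, group_id=str(i))
            for i, (c, s) in enumerate(zip(centers, sds))
        ]
        hand = sum(
            univariate_gamma(centers[i], sds[i], centers[j], sds[j])
            for i, j in itertools.combinations(range(3), 2)
        )
        assert gamma_metric(es).gamma == pytest.approx(hand, abs=1e-12)

    def test_single_group_raises(self):
        e = GroupEllipsoid(center=[0.0], covariance=[[1.0]], n=5)
        with pytest.raises(InsufficientGroups):
            gamma_metric([e])


class TestUnivariateGamma:
    def test_published_third_derivative_sd_row(self):
        assert round(univariate_gamma(0.14, 0.10, 2.58, 0.75), 2) == 1.87

    def test_rounding_sensitive_fifth_derivative_sd_row(self):
        # two-decimal printed inputs cannot pin this value better than ~0.01
        g = univariate_gamma(1.01, 1.19, 31.77, 15.13)
        assert g == pytest.approx(0.8848, abs=5e-4)

    def test_fully_overlapping_groups(self):
        assert univariate_gamma(5, 1, 5, 3) == -1.0

    def test_consistency_with_multivariate_1d(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            m1, m2 = rng.normal(size=2)
            s1, s2 = rng.uniform(0.1, 2.0, size=2)
            e1 = GroupEllipsoid(center=[m1], covariance=[[s1**2]], n=10)
            e2 = GroupEllipsoid(center=[m2], covariance=[[s2**2]], n=10)
            assert pair_distance(e1, e2) == pytest.approx(
                univariate_gamma(m1, s1, m2, s2), abs=1e-12
            )


class TestInvariants:
    def test_gamma_at_least_minus_one_for_two_groups(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            dim = int(rng.integers(1, 5))
            d = pair_distance(random_ellipsoid(rng, dim), random_ellipsoid(rng, dim))
            assert d >= -1.0

    def test_affine_invariance(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            X1 = rng.normal(size=(40, 3)) + rng.normal(scale=2, size=3)
            X2 = rng.normal(size=(40, 3)) @ np.diag([1, 2, 0.5]) + rng.normal(
                scale=2, size=3
            )
            d0 = pair_distance(fit_ellipsoid(X1), fit_ellipsoid(X2))
            A = rng.normal(size=(3, 3)) + 3 * np.eye(3)  # invertible w.h.p.
            b = rng.normal(size=3)
            d1 = pair_distance(fit_ellipsoid(X1 @ A.T + b), fit_ellipsoid(X2 @ A.T + b))
            assert d1 == pytest.approx(d0, rel=1e-8)

    def test_monotone_shrinkage(self):
        rng = np.random.default_rng(3)
        e1, e2 = random_ellipsoid(rng, 3), random_ellipsoid(rng, 3)
        base = pair_distance(e1, e2)
        for c in (1.5, 2.0, 5.0):
            scaled = pair_distance(
                GroupEllipsoid(e1.center, c * e1.covariance, e1.n),
                GroupEllipsoid(e2.center, c * e2.covariance, e2.n),
            )
            assert scaled < base
            base = scaled


def make_matrix(columns: dict, labels):
    """FeatureMatrix from raw columns keyed by FeatureName."""
    max_order = max(n.order for n in columns)
    from rrgamma import canonical_features

    names = canonical_features(max_order)
    data = {"record_id": [str(i) for i in range(len(labels))], "label": list(labels)}
    for name in names:
        col = columns.get(name)
        if col is None:
            col = np.zeros(len(labels))
        data[name.column] = np.asarray(col, dtype=float)
    return FeatureMatrix(
        data=pd.DataFrame(data, columns=["record_id", "label"] + [n.column for n in names]),
        max_order=max_order,
    )


class TestSubsetSearch:
    def test_single_informative_feature_wins(self):
        rng = np.random.default_rng(17)
        labels = ["a"] * 50 + ["b"] * 50
        signal = np.concatenate([rng.normal(0, 0.1, 50), rng.normal(5, 0.1, 50)])
        cols = {
            FeatureName("mean", 0): signal,
            FeatureName("mean", 1): rng.normal(size=100),
            FeatureName("sd", 0): rng.normal(size=100),
            FeatureName("sd", 1): rng.normal(size=100),
        }
        fm = make_matrix(cols, labels)
        rank = exhaustive_subset_search(fm, sizes=[1])
        assert rank.best_per_size[1][0] == (FeatureName("mean", 0),)

    def test_matches_brute_force_enumeration(self, small_features):
        # independent oracle: enumerate subsets via fit_ellipsoid + gamma_metric
        fm = FeatureMatrix(data=small_features.data.copy(), max_order=3)  # 8 features
        fm.data = fm.data[
            ["record_id", "label"]
            + [f.column for f in fm.feature_names]
        ]
        rank = exhaustive_subset_search(fm, sizes=range(1, 9))
        names = fm.feature_names
        for n in range(1, 9):
            best_g, best_sub = -math.inf, None
            for idx in itertools.combinations(range(len(names)), n):
                sub = [names[i] for i in idx]
                groups = [
                    fit_ellipsoid(fm.group(lab, sub), group_id=lab)
                    for lab in ("AF", "NSR")
                ]
                g = gamma_metric(groups).gamma
                if g > best_g:
                    best_g, best_sub = g, tuple(sub)
            sub, g = rank.best_per_size[n]
            assert sub == best_sub
            assert g == pytest.approx(best_g, rel=1e-6)

    def test_zero_variance_in_both_groups_is_excluded(self):
        rng = np.random.default_rng(30)
        labels = ["a"] * 20 + ["b"] * 20
        cols = {
            FeatureName("mean", 0): np.concatenate(
                [rng.normal(0, 1, 20), rng.normal(3, 1, 20)]
            ),
            FeatureName("mean", 1): np.zeros(40),  # constant in both groups
            FeatureName("sd", 0): rng.normal(size=40),
            FeatureName("sd", 1): rng.normal(size=40),
        }
        rank = exhaustive_subset_search(make_matrix(cols, labels), sizes=[1])
        assert FeatureName("mean", 1) in rank.excluded
        assert all(
            FeatureName("mean", 1) not in sub
            for sub, _ in rank.best_per_size.values()
        )

    def test_beam_mode_is_flagged_and_exact_mode_default(self, small_features):
        exact = exhaustive_subset_search(small_features, sizes=[1, 2])
        assert exact.mode == "exact"
        beam = exhaustive_subset_search(
            small_features, sizes=[1, 3], exact_limit=100, beam_width=16
        )
        assert beam.mode == "beam"
        assert len(beam.best_per_size[3][0]) == 3

    def test_ranking_json_round_trip(self, small_features):
        import json

        rank = exhaustive_subset_search(small_features, sizes=[1, 2])
        payload = json.loads(rank.to_json())
        assert payload["mode"] == "exact"
        assert payload["global_best"]["gamma"] == pytest.approx(
            rank.global_best[1]
        )
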
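"""Mantel machinery and the IBD regression."""

import math
from itertools import permutations

import numpy as np
import pytest
import statsmodels.api as sm

from seakernel.spatial_stats import (
    DistanceMatrix,
    ibd_regression,
    mantel,
    ols_fit,
    partial_mantel,
)


def sym_matrix(rng, n, scale=10.0):
    m = rng.random((n, n)) * scale
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m


def dm(values, kind="geographic_km"):
    n = len(values)
    return DistanceMatrix(labels=[f"s{i}" for i in range(n)], values=np.asarray(values), kind=kind)


def mantel_p_enumeration(a, b, tail="greater"):
    """Brute-force Mantel p over all n! relabelings (independent oracle)."""
    n = a.shape[0]
    tri = np.tril_indices(n, k=-1)
    bv = b[tri]

    def corr(x, y):
        return np.corrcoef(x, y)[0, 1]

    r_obs = corr(a[tri], bv)
    count = 0
    total = 0
    for perm in permutations(range(n)):
        p = np.asarray(perm)
        r = corr(a[np.ix_(p, p)][tri], bv)
        total += 1
        if tail == "greater" and r >= r_obs - 1e-12:
            count += 1
        elif tail == "less" and r <= r_obs + 1e-12:
            count += 1
    return count / total


class TestMantel:
    def test_affine_relation_gives_r_one(self):
        rng = np.random.default_rng(0)
        a = sym_matrix(rng, 5)
        res = mantel(dm(a), dm(2 * a + 3), n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_negated_matrix(self):
        rng = np.random.default_rng(1)
        a = sym_matrix(rng, 5)
        res = mantel(dm(a), dm(a.max() - a + 1.0), n_perm=999, seed=0)
        assert res.r == pytest.approx(-1.0)
        assert res.p_value > 0.9  # one-tailed greater

    @pytest.mark.parametrize("n,count", [(4, 23), (6, 719), (7, 5039)])
    def test_exhaustive_permutation_counts(self, n, count):
        rng = np.random.default_rng(2)
        res = mantel(dm(sym_matrix(rng, n)), dm(sym_matrix(rng, n)), n_perm=9999, seed=0)
        assert res.mode == "exhaustive"
        assert res.n_permutations == count

    @pytest.mark.parametrize("seed", range(4))
    def test_four_site_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a, b = sym_matrix(rng, 4), sym_matrix(rng, 4)
        res = mantel(dm(a), dm(b), n_perm=999, seed=0)
        assert res.mode == "exhaustive"
        assert res.p_value == pytest.approx(mantel_p_enumeration(a, b), abs=1e-12)

    def test_sampled_converges_to_exhaustive(self):
        rng = np.random.default_rng(3)
        a, b = sym_matrix(rng, 5), sym_matrix(rng, 5)
        exact = mantel(dm(a), dm(b), n_perm=999, seed=0)  # 5! - 1 = 119 <= 999
        assert exact.mode == "exhaustive"
        sampled = mantel(dm(a), dm(b), n_perm=100_000, seed=4, method="sampled")
        assert sampled.mode == "sampled"
        assert sampled.p_value == pytest.approx(exact.p_value, abs=0.01)

    def test_r_invariant_to_joint_relabeling(self):
        rng = np.random.default_rng(5)
        a, b = sym_matrix(rng, 6), sym_matrix(rng, 6)
        perm = rng.permutation(6)
        r1 = mantel(dm(a), dm(b), n_perm=23, seed=0).r
        r2 = mantel(
            dm(a[np.ix_(perm, perm)]), dm(b[np.ix_(perm, perm)]), n_perm=23, seed=0
        ).r
        assert r1 == pytest.approx(r2)

    def test_label_mismatch_rejected(self):
        rng = np.random.default_rng(6)
        a = dm(sym_matrix(rng, 4))
        b = DistanceMatrix(labels=list("wxyz"), values=sym_matrix(rng, 4))
        with pytest.raises(ValueError, match="mismatch"):
            mantel(a, b)

    def test_constant_matrix_rejected(self):
        rng = np.random.default_rng(7)
        a = sym_matrix(rng, 4)
        c = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError, match="constant"):
            mantel(dm(a), dm(c))


class TestPartialMantel:
    def test_identity_preserved_under_partialling(self):
        rng = np.random.default_rng(0)
        a = sym_matrix(rng, 6)
        c = sym_matrix(rng, 6)
        res = partial_mantel(dm(a), dm(a.copy()), dm(c), n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_matches_residual_correlation(self):
        rng = np.random.default_rng(1)
        c = sym_matrix(rng, 7)
        noise_a, noise_b = sym_matrix(rng, 7, 1.0), sym_matrix(rng, 7, 1.0)
        a, b = c + noise_a, c + noise_b
        tri = np.tril_indices(7, k=-1)

        def resid(y, x):
            fit = sm.OLS(y, sm.add_constant(x)).fit()
            return fit.resid

        oracle = np.corrcoef(resid(a[tri], c[tri]), resid(b[tri], c[tri]))[0, 1]
        res = partial_mantel(dm(a), dm(b), dm(c), n_perm=23, seed=0)
        assert res.r == pytest.approx(oracle, abs=1e-10)

    def test_four_site_p_matches_enumeration(self):
        rng = np.random.default_rng(2)
        a, b, c = (sym_matrix(rng, 4) for _ in range(3))
        tri = np.tril_indices(4, k=-1)

        def pr(x, y, z):
            rxy = np.corrcoef(x, y)[0, 1]
            rxz = np.corrcoef(x, z)[0, 1]
            ryz = np.corrcoef(y, z)[0, 1]
            return (rxy - rxz * ryz) / math.sqrt((1 - rxz**2) * (1 - ryz**2))

        r_obs = pr(a[tri], b[tri], c[tri])
        count = total = 0
        for perm in permutations(range(4)):
            p = np.asarray(perm)
            if pr(a[np.ix_(p, p)][tri], b[tri], c[tri]) >= r_obs - 1e-12:
                count += 1
            total += 1
        res = partial_mantel(dm(a), dm(b), dm(c), n_perm=999, seed=0)
        assert res.mode == "exhaustive"
        assert res.p_value == pytest.approx(count / total, abs=1e-12)

    def test_degenerate_control_rejected(self):
        rng = np.random.default_rng(3)
        a = sym_matrix(rng, 4)
        b = sym_matrix(rng, 4)
        with pytest.raises(ValueError, match="degenerate"):
            partial_mantel(dm(a), dm(b), dm(2 * a), n_perm=23, seed=0)


class TestIbdRegression:
    def test_exact_line(self):
        rng = np.random.default_rng(0)
        x = sym_matrix(rng, 5, 100.0)
        y = 1e-5 * x
        fit = ibd_regression(dm(x), dm(y, kind="linearized_fst"))
        assert fit.slope == pytest.approx(1e-5)
        assert fit.slope_se == pytest.approx(0.0, abs=1e-18)
        assert fit.r_squared == pytest.approx(1.0)

    def test_three_point_slope(self):
        fit = ols_fit(np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 2.0]))
        assert fit.slope == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_statsmodels(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random(15) * 100
        y = 2e-5 * x + rng.normal(0, 1e-4, 15)
        fit = ols_fit(x, y)
        sm_fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert fit.slope == pytest.approx(sm_fit.params[1], rel=1e-10)
        assert fit.slope_se == pytest.approx(sm_fit.bse[1], rel=1e-10)
        assert fit.intercept == pytest.approx(sm_fit.params[0], rel=1e-8)
        assert fit.r_squared == pytest.approx(sm_fit.rsquared, rel=1e-10)

    def test_slope_invariant_to_y_shift(self):
        rng = np.random.default_rng(4)
        x = rng.random(10)
        y = rng.random(10)
        assert ols_fit(x, y).slope == pytest.approx(ols_fit(x, y + 5.0).slope)

    def test_zero_x_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            ols_fit(np.ones(5), np.arange(5.0))
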
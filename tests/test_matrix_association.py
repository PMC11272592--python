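import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata, spearmanr

from ancestrylayers.datatypes import DataFormatError, DistanceMatrix
from ancestrylayers.matrix_association import (
    cadm_global,
    cadm_post,
    mantel_test,
    mmrr,
    p_adjust,
)
from conftest import random_distance_matrix


def exhaustive_mantel_p(d1, d2, method="spearman"):
    """Oracle: exact permutation p by enumerating all relabelings of d2."""
    n = d1.n
    iu = np.triu_indices(n, 1)

    def corr(a, b):
        if method == "spearman":
            a, b = rankdata(a), rankdata(b)
        return np.corrcoef(a, b)[0, 1]

    obs = corr(d1.values[iu], d2.values[iu])
    hits = 0
    perms = list(itertools.permutations(range(n)))
    for p in perms:
        p = np.asarray(p)
        r = corr(d1.values[iu], d2.values[np.ix_(p, p)][iu])
        hits += abs(r) >= abs(obs) - 1e-12
    return hits / len(perms), obs


class TestMantel:
    def test_perfect_correlation(self):
        rng = np.random.default_rng(0)
        d1 = random_distance_matrix(rng, 6)
        res = mantel_test(d1, d1, n_perm=99, seed=1)
        assert res.rho == pytest.approx(1.0)

    def test_exhaustive_enumeration_on_four_objects(self):
        rng = np.random.default_rng(1)
        d1 = random_distance_matrix(rng, 4)
        d2 = random_distance_matrix(rng, 4)
        exact_p, exact_rho = exhaustive_mantel_p(d1, d2)
        res = mantel_test(d1, d2, n_perm=4999, seed=2)
        assert res.rho == pytest.approx(exact_rho)
        # add-one Monte Carlo estimate converges to the enumerated p
        assert abs(res.p - exact_p) < 0.05

    def test_agrees_with_skbio_mantel_statistic(self):
        from skbio.stats.distance import DistanceMatrix as SkbioDM, mantel
        rng = np.random.default_rng(3)
        d1 = random_distance_matrix(rng, 8)
        d2 = random_distance_matrix(rng, 8)
        ours = mantel_test(d1, d2, n_perm=9, seed=0)
        theirs, _, _ = mantel(SkbioDM(d1.values, d1.labels),
                              SkbioDM(d2.values, d2.labels),
                              method="spearman", permutations=0)
        assert ours.rho == pytest.approx(float(theirs))

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(st.integers(0, 2 ** 30))
    def test_spearman_rho_invariant_to_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        d1 = random_distance_matrix(rng, 6)
        d2 = random_distance_matrix(rng, 6)
        base = mantel_test(d1, d2, n_perm=9, seed=0).rho
        warped = DistanceMatrix(np.exp(d2.values) - 1 + 3 * d2.values,
                                d2.labels)
        assert mantel_test(d1, warped, n_perm=9, seed=0).rho == pytest.approx(base)

    def test_constant_matrix_rejected(self):
        ones = np.ones((4, 4)) - np.eye(4)
        d1 = DistanceMatrix(ones, list("abcd"))
        d2 = random_distance_matrix(np.random.default_rng(0), 4, list("abcd"))
        with pytest.raises(DataFormatError, match="constant"):
            mantel_test(d1, d2, n_perm=9, seed=0)

    def test_seeded_runs_bit_reproducible(self):
        rng = np.random.default_rng(5)
        d1 = random_distance_matrix(rng, 7)
        d2 = random_distance_matrix(rng, 7)
        a = mantel_test(d1, d2, n_perm=199, seed=42)
        b = mantel_test(d1, d2, n_perm=199, seed=42)
        assert (a.rho, a.p) == (b.rho, b.p)

    def test_p_floor_is_add_one(self):
        rng = np.random.default_rng(6)
        d1 = random_distance_matrix(rng, 8)
        res = mantel_test(d1, d1, n_perm=99, seed=0)
        assert res.p >= 1 / 100


class TestMmrr:
    def test_exact_linear_relation(self):
        rng = np.random.default_rng(0)
        pred = random_distance_matrix(rng, 6)
        resp = DistanceMatrix(2.0 * pred.values, pred.labels)
        res = mmrr(resp, {"x": pred}, n_perm=99, seed=0)
        assert res.coefficients["x"] == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_single_predictor_agrees_with_pearson_mantel(self):
        rng = np.random.default_rng(1)
        resp = random_distance_matrix(rng, 7)
        pred = random_distance_matrix(rng, 7)
        m = mantel_test(resp, pred, n_perm=999, seed=3, method="pearson")
        r = mmrr(resp, {"x": pred}, n_perm=999, seed=4)
        assert abs(r.p_values["x"] - m.p) < 0.05  # same null within MC error

    def test_exhaustive_enumeration_on_four_objects(self):
        rng = np.random.default_rng(2)
        resp = random_distance_matrix(rng, 4)
        pred = random_distance_matrix(rng, 4)
        iu = np.triu_indices(4, 1)
        X = np.column_stack([np.ones(6), pred.values[iu]])

        def tstat(y):
            XtX_inv = np.linalg.pinv(X.T @ X)
            beta = XtX_inv @ X.T @ y
            resid = y - X @ beta
            sigma2 = resid @ resid / (len(y) - 2)
            return beta[1] / np.sqrt(XtX_inv[1, 1] * sigma2)

        obs = tstat(resp.values[iu])
        hits = 0
        perms = list(itertools.permutations(range(4)))
        for p in perms:
            p = np.asarray(p)
            hits += abs(tstat(resp.values[np.ix_(p, p)][iu])) >= abs(obs) - 1e-12
        exact = hits / len(perms)
        res = mmrr(resp, {"x": pred}, n_perm=4999, seed=5)
        assert abs(res.p_values["x"] - exact) < 0.05

    def test_collinear_predictors_named(self):
        rng = np.random.default_rng(3)
        a = random_distance_matrix(rng, 5)
        b = DistanceMatrix(3.0 * a.values, a.labels)
        resp = random_distance_matrix(rng, 5, a.labels)
        with pytest.raises(DataFormatError, match="'a'.*'b'|collinear"):
            mmrr(resp, {"a": a, "b": b}, n_perm=9, seed=0)


class TestCadm:
    def _fixture(self):
        rng = np.random.default_rng(42)
        n = 6
        mats = []
        for _ in range(3):
            a = rng.random((n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0)
            mats.append(a)
        mats[1] = 0.7 * mats[0] + 0.3 * mats[1]
        return [DistanceMatrix(m, list("ABCDEF")) for m in mats]

    def test_matches_ape_reference_values(self):
        # oracle values computed once with R ape::CADM.global / CADM.post on
        # the identical fixture (seeded numpy draws above)
        res = cadm_global(self._fixture(), n_perm=99, seed=0)
        assert res.W == pytest.approx(0.4865079, abs=1e-6)
        assert res.chi2 == pytest.approx(20.4333333, abs=1e-6)
        post = cadm_post(self._fixture(), n_perm=99, seed=0)
        means = list(post.post_mean_correlations.values())
        np.testing.assert_allclose(means, [0.4464286, 0.3678571, -0.125],
                                   atol=1e-6)

    def test_identical_matrices_fully_concordant(self):
        rng = np.random.default_rng(1)
        d = random_distance_matrix(rng, 6)
        res = cadm_global([d, d, d], n_perm=9, seed=0)
        assert res.W == pytest.approx(1.0)

    def test_two_matrix_identity_with_spearman(self):
        rng = np.random.default_rng(2)
        d1 = random_distance_matrix(rng, 7)
        d2 = random_distance_matrix(rng, 7)
        res = cadm_global([d1, d2], n_perm=9, seed=0)
        iu = np.triu_indices(7, 1)
        r = spearmanr(d1.values[iu], d2.values[iu]).statistic
        assert res.W == pytest.approx((r + 1) / 2)

    def test_duplicated_matrix_flagged_congruent(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            d = random_distance_matrix(rng, 9)
            others = [random_distance_matrix(rng, 9, d.labels) for _ in range(2)]
            dup = DistanceMatrix(d.values.copy(), d.labels)
            post = cadm_post([d, dup] + others, n_perm=199, seed=seed)
            ps = list(post.post_p_adjusted.values())
            hits += ps[0] < 0.05 and ps[1] < 0.05
        assert hits >= 19  # the duplicated pair should be detected essentially always

    def test_two_matrices_post_agrees_with_global(self):
        rng = np.random.default_rng(3)
        d1 = random_distance_matrix(rng, 6)
        d2 = random_distance_matrix(rng, 6)
        post = cadm_post([d1, d2], n_perm=999, seed=7)
        ms = list(post.post_mean_correlations.values())
        assert ms[0] == pytest.approx(ms[1])  # both equal their mutual correlation
        # with k = 2 the a posteriori and global hypotheses coincide
        for p in post.post_p.values():
            assert abs(p - post.p_global) < 0.1

    def test_fewer_than_two_matrices_rejected(self):
        d = random_distance_matrix(np.random.default_rng(0), 5)
        with pytest.raises(DataFormatError, match="at least two"):
            cadm_global([d], n_perm=9, seed=0)


class TestPAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(p_adjust([0.03], "bh"), [0.03])

    def test_bh_step_up_hand_application(self):
        np.testing.assert_allclose(p_adjust([0.01, 0.02, 0.03, 0.04], "bh"),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_holm_step_down_hand_application(self):
        np.testing.assert_allclose(p_adjust([0.01, 0.04], "holm"), [0.02, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(DataFormatError):
            p_adjust([0.5, 1.2], "bh")
        with pytest.raises(DataFormatError):
            p_adjust([0.5], "bonferroni-ish")
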
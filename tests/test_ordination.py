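import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from commdrivers.exceptions import (
    CollinearityError,
    DegreesOfFreedomError,
    EmptyCandidateError,
    InvalidParameterError,
    RankError,
    ZeroInformationError,
)
from commdrivers.ordination import (
    adjusted_r2,
    forward_select,
    partial_rda,
    plsr_fit,
    rda_fit,
    rda_permutation_test,
)


class TestRdaFit:
    def test_perfect_fit(self, rng):
        x = rng.standard_normal((25, 1))
        assert rda_fit(x, x).r2 == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_response(self, rng):
        # Y orthogonal to X by construction
        x = rng.standard_normal((30, 2))
        y = rng.standard_normal((30, 3))
        xc = x - x.mean(0)
        q, _ = np.linalg.qr(xc)
        y = (y - y.mean(0)) - q @ (q.T @ (y - y.mean(0)))
        assert rda_fit(y, x).r2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_per_response_regression_oracle(self, rng):
        Y = rng.standard_normal((30, 4))
        X = rng.standard_normal((30, 3))
        res = rda_fit(Y, X)
        # oracle: sum over responses of each column's regression SS / total SS
        Yc = Y - Y.mean(0)
        Xd = np.hstack([np.ones((30, 1)), X])
        ss_fit = 0.0
        for j in range(4):
            beta, *_ = np.linalg.lstsq(Xd, Yc[:, j], rcond=None)
            fit = Xd @ beta
            ss_fit += np.sum((fit - fit.mean()) ** 2)
        oracle = ss_fit / np.sum(Yc * Yc)
        assert res.r2 == pytest.approx(oracle, abs=1e-10)

    def test_collinear_column_named(self, rng):
        X = rng.standard_normal((20, 2))
        X = np.hstack([X, X[:, [0]]])
        with pytest.raises(CollinearityError, match="dup"):
            rda_fit(rng.standard_normal((20, 2)), X, names=["a", "b", "dup"])
        Xc = np.hstack([X[:, :2], np.full((20, 1), 3.0)])
        with pytest.raises(CollinearityError, match="const"):
            rda_fit(rng.standard_normal((20, 2)), Xc, names=["a", "b", "const"])

    def test_invariant_to_linear_recoding(self, rng):
        Y = rng.standard_normal((25, 3))
        X = rng.standard_normal((25, 4))
        A = rng.standard_normal((4, 4)) + 4 * np.eye(4)  # invertible
        r1 = rda_fit(Y, X)
        r2 = rda_fit(Y, X @ A)
        assert r1.r2 == pytest.approx(r2.r2, abs=1e-10)

    def test_eigenvalues_nonincreasing(self, rng):
        res = rda_fit(rng.standard_normal((30, 5)), rng.standard_normal((30, 4)))
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)


class TestAdjustedR2:
    @pytest.mark.parametrize(
        "r2,n,m,expected",
        [
            (0.5, 68, 16, 1 - 0.5 * 67 / 51),
            (1.0, 30, 5, 1.0),
            (0.0, 20, 5, 1 - 19 / 14),
        ],
    )
    def test_formula(self, r2, n, m, expected):
        assert adjusted_r2(r2, n, m) == pytest.approx(expected, abs=1e-12)

    def test_penalizes_below_r2(self, rng):
        for _ in range(20):
            r2 = rng.uniform(0, 0.99)
            n, m = int(rng.integers(10, 100)), int(rng.integers(1, 5))
            assert adjusted_r2(r2, n, m) < r2

    def test_df_exhausted(self):
        with pytest.raises(DegreesOfFreedomError):
            adjusted_r2(0.5, 10, 9)


class TestPermutationTest:
    def test_strong_signal_gives_minimal_p(self, rng):
        X = rng.standard_normal((40, 2))
        Y = X @ rng.standard_normal((2, 3)) + 0.01 * rng.standard_normal((40, 3))
        res = rda_permutation_test(Y, X, n_perm=999, seed=1)
        assert res.perm_p <= 0.005

    def test_p_in_valid_range(self, rng):
        res = rda_permutation_test(
            rng.standard_normal((20, 2)), rng.standard_normal((20, 2)),
            n_perm=99, seed=2)
        assert 1 / 100 <= res.perm_p <= 1.0

    def test_zero_permutations_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            rda_permutation_test(rng.standard_normal((10, 1)),
                                 rng.standard_normal((10, 1)), n_perm=0)

    def test_type_i_error_calibrated(self):
        # independent noise: rejection rate at alpha=0.05 should be ~5%
        rng = np.random.default_rng(11)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            Y = rng.standard_normal((20, 2))
            X = rng.standard_normal((20, 2))
            if rda_permutation_test(Y, X, n_perm=99, seed=rng).perm_p <= 0.05:
                hits += 1
        assert hits / n_sim == pytest.approx(0.05, abs=0.02)


class TestPartialRda:
    def test_empty_conditioning_equals_rda(self, rng):
        Y = rng.standard_normal((25, 3))
        X = rng.standard_normal((25, 2))
        assert partial_rda(Y, X, None).r2 == pytest.approx(rda_fit(Y, X).r2)

    def test_x_inside_span_z_raises(self, rng):
        Z = rng.standard_normal((25, 3))
        X = Z[:, :2] @ rng.standard_normal((2, 2))
        with pytest.raises(ZeroInformationError):
            partial_rda(rng.standard_normal((25, 2)), X, Z)

    def test_matches_residualization_oracle(self, rng):
        Y = rng.standard_normal((30, 4))
        X = rng.standard_normal((30, 3))
        Z = rng.standard_normal((30, 2))
        res = partial_rda(Y, X, Z)
        # oracle: explicit residualization then RDA, rescaled to total Y SS
        def resid(A, B):
            Bc = np.hstack([np.ones((len(B), 1)), B])
            beta, *_ = np.linalg.lstsq(Bc, A, rcond=None)
            return A - Bc @ beta
        Yc = Y - Y.mean(0)
        Yr = resid(Yc, Z)
        Xr = resid(X - X.mean(0), Z)
        sub = rda_fit(Yr, Xr)
        oracle = sub.r2 * np.sum((Yr - Yr.mean(0)) ** 2) / np.sum(Yc * Yc)
        assert res.r2 == pytest.approx(oracle, abs=1e-10)


class TestForwardSelect:
    def test_true_driver_selected_first(self):
        # x3 is the dominant driver; the other candidates carry weak signal
        # so the global-model ceiling is informative rather than binding
        rng = np.random.default_rng(3)
        wins = 0
        for _ in range(20):
            X = rng.standard_normal((40, 10))
            coefs = np.full((10, 2), 0.3)
            coefs[3] = 2.0
            Y = X @ coefs + 0.5 * rng.standard_normal((40, 2))
            res = forward_select(Y, X, alpha=0.05, n_perm=199, seed=rng)
            wins += bool(res.selected and res.selected[0] == "x3")
        assert wins == 20

    def test_noise_stops_globally(self):
        rng = np.random.default_rng(4)
        stops = 0
        n_sim = 20
        for _ in range(n_sim):
            Y = rng.standard_normal((30, 2))
            X = rng.standard_normal((30, 5))
            res = forward_select(Y, X, alpha=1e-6, n_perm=199, seed=rng)
            stops += res.stop_reason == "global_ns" and not res.selected
        assert stops >= 0.95 * n_sim

    def test_duplicate_column_never_selected_twice(self, rng):
        X = rng.standard_normal((40, 3))
        X = np.hstack([X, X[:, [0]]])  # x3 duplicates x0
        Y = X[:, [0]] + 0.1 * rng.standard_normal((40, 1))
        res = forward_select(Y, X, alpha=0.05, n_perm=199, seed=5)
        assert not {"x0", "x3"} <= set(res.selected)

    def test_ceiling_never_exceeded(self, rng):
        for _ in range(5):
            X = rng.standard_normal((35, 6))
            Y = X[:, :2] @ rng.standard_normal((2, 3)) + rng.standard_normal((35, 3))
            res = forward_select(Y, X, alpha=0.1, n_perm=99, seed=rng)
            for cum in res.cumulative_r2_adj:
                assert cum <= res.global_r2_adj + 1e-12

    def test_empty_candidates_rejected(self, rng):
        with pytest.raises(EmptyCandidateError):
            forward_select(rng.standard_normal((10, 1)), np.empty((10, 0)))


class TestPlsr:
    def test_single_driver_fully_explained(self, rng):
        x1 = rng.standard_normal(30)
        x2 = rng.standard_normal(30)
        x1 -= x1.mean()
        x2 -= x2.mean()
        x2 -= x2 @ x1 / (x1 @ x1) * x1  # orthogonalize (centered)
        X = np.column_stack([x1, x2])
        res = plsr_fit(x1[:, None], X, h=1)
        assert res.explained[0] == pytest.approx(100.0, abs=1e-8)
        corr = np.corrcoef(res.scores[:, 0], x1 - x1.mean())[0, 1]
        assert abs(corr) == pytest.approx(1.0, abs=1e-10)

    def test_cumulative_nondecreasing_and_orthogonal_scores(self, rng):
        Y = rng.standard_normal((20, 3))
        X = rng.standard_normal((20, 5))
        res = plsr_fit(Y, X, h=4)
        assert np.all(np.diff(res.cumulative) >= -1e-12)
        gram = res.scores.T @ res.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    @staticmethod
    def _nipals_oracle(Y, X, h, tol=1e-13, max_iter=5000):
        # textbook iterative NIPALS for PLS2, independent of the SVD route
        X = X - X.mean(0)
        Y = Y - Y.mean(0)
        scores = []
        for _ in range(h):
            u = Y[:, [int(np.argmax(Y.var(0)))]].copy()
            w = np.zeros((X.shape[1], 1))
            for _ in range(max_iter):
                w_new = X.T @ u
                w_new /= np.linalg.norm(w_new)
                t = X @ w_new
                c = Y.T @ t / float((t * t).sum())
                u_new = Y @ c / float((c * c).sum())
                if np.linalg.norm(w_new - w) < tol:
                    w = w_new
                    break
                w, u = w_new, u_new
            t = X @ w
            p = X.T @ t / float((t * t).sum())
            X = X - t @ p.T
            scores.append(t[:, 0])
        return np.column_stack(scores)

    def test_matches_nipals_oracle(self, rng):
        Y = rng.standard_normal((20, 3))
        X = rng.standard_normal((20, 5))
        res = plsr_fit(Y, X, h=3, scale_x=False)
        ref = self._nipals_oracle(Y.copy(), X.copy(), 3)
        for a in range(3):
            ours = res.scores[:, a]
            theirs = ref[:, a]
            sign = np.sign(ours @ theirs)
            np.testing.assert_allclose(ours, sign * theirs, atol=1e-8)
        # second, coarser route: sklearn's implementation agrees too
        skl = PLSRegression(n_components=3, scale=False).fit(X, Y)
        for a in range(3):
            ours = res.scores[:, a]
            theirs = skl.x_scores_[:, a]
            sign = np.sign(ours @ theirs)
            np.testing.assert_allclose(ours, sign * theirs, atol=1e-2)

    def test_rank_exceeded(self, rng):
        X = rng.standard_normal((10, 3))
        X = np.hstack([X, X])  # rank 3
        with pytest.raises(RankError):
            plsr_fit(rng.standard_normal((10, 2)), X, h=4)
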
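"""O2PLS decomposition: scaling, oracle agreement, invariants, permutation."""

import numpy as np
import pytest
from scipy import linalg

from huangjiu_core import ConfigurationError, DataError
from huangjiu_core.o2pls import ScalingSpec, fit, normalize, permutation_test


def svd_oracle(X: np.ndarray, Y: np.ndarray, n: int):
    """Singular vectors of X'Y via eigendecomposition — an independent route."""
    M = X.T @ Y
    _, Vx = linalg.eigh(M @ M.T)
    _, Vy = linalg.eigh(M.T @ M)
    W = Vx[:, ::-1][:, :n]
    C = Vy[:, ::-1][:, :n]
    return W, C


def align_signs(A: np.ndarray, ref: np.ndarray) -> np.ndarray:
    out = A.copy()
    for k in range(A.shape[1]):
        if A[:, k] @ ref[:, k] < 0:
            out[:, k] = -out[:, k]
    return out


class TestNormalize:
    def test_centering_zeroes_column_sums(self, rng):
        A = normalize(rng.normal(2.0, 1.0, size=(10, 4)), ScalingSpec())
        assert np.allclose(A.sum(axis=0), 0.0, atol=1e-10)

    def test_zscore_mode_unit_column_sd(self, rng):
        spec = ScalingSpec(center=True, unit_variance_y=False,
                           equal_total_ssq=False, zscore_columns=True)
        A = normalize(rng.normal(size=(12, 5)), spec)
        assert np.allclose(A.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_equal_total_ssq_unit_frobenius(self, rng):
        A = normalize(rng.normal(size=(8, 6)), ScalingSpec())
        assert np.linalg.norm(A) == pytest.approx(1.0, abs=1e-12)

    def test_y_block_unit_variance_before_ssq(self, rng):
        spec = ScalingSpec(equal_total_ssq=False)
        A = normalize(rng.normal(size=(9, 3)), spec, block="y")
        assert np.allclose(A.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_zero_variance_column_named(self, rng):
        M = rng.normal(size=(6, 3))
        M[:, 1] = 7.0
        with pytest.raises(DataError, match="zero-variance"):
            normalize(M, ScalingSpec(), block="y")

    def test_conflicting_modes_rejected(self):
        with pytest.raises(ConfigurationError):
            ScalingSpec(zscore_columns=True)


class TestFit:
    def test_self_integration(self, rng):
        X = normalize(rng.normal(size=(8, 5)), ScalingSpec())
        m = fit(X, X, n=1)
        W = align_signs(m.W, m.C)
        assert np.allclose(W, m.C, atol=1e-10)
        assert np.allclose(np.abs(m.T), np.abs(m.U), atol=1e-10)
        assert float(np.abs(m.B[0, 0])) == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_joint_loadings_match_svd_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = normalize(rng.normal(size=(6, 8)), ScalingSpec())
        Y = normalize(rng.normal(size=(6, 5)), ScalingSpec(), block="y")
        m = fit(X, Y, n=2)
        W_ref, C_ref = svd_oracle(np.asarray(X), np.asarray(Y), 2)
        assert np.allclose(align_signs(W_ref, m.W), m.W, atol=1e-8)
        assert np.allclose(align_signs(C_ref, m.C), m.C, atol=1e-8)

    def test_planted_rank_one_pair(self, rng):
        t = rng.normal(size=50)
        X = np.outer(t, rng.normal(size=12)) + 0.01 * rng.normal(size=(50, 12))
        Y = np.outer(t, rng.normal(size=6)) + 0.01 * rng.normal(size=(50, 6))
        m = fit(normalize(X, ScalingSpec()),
                normalize(Y, ScalingSpec(), block="y"), n=1)
        corr = np.corrcoef(m.T[:, 0], m.U[:, 0])[0, 1]
        assert abs(corr) > 0.99

    @pytest.mark.parametrize("seed", range(10))
    def test_orthogonality_and_norm_conservation(self, seed):
        rng = np.random.default_rng(100 + seed)
        X = normalize(rng.normal(size=(12, 9)), ScalingSpec())
        Y = normalize(rng.normal(size=(12, 7)), ScalingSpec(), block="y")
        m = fit(X, Y, n=2, nx=2, ny=1)
        assert np.abs(m.T.T @ m.T_orth).max() < 1e-8
        assert np.abs(m.U.T @ m.U_orth).max() < 1e-8
        for block, joint, t_o, p_o in ((np.asarray(X), m.T @ m.W.T, m.T_orth,
                                        m.P_orth_x),
                                       (np.asarray(Y), m.U @ m.C.T, m.U_orth,
                                        m.P_orth_y)):
            resid = block - joint - t_o @ p_o.T
            total = (block**2).sum()
            parts = (joint**2).sum() + (t_o @ p_o.T).__pow__(2).sum() \
                + (resid**2).sum()
            assert parts == pytest.approx(total, rel=1e-6)
        for side in ("x", "y"):
            fr = m.variance_explained[side]
            assert fr["joint"] + fr["orthogonal"] + fr["residual"] == \
                pytest.approx(1.0, rel=1e-9)

    def test_unit_norm_loadings(self, rng):
        X = normalize(rng.normal(size=(10, 6)), ScalingSpec())
        Y = normalize(rng.normal(size=(10, 4)), ScalingSpec(), block="y")
        m = fit(X, Y, n=2, nx=1, ny=1)
        assert np.allclose(np.linalg.norm(m.W, axis=0), 1.0, atol=1e-10)
        assert np.allclose(np.linalg.norm(m.C, axis=0), 1.0, atol=1e-10)

    def test_single_ha_loading_proportional_to_cross_covariance(self, rng):
        X = normalize(rng.normal(size=(9, 7)), ScalingSpec())
        y = normalize(rng.normal(size=(9, 1)), ScalingSpec(), block="y")
        m = fit(X, y, n=1)
        direction = np.asarray(X).T @ np.asarray(y)[:, 0]
        direction /= np.linalg.norm(direction)
        assert np.allclose(align_signs(direction[:, None], m.W), m.W, atol=1e-10)

    def test_dimension_errors(self, rng):
        X = rng.normal(size=(6, 8))
        Y = rng.normal(size=(6, 5))
        with pytest.raises(ConfigurationError):
            fit(X, Y, n=0)
        with pytest.raises(ConfigurationError):
            fit(X, Y, n=5, nx=2)
        with pytest.raises(Exception):
            fit(X, Y[:5], n=1)


class TestPermutationTest:
    def _noise_pair(self, seed):
        rng = np.random.default_rng(seed)
        X = normalize(rng.normal(size=(18, 20)), ScalingSpec())
        Y = normalize(rng.normal(size=(18, 6)), ScalingSpec(), block="y")
        return X, Y

    def test_deterministic_given_seed(self):
        X, Y = self._noise_pair(3)
        a = permutation_test(X, Y, n=1, n_perm=150, seed=11)
        b = permutation_test(X, Y, n=1, n_perm=150, seed=11)
        assert a.significant_x == b.significant_x
        assert a.significant_y == b.significant_y
        assert a.lower_q == b.lower_q

    def test_planted_producers_have_high_power(self):
        """At strong planted signal nearly every producer is flagged.

        The dominant taxon's compositional variance can occasionally
        displace the weakest producer from the joint subspace, so power
        is asserted in aggregate over seeds rather than per seed.
        """
        from huangjiu_core import SimConfig, generate_community, generate_ha
        from huangjiu_core.assoc import AssocConfig, ha_sample_matrix
        from huangjiu_core.community import to_relative
        from huangjiu_core.ha_quant import summarize_replicates

        flagged = total = 0
        for seed in range(10):
            sim = SimConfig(n_taxa=30, n_producers=3, n_has=8,
                            effect_size=2.0, noise_sd=0.1, seed=seed)
            abundance, truth = generate_community(sim)
            ha = generate_ha(abundance, truth, sim)
            rel = to_relative(abundance)
            matrix = ha_sample_matrix(summarize_replicates(ha), AssocConfig())
            X = normalize(rel.data.T, ScalingSpec())
            Y = normalize(matrix.T, ScalingSpec(), block="y")
            res = permutation_test(X, Y, n=5, nx=1, ny=1, n_perm=500, seed=0)
            flagged += len(set(truth.producer_ids) & res.significant_x)
            total += len(truth.producer_ids)
        assert flagged / total >= 0.9

    def test_small_n_perm_warns(self):
        X, Y = self._noise_pair(4)
        with pytest.warns(UserWarning, match="n_perm"):
            permutation_test(X, Y, n=1, n_perm=50, seed=0)

    def test_invalid_alpha_rejected(self):
        X, Y = self._noise_pair(5)
        with pytest.raises(ConfigurationError):
            permutation_test(X, Y, n=1, alpha=1.5, seed=0)

    def test_sign_flip_of_y_leaves_selection_unchanged(self):
        """Negating Y flips loadings but not the selected variable sets."""
        X, Y = self._noise_pair(6)
        a = permutation_test(X, Y, n=1, n_perm=200, seed=2)
        b = permutation_test(X, -np.asarray(Y), n=1, n_perm=200, seed=2)
        assert a.significant_x == b.significant_x
        assert a.significant_y == b.significant_y
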
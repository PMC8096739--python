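"""Noise covariance estimation, prewhitening, crossnobis distances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from imagery_rsa import (EffectSpec, NoiseSpec, PatternSet, crossnobis_rdm,
                         estimate_noise_cov, make_geometry, pool_noise_cov,
                         prewhiten, prewhiten_by_run, simulate_run_patterns)
from imagery_rsa.crossnobis import NoiseCovariance, inverse_sqrt
from conftest import make_conditions


def naive_crossnobis(patterns):
    """Independent double-loop oracle for the cross-validated distance:
    sum over ordered run pairs (l, m), l != m, of
    (u_i^m - u_j^m) . (u_i^l - u_j^l), divided by M(M-1)."""
    m, c, _ = patterns.shape
    d = np.zeros((c, c))
    for i in range(c):
        for j in range(c):
            if i == j:
                continue
            acc = 0.0
            for run_m in range(m):
                for run_l in range(m):
                    if run_l == run_m:
                        continue
                    acc += (patterns[run_m, i] - patterns[run_m, j]) @ \
                           (patterns[run_l, i] - patterns[run_l, j])
            d[i, j] = acc / (m * (m - 1))
    return d


def _pattern_set(arr):
    arr = np.asarray(arr, dtype=float)
    return PatternSet(patterns=arr,
                      condition_names=[f"c{i}" for i in range(arr.shape[1])])


class TestNoiseCovariance:
    def test_full_shrinkage_is_diagonal(self, rng):
        resid = rng.standard_normal((50, 6)) @ rng.standard_normal((6, 6))
        nc = estimate_noise_cov(resid, shrinkage=1.0)
        assert np.allclose(nc.cov, np.diag(np.diag(nc.cov)))
        centered = resid - resid.mean(0)
        assert np.allclose(np.diag(nc.cov),
                           (centered ** 2).sum(0) / (len(resid) - 1))

    def test_white_noise_off_diagonals_vanish_large_t(self, rng):
        resid = rng.standard_normal((20000, 5))
        nc = estimate_noise_cov(resid, shrinkage=0.0)
        off = nc.cov[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_auto_shrinkage_pd_when_voxels_exceed_timepoints(self, rng):
        resid = rng.standard_normal((10, 40))
        nc = estimate_noise_cov(resid, shrinkage="auto")
        assert np.linalg.eigvalsh(nc.cov).min() > 0

    def test_auto_shrinkage_regimes(self, rng):
        """With genuinely correlated noise, plenty of data drives the auto
        weight toward zero while short series shrink hard; on white noise
        the diagonal target is the truth, so the weight approaches one —
        the same regime sklearn's Ledoit-Wolf shows there (its identity
        target coincides with the diagonal for white noise)."""
        from sklearn.covariance import LedoitWolf
        chol = np.linalg.cholesky(0.5 * np.ones((4, 4)) + 0.5 * np.eye(4))
        corr_big = rng.standard_normal((5000, 4)) @ chol.T
        corr_small = rng.standard_normal((12, 4)) @ chol.T
        lam_big = estimate_noise_cov(corr_big).shrinkage
        assert lam_big < 0.05
        assert estimate_noise_cov(corr_small).shrinkage > lam_big
        white = rng.standard_normal((5000, 4))
        lam_white = estimate_noise_cov(white).shrinkage
        lw = LedoitWolf().fit(white).shrinkage_
        assert lam_white > 0.5 and lw > 0.5

    def test_errors(self, rng):
        with pytest.raises(ValueError):
            estimate_noise_cov(rng.standard_normal((1, 3)))
        with pytest.raises(ValueError):
            estimate_noise_cov(rng.standard_normal((10, 3)), shrinkage=1.5)
        degenerate = np.zeros((10, 3))
        with pytest.raises(ValueError):
            estimate_noise_cov(degenerate, shrinkage=0.0)

    def test_pooling_weights_by_dof(self, rng):
        a = NoiseCovariance(cov=np.eye(2), shrinkage=0.0, dof=10)
        b = NoiseCovariance(cov=3 * np.eye(2), shrinkage=0.0, dof=30)
        pooled = pool_noise_cov([a, b])
        assert pooled.dof == 40
        assert np.allclose(pooled.cov, 2.5 * np.eye(2))


class TestPrewhiten:
    def test_identity_covariance_is_noop(self, rng):
        pats = rng.standard_normal((3, 4, 6))
        nc = NoiseCovariance(cov=np.eye(6), shrinkage=0.0, dof=100)
        out = prewhiten(_pattern_set(pats), nc)
        assert np.allclose(out.patterns, pats)

    def test_whitened_euclidean_equals_mahalanobis(self, rng):
        """|W a - W b|^2 == (a-b)' Sigma^-1 (a-b) against an explicit
        inverse."""
        a = rng.standard_normal((8, 8))
        sigma = a @ a.T + 8 * np.eye(8)
        w = inverse_sqrt(sigma)
        x, y = rng.standard_normal(8), rng.standard_normal(8)
        lhs = np.sum((w @ x - w @ y) ** 2)
        rhs = (x - y) @ np.linalg.inv(sigma) @ (x - y)
        assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_self_whitened_residual_covariance_is_identity(self, rng):
        resid = rng.standard_normal((500, 6)) @ (rng.standard_normal((6, 6))
                                                 + 3 * np.eye(6))
        nc = estimate_noise_cov(resid, shrinkage=0.0)
        white = prewhiten(resid - resid.mean(0), nc)
        cov = white.T @ white / (len(resid) - 1)
        assert np.abs(cov - np.eye(6)).max() < 1e-10

    def test_non_pd_rejected(self):
        nc = NoiseCovariance(cov=np.diag([1.0, 0.0]), shrinkage=0.0, dof=10)
        with pytest.raises(np.linalg.LinAlgError):
            prewhiten(np.zeros((2, 2)), nc)

    def test_bias_correction_requires_dof(self):
        nc = NoiseCovariance(cov=np.eye(4), shrinkage=0.0, dof=5)
        with pytest.raises(ValueError):
            prewhiten(np.zeros((2, 4)), nc, bias_correction=True)


class TestCrossnobis:
    def test_hand_example_positive(self):
        ps = _pattern_set([[[1.0, 0.0], [0.0, 0.0]],
                           [[1.0, 0.0], [0.0, 0.0]]])
        assert crossnobis_rdm(ps).matrix[0, 1] == pytest.approx(1.0)

    def test_hand_example_negative(self):
        """Sign-flipping pattern differences across runs yield a negative
        cross-validated distance."""
        ps = _pattern_set([[[1.0, 0.0], [0.0, 0.0]],
                           [[0.0, 0.0], [1.0, 0.0]]])
        assert crossnobis_rdm(ps).matrix[0, 1] == pytest.approx(-1.0)

    def test_diagonal_exactly_zero(self, rng):
        ps = _pattern_set(rng.standard_normal((4, 5, 7)))
        assert (np.diag(crossnobis_rdm(ps).matrix) == 0.0).all()

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(m=st.integers(2, 4), c=st.integers(2, 5), v=st.integers(2, 6),
           seed=st.integers(0, 10_000))
    def test_matches_naive_oracle(self, m, c, v, seed):
        pats = np.random.default_rng(seed).standard_normal((m, c, v))
        got = crossnobis_rdm(_pattern_set(pats)).matrix
        assert np.abs(got - naive_crossnobis(pats)).max() < 1e-10

    def test_symmetry_exact(self, rng):
        got = crossnobis_rdm(_pattern_set(rng.standard_normal((3, 6, 4)))).matrix
        assert (got == got.T).all()

    def test_unordered_pair_fold_identity(self, rng):
        """Summing unordered run pairs and doubling equals the ordered-pair
        sum."""
        pats = rng.standard_normal((4, 3, 5))
        m = 4
        acc = np.zeros((3, 3))
        for l in range(m):
            for k in range(l + 1, m):
                dl = pats[l][:, None, :] - pats[l][None, :, :]
                dk = pats[k][:, None, :] - pats[k][None, :, :]
                acc += 2.0 * np.einsum("ijv,ijv->ij", dl, dk)
        expected = acc / (m * (m - 1))
        got = crossnobis_rdm(_pattern_set(pats)).matrix
        assert np.allclose(got, expected, atol=1e-12)

    def test_single_run_rejected(self, rng):
        with pytest.raises(ValueError):
            crossnobis_rdm(_pattern_set(rng.standard_normal((1, 2, 3))))

    def test_voxel_normalization_flag(self, rng):
        pats = rng.standard_normal((3, 4, 10))
        a = crossnobis_rdm(_pattern_set(pats)).matrix
        b = crossnobis_rdm(_pattern_set(pats), normalize_voxels=True).matrix
        assert np.allclose(b, a / 10)

    def test_null_mean_within_monte_carlo_error(self):
        """Meaningful zero point: identical true patterns give mean
        distance ~ 0."""
        conds = make_conditions(2)
        geo = make_geometry(conds, EffectSpec(), 40, seed=0)
        vals = []
        for seed in range(400):
            ps = simulate_run_patterns(geo, 4, NoiseSpec(sigma=1.0),
                                       seed=seed)
            vals.append(crossnobis_rdm(ps).matrix[0, 1])
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se

    def test_consistency_with_true_covariance_whitening(self, rng):
        """With whitening by the true noise covariance the mean estimate
        approaches delta' Sigma^-1 delta."""
        conds = make_conditions(2)
        spec = NoiseSpec(sigma=1.0, spatial_correlation=0.4)
        geo = make_geometry(conds, EffectSpec(item_separation=2.0), 15,
                            seed=3)
        cov = spec.covariance(15)
        delta = geo.true_patterns[0] - geo.true_patterns[1]
        target = delta @ np.linalg.solve(cov, delta)
        nc = NoiseCovariance(cov=cov, shrinkage=0.0, dof=10**6)
        vals = []
        for seed in range(400):
            ps = simulate_run_patterns(geo, 4, spec, seed=1000 + seed)
            vals.append(crossnobis_rdm(prewhiten(ps, nc)).matrix[0, 1])
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert vals.mean() == pytest.approx(target, abs=3 * se)

    def test_per_run_and_pooled_modes(self, rng):
        from imagery_rsa import crossnobis_from_runs
        pats = rng.standard_normal((3, 4, 5))
        resids = [rng.standard_normal((60, 5)) for _ in range(3)]
        ps = _pattern_set(pats)
        rdm_pool = crossnobis_from_runs(ps, resids, noise_mode="pooled")
        rdm_run = crossnobis_from_runs(ps, resids, noise_mode="per_run")
        for rdm in (rdm_pool, rdm_run):
            assert (np.diag(rdm.matrix) == 0.0).all()
            assert np.allclose(rdm.matrix, rdm.matrix.T)
        with pytest.raises(ValueError):
            crossnobis_from_runs(ps, resids, noise_mode="bogus")
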
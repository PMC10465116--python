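"""Closed-form mean/covariance estimation, eigenvalue shrinkage, and
eigenimages."""

import numpy as np
import pytest

import fbcwf as F
from fbcwf.basis import BasisSpec, CoefficientSet
from fbcwf.covariance import (AssumptionA3Error, estimate_covariance,
                              estimate_mean, shrink_block)


def synthetic_spec(rng=None, max_n=3, max_k=3):
    """Small abstract index set (block structure only, no grid attached)."""
    rng = rng or np.random.default_rng(0)
    ns, ks = [], []
    for n in range(-max_n, max_n + 1):
        kk = int(rng.integers(1, max_k + 1)) if rng is not None else max_k
        for k in range(1, kk + 1):
            ns.append(n)
            ks.append(k)
    ns = np.asarray(ns)
    ks = np.asarray(ks)
    roots = np.abs(ns) + 2.0 * ks
    return BasisSpec(L=8, bandlimit=1e9, ns=ns, ks=ks, roots=roots,
                     normalizers=np.ones_like(roots))


def random_instance(rng):
    spec = synthetic_spec(rng)
    N = int(rng.integers(20, 101))
    D = int(rng.integers(1, 6))
    groups = rng.integers(0, D, size=N)
    while len(np.unique(groups)) < D:
        groups = rng.integers(0, D, size=N)
    W = rng.uniform(0.3, 1.5, size=(D, spec.size)) * rng.choice([-1.0, 1.0],
                                                                size=(D, spec.size))
    y = rng.standard_normal((N, spec.size)) + 1j * rng.standard_normal((N, spec.size))
    return spec, CoefficientSet(data=y, spec=spec), W, groups


def dense_mean_oracle(spec, y, W, groups):
    """Entrywise weighted least squares via generic lstsq."""
    out = np.zeros(spec.size, dtype=complex)
    sl = spec.block_slice(0)
    for j in range(sl.start, sl.stop):
        A = W[groups, j][:, None].astype(complex)
        out[j] = np.linalg.lstsq(A, y[:, j], rcond=None)[0][0]
    return out


def dense_cov_oracle(spec, y, W, groups, mean_vec, sigma2):
    """Per-entry generic least-squares solve of the covariance system."""
    Z = y - W[groups] * mean_vec[None, :]
    blocks = {}
    for n in spec.n_values:
        if n < 0:
            continue
        sl = spec.block_slice(n)
        k = sl.stop - sl.start
        S = np.zeros((k, k), dtype=complex)
        for j in range(k):
            for l in range(k):
                c = (W[groups, sl.start + j] * W[groups, sl.start + l]).astype(complex)
                rhs = Z[:, sl.start + j] * np.conj(Z[:, sl.start + l])
                if j == l:
                    rhs = rhs - sigma2
                S[j, l] = np.linalg.lstsq(c[:, None], rhs, rcond=None)[0][0]
        blocks[int(n)] = S
    return blocks


class TestEstimateMean:
    def test_uniform_weights_reduce_to_plain_average(self):
        rng = np.random.default_rng(1)
        spec = synthetic_spec(rng)
        y = rng.standard_normal((50, spec.size)) + 0j
        mean = estimate_mean(CoefficientSet(data=y, spec=spec),
                             np.ones((1, spec.size)), np.zeros(50, dtype=int))
        sl = spec.block_slice(0)
        np.testing.assert_allclose(mean.vec[sl], y[:, sl].mean(axis=0),
                                   atol=1e-12)
        mask = np.ones(spec.size, bool)
        mask[sl] = False
        assert np.abs(mean.vec[mask]).max() == 0.0

    def test_noiseless_scaled_signal_recovered_exactly(self):
        # y_i = c_{g(i)} o m: the weighted average returns m on n = 0
        rng = np.random.default_rng(2)
        spec = synthetic_spec(rng)
        D, N = 4, 80
        groups = np.arange(N) % D
        W = rng.uniform(0.2, 2.0, size=(D, spec.size))
        m = rng.standard_normal(spec.size) + 1j * rng.standard_normal(spec.size)
        y = W[groups] * m[None, :]
        mean = estimate_mean(CoefficientSet(data=y, spec=spec), W, groups)
        sl = spec.block_slice(0)
        np.testing.assert_allclose(mean.vec[sl], m[sl], rtol=1e-12)

    def test_matches_generic_wls_oracle(self):
        rng = np.random.default_rng(3)
        spec, cs, W, groups = random_instance(rng)
        mean = estimate_mean(cs, W, groups)
        oracle = dense_mean_oracle(spec, cs.data, W, groups)
        sl = spec.block_slice(0)
        np.testing.assert_allclose(mean.vec[sl], oracle[sl], atol=1e-10)


class TestEstimateCovariance:
    def test_reduces_to_plain_sample_covariance(self):
        # all CTF weights 1, sigma2 = 0, no shrinkage: exactly the
        # block-restricted sample covariance
        rng = np.random.default_rng(4)
        spec = synthetic_spec(rng)
        N = 60
        y = rng.standard_normal((N, spec.size)) + 1j * rng.standard_normal((N, spec.size))
        cs = CoefficientSet(data=y, spec=spec)
        W = np.ones((1, spec.size))
        groups = np.zeros(N, dtype=int)
        cov = estimate_covariance(cs, W, groups, sigma2=0.0, shrink=False)
        mean = estimate_mean(cs, W, groups)
        Z = y - mean.vec[None, :] * W[groups]
        for n, S in cov.blocks.items():
            sl = spec.block_slice(n)
            sample = Z[:, sl].T @ np.conj(Z[:, sl]) / N
            np.testing.assert_allclose(S, sample, atol=1e-12)

    def test_closed_form_equals_lstsq_oracle_on_random_instances(self):
        # property-based: 100 random instances, entrywise agreement
        rng = np.random.default_rng(5)
        for _ in range(100):
            spec, cs, W, groups = random_instance(rng)
            sigma2 = float(rng.uniform(0.0, 0.5))
            mean = estimate_mean(cs, W, groups)
            cov = estimate_covariance(cs, W, groups, mean=mean, sigma2=sigma2,
                                      shrink=False, a3_tol=0.0)
            oracle = dense_cov_oracle(spec, cs.data, W, groups, mean.vec, sigma2)
            for n, S in cov.blocks.items():
                np.testing.assert_allclose(S, oracle[n], atol=1e-9)

    def test_recovers_known_block_covariance(self, spec16):
        # draws from a known block covariance, through CTFs and noise
        rng = np.random.default_rng(6)
        blocks = {}
        for n in spec16.n_values:
            if n < 0:
                continue
            k = spec16.block_slice(n).stop - spec16.block_slice(n).start
            Araw = rng.standard_normal((k, k)) + 1j * rng.standard_normal((k, k))
            if n == 0:
                Araw = Araw.real.astype(complex)
            blocks[int(n)] = Araw @ Araw.conj().T / k
        truth = F.BlockCovariance(blocks=blocks, spec=spec16, sigma2=0.0)
        mean0 = F.MeanCoefficients(vec=np.zeros(spec16.size, complex), spec=spec16)
        N, D = 10_000, 16
        coeffs = F.sample_from_block_covariance(truth, mean0, N, seed=7)
        groups = np.arange(N) % D
        W = rng.uniform(0.5, 1.5, size=(D, spec16.size))
        noisy = coeffs.data * W[groups]
        noise = (rng.standard_normal((N, spec16.size))
                 + 1j * rng.standard_normal((N, spec16.size))) / np.sqrt(2)
        noisy = noisy + noise
        cs = CoefficientSet(data=noisy, spec=spec16)
        cov = estimate_covariance(cs, W, groups, sigma2=1.0, shrink=False)
        errs = F.block_relative_error(cov, truth)
        # threshold calibrated once at this seed; 1/sqrt(N) statistical scale
        assert np.median(list(errs.values())) < 0.15

    def test_a3_guard_names_offending_pair(self):
        rng = np.random.default_rng(8)
        spec = synthetic_spec(rng)
        N, D = 40, 2
        groups = np.arange(N) % D
        W = rng.uniform(0.5, 1.0, size=(D, spec.size))
        j = spec.block_slice(1).start
        W[:, j] = 0.0              # every CTF kills (n=1, k=1)
        y = rng.standard_normal((N, spec.size)) + 0j
        with pytest.raises(AssumptionA3Error, match=r"n=1, k=1"):
            estimate_covariance(CoefficientSet(data=y, spec=spec), W, groups,
                                sigma2=0.0, shrink=False)

    def test_insufficient_images_rejected(self):
        spec = synthetic_spec(np.random.default_rng(9))
        cs = CoefficientSet(data=np.zeros((1, spec.size), complex), spec=spec)
        with pytest.raises(ValueError, match="two images"):
            estimate_covariance(cs, np.ones((1, spec.size)), np.zeros(1, int))

    def test_shrunk_blocks_positive_semidefinite(self):
        rng = np.random.default_rng(10)
        spec, cs, W, groups = random_instance(rng)
        cov = estimate_covariance(cs, W, groups, sigma2=1.0, shrink=True,
                                  a3_tol=0.0)
        for S in cov.blocks.values():
            lam = np.linalg.eigvalsh(S)
            assert lam.min() >= -1e-10 * max(lam.max(), 1e-30)


class TestShrinkBlock:
    def test_pure_noise_block_maps_to_zero(self):
        for gamma in (0.05, 0.3, 1.0):
            out = shrink_block(np.eye(6) * 2.5, sigma2=2.5, gamma=gamma)
            assert np.abs(out).max() == 0.0

    def test_small_gamma_limit_is_debiasing(self):
        S = np.diag([4.0, 2.0, 0.5]).astype(complex)
        out = shrink_block(S, sigma2=1.0, gamma=1e-10)
        lam = np.sort(np.linalg.eigvalsh(out))[::-1]
        np.testing.assert_allclose(lam, [3.0, 1.0, 0.0], atol=1e-4)

    def test_spiked_model_recovery(self):
        # planted spike ell = 5 in sigma2 = 1 noise, gamma = 0.1, N = 5000:
        # the shrunk top eigenvalue is a consistent estimate of ell
        rng = np.random.default_rng(11)
        N, ell = 5000, 5.0
        p = int(0.1 * N)
        u = rng.standard_normal(p)
        u /= np.linalg.norm(u)
        X = rng.standard_normal((N, p)) + np.sqrt(ell) * np.outer(
            rng.standard_normal(N), u)
        S = X.T @ X / N
        out = shrink_block(S.astype(complex), sigma2=1.0, gamma=p / N)
        top = np.linalg.eigvalsh(out).max()
        assert top == pytest.approx(ell, rel=0.10)

    def test_non_hermitian_rejected(self):
        S = np.array([[1.0, 2.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="Hermitian"):
            shrink_block(S, 1.0, 0.1)

    def test_output_always_psd_on_random_hermitian(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            k = int(rng.integers(2, 8))
            A = rng.standard_normal((k, k)) + 1j * rng.standard_normal((k, k))
            S = 0.5 * (A + A.conj().T)
            out = shrink_block(S, sigma2=float(rng.uniform(0.1, 2.0)),
                               gamma=float(rng.uniform(0.01, 1.0)))
            assert np.linalg.eigvalsh(out).min() >= -1e-12


class TestEigenimages:
    def test_single_mode_covariance_returns_that_mode(self, spec16):
        blocks = {}
        for n in spec16.n_values:
            if n < 0:
                continue
            k = spec16.block_slice(n).stop - spec16.block_slice(n).start
            blocks[int(n)] = np.zeros((k, k), complex)
        blocks[0][0, 0] = 1.0      # only (n=0, k=1) active
        cov = F.BlockCovariance(blocks=blocks, spec=spec16)
        imgs, vals, orders = F.eigenimages(cov, spec16, 1)
        e = np.zeros(spec16.size, complex)
        e[spec16.block_slice(0).start] = 1.0
        psi = F.synthesize(e, spec16)[0]
        psi /= np.linalg.norm(psi)
        agreement = abs(np.vdot(imgs[0], psi))
        assert agreement == pytest.approx(1.0, abs=1e-10)
        assert vals[0] == pytest.approx(1.0)
        assert orders[0] == 0

    def test_eigenvalues_match_block_assembled_dense_solve(self, spec16):
        rng = np.random.default_rng(13)
        blocks = {}
        for n in spec16.n_values:
            if n < 0:
                continue
            k = spec16.block_slice(n).stop - spec16.block_slice(n).start
            A = rng.standard_normal((k, k)) + 1j * rng.standard_normal((k, k))
            blocks[int(n)] = A @ A.conj().T
        cov = F.BlockCovariance(blocks=blocks, spec=spec16)
        m = 10
        _, vals, _ = F.eigenimages(cov, spec16, m)
        # dense oracle: assemble the nonnegative-order blocks into one matrix
        idx = np.flatnonzero(spec16.ns >= 0)
        big = np.zeros((idx.size, idx.size), complex)
        pos = {int(j): i for i, j in enumerate(idx)}
        for n, S in blocks.items():
            sl = spec16.block_slice(n)
            for a in range(S.shape[0]):
                for b in range(S.shape[1]):
                    big[pos[sl.start + a], pos[sl.start + b]] = S[a, b]
        dense = np.sort(np.linalg.eigvalsh(big))[::-1][:m]
        np.testing.assert_allclose(vals, dense, rtol=1e-10)

    def test_requesting_more_than_rank_warns_and_truncates(self, spec16):
        blocks = {int(n): np.zeros((spec16.block_slice(n).stop
                                    - spec16.block_slice(n).start,) * 2,
                                   complex)
                  for n in spec16.n_values if n >= 0}
        blocks[0][0, 0] = 1.0
        cov = F.BlockCovariance(blocks=blocks, spec=spec16)
        total = sum(S.shape[0] for S in blocks.values())
        with pytest.warns(UserWarning, match="truncating"):
            imgs, vals, _ = F.eigenimages(cov, spec16, total + 5)
        assert imgs.shape[0] == total
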
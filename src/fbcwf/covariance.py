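"""Closed-form estimation of the mean and block-diagonal covariance of
CTF-affected images in the disk-harmonic basis.

Model: each observed coefficient vector is ``y_i = c_{g(i)} o x_i + eps_i``
where ``c_d`` is the (diagonal) CTF weight vector of defocus group ``d``,
``x_i`` is the clean image, and ``eps_i`` is white noise of per-coefficient
variance ``sigma2`` (unity after whitening).  For an ensemble whose
distribution is invariant to in-plane rotation, the covariance of the
``x_i`` is block diagonal over angular orders ``n``, and the least-squares
estimators of the mean and of every block entry have closed forms:

    mu_hat      = (sum_i c_i o y_i) / (sum_i c_i^2)          on n = 0,
    Sigma_{jl}  = sum_i c_ij c_il (z_ij conj(z_il) - sigma2*1{j=l})
                  / sum_i c_ij^2 c_il^2,
    z_i = y_i - c_i o mu_hat,

with j, l restricted to a common angular block.  The per-image work is a
single rank-one accumulation per block, so the cost is independent of the
number of defocus groups.  Because the sigma2 subtraction can push blocks
indefinite, eigenvalue shrinkage of the un-debiased per-block second moment
replaces the subtraction when ``shrink=True`` (the default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import BasisSpec, synthesize
from .ctf import weights_matrix


class AssumptionA3Error(ValueError):
    """The CTF ensemble annihilates some frequency pair."""


@dataclass
class MeanCoefficients:
    """Estimated mean coefficient vector; nonzero only on angular order 0."""

    vec: np.ndarray
    spec: BasisSpec


@dataclass
class BlockCovariance:
    """Block-diagonal covariance: angular order n >= 0 -> Hermitian block.

    Negative-order blocks are not stored; by the real-image conjugate
    symmetry they equal the complex conjugates of the positive-order
    blocks.
    """

    blocks: dict[int, np.ndarray]
    spec: BasisSpec
    sigma2: float = 1.0
    n_images: int = 0

    def block(self, n: int) -> np.ndarray:
        if n >= 0:
            return self.blocks[n]
        return np.conj(self.blocks[-n])

    @property
    def n_values(self):
        return sorted(self.blocks.keys())

    def eigenvalues(self) -> np.ndarray:
        """All block eigenvalues (positive orders only), descending."""
        vals = [np.linalg.eigvalsh(S) for S in self.blocks.values()]
        return np.sort(np.concatenate(vals))[::-1]

    def total_trace(self) -> float:
        return float(sum(np.trace(S).real for S in self.blocks.values()))


def _group_sums(data: np.ndarray, groups: np.ndarray, n_groups: int):
    """Per-group sums of rows of ``data`` (complex safe)."""
    out = np.zeros((n_groups, data.shape[1]), dtype=data.dtype)
    np.add.at(out, groups, data)
    return out


def _check_groups(n_images: int, groups, n_groups: int) -> np.ndarray:
    groups = np.asarray(groups, dtype=np.int64)
    if groups.shape != (n_images,):
        raise ValueError("group map must assign one group per image")
    if groups.min() < 0 or groups.max() >= n_groups:
        raise ValueError("group index out of range of the CTF table")
    return groups


def estimate_mean(coeffs, weights, groups) -> MeanCoefficients:
    """Closed-form weighted least-squares estimate of the mean.

    Only the angular order 0 entries can be nonzero: for a rotation-
    invariant ensemble every other angular component averages to zero.
    """
    data = coeffs.data if hasattr(coeffs, "data") else np.atleast_2d(coeffs)
    spec = coeffs.spec
    W = weights_matrix(weights)
    groups = _check_groups(data.shape[0], groups, W.shape[0])

    sl = spec.block_slice(0)
    counts = np.bincount(groups, minlength=W.shape[0]).astype(float)
    ysum = _group_sums(data[:, sl], groups, W.shape[0])
    num = (W[:, sl] * ysum).sum(axis=0)
    den = (counts[:, None] * W[:, sl] ** 2).sum(axis=0)
    if np.any(den <= 0):
        k_bad = int(spec.ks[sl][int(np.argmin(den))])
        raise AssumptionA3Error(
            f"all CTFs vanish at angular order 0, radial index k={k_bad}; "
            "the mean is unidentifiable there")
    vec = np.zeros(spec.size, dtype=np.complex128)
    vec[sl] = num / den
    return MeanCoefficients(vec=vec, spec=spec)


def shrink_block(S: np.ndarray, sigma2: float, gamma: float,
                 herm_tol: float = 1e-8) -> np.ndarray:
    """Operator-norm eigenvalue shrinkage of a Hermitian block.

    Under the spiked covariance model with noise level ``sigma2`` and
    aspect ratio ``gamma = k / N``, sample eigenvalues inside the noise
    bulk (lambda <= sigma2 * (1 + sqrt(gamma))^2) carry no signal and are
    mapped to zero; eigenvalues above the bulk edge are debiased to the
    consistent estimate of the underlying spike,

        ell = sigma2 * ((x - 1 - gamma) + sqrt((x-1-gamma)^2 - 4 gamma))/2,
        x = lambda / sigma2.

    As gamma -> 0 this reduces to plain subtraction ell = lambda - sigma2.
    The output is positive semidefinite by construction.
    """
    S = np.asarray(S)
    if S.shape[0] != S.shape[1]:
        raise ValueError("block must be square")
    scale = max(np.abs(S).max(), 1e-300)
    if np.abs(S - S.conj().T).max() > herm_tol * scale:
        raise ValueError("block is not Hermitian within tolerance")
    if gamma <= 0:
        raise ValueError("aspect ratio gamma must be positive")
    Sh = 0.5 * (S + S.conj().T)
    lam, V = np.linalg.eigh(Sh)
    if sigma2 <= 0:
        out_lam = np.clip(lam, 0.0, None)
    else:
        edge = sigma2 * (1.0 + np.sqrt(gamma)) ** 2
        x = lam / sigma2
        t = x - 1.0 - gamma
        disc = np.clip(t * t - 4.0 * gamma, 0.0, None)
        ell = sigma2 * 0.5 * (t + np.sqrt(disc))
        out_lam = np.where(lam > edge, np.clip(ell, 0.0, None), 0.0)
    return (V * out_lam[None, :]) @ V.conj().T


def estimate_covariance(coeffs, weights, groups, mean: MeanCoefficients | None = None,
                        sigma2: float = 1.0, shrink: bool = True,
                        a3_tol: float = 1e-8) -> BlockCovariance:
    """Closed-form block covariance estimate across defocus groups.

    Parameters
    ----------
    coeffs : CoefficientSet or (N, b) array of whitened coefficients.
    weights : per-group CTF weights, list of CTFWeights or (D, b) array
        (whitened to match ``sigma2``).
    groups : (N,) integer map image -> defocus group.
    mean : mean coefficients; estimated if None.
    sigma2 : per-coefficient noise variance (1 after whitening).
    shrink : replace the sigma2 debiasing subtraction with per-block
        eigenvalue shrinkage of the second-moment matrix (default), which
        also guarantees positive semidefinite output.
    a3_tol : identifiability guard: the minimum over same-block pairs
        (j, l) of sum_d N_d c_dj^2 c_dl^2 / N must exceed this.
    """
    data = coeffs.data if hasattr(coeffs, "data") else np.atleast_2d(coeffs)
    spec = coeffs.spec
    W = weights_matrix(weights)
    groups = _check_groups(data.shape[0], groups, W.shape[0])
    N = data.shape[0]
    if N < 2:
        raise ValueError("covariance estimation needs at least two images")

    if mean is None:
        mean = estimate_mean(coeffs, weights, groups)

    counts = np.bincount(groups, minlength=W.shape[0]).astype(float)
    # z_i = y_i - c_{g(i)} o mu ; then w_i = c_{g(i)} o z_i so that each
    # block numerator is a plain Gram accumulation sum_i w_i w_i^H.
    Z = data - W[groups] * mean.vec[None, :]
    Wz = W[groups] * Z
    csum2 = (counts[:, None] * W ** 2).sum(axis=0)     # sum_i c_{i,j}^2

    blocks: dict[int, np.ndarray] = {}
    for n in spec.n_values:
        if n < 0:
            continue
        sl = spec.block_slice(n)
        k = sl.stop - sl.start
        Cb2 = W[:, sl] ** 2
        den = (Cb2 * counts[:, None]).T @ Cb2      # sum_d N_d c^2 (c^2)^T
        if den.min() < a3_tol * N:
            j, l = np.unravel_index(np.argmin(den), den.shape)
            raise AssumptionA3Error(
                "CTF ensemble nearly annihilates the frequency pair "
                f"(n={int(n)}, k={int(spec.ks[sl][j])}) x "
                f"(n={int(n)}, k={int(spec.ks[sl][l])}): "
                f"sum_d N_d c_j^2 c_l^2 / N = {den.min() / N:.3e} < {a3_tol:.1e}")
        A = Wz[:, sl].T @ np.conj(Wz[:, sl])           # sum_i w_i w_i^H
        if shrink:
            # Normalize by sqrt(mean c^2) per entry so the additive noise
            # floor of the second-moment matrix is exactly sigma2 on the
            # diagonal (and approximately white off it); shrink there, then
            # map back.  Without this the division below amplifies whatever
            # noise survives shrinkage at weakly transferred frequencies.
            q = np.sqrt(csum2[sl] / N)
            Sn = shrink_block((A / N) / np.outer(q, q), sigma2, k / N)
            num = N * Sn * np.outer(q, q)
        else:
            num = A - sigma2 * np.diag(csum2[sl])
        Sb = num / den
        Sb = 0.5 * (Sb + Sb.conj().T)
        if shrink:
            # Hadamard division does not preserve semidefiniteness exactly;
            # clip residual negative curvature.
            lam, V = np.linalg.eigh(Sb)
            Sb = (V * np.clip(lam, 0.0, None)[None, :]) @ V.conj().T
        blocks[int(n)] = Sb
    return BlockCovariance(blocks=blocks, spec=spec, sigma2=sigma2, n_images=N)


def eigenimages(cov: BlockCovariance, spec: BasisSpec, m: int):
    """Top-m principal component images of a block covariance.

    Per-block eigendecompositions are merged and sorted by eigenvalue.  For
    n > 0 the returned image is the real part of the synthesized complex
    eigenfunction; each such eigenvalue is two-fold degenerate (shared with
    the conjugate block at -n), and the returned representative is defined
    up to a global rotation phase.

    Returns (images, eigenvalues, orders); images are L2-normalized.
    """
    entries = []
    for n, S in cov.blocks.items():
        lam, V = np.linalg.eigh(S)
        for i in range(lam.size):
            entries.append((float(lam[i]), int(n), V[:, i]))
    entries.sort(key=lambda e: -e[0])
    total = len(entries)
    if m > total:
        import warnings
        warnings.warn(f"requested {m} eigenimages but rank is {total}; truncating")
        m = total
    imgs = np.zeros((m, spec.L, spec.L))
    vals = np.zeros(m)
    orders = np.zeros(m, dtype=int)
    for i, (lam, n, v) in enumerate(entries[:m]):
        vec = np.zeros(spec.size, dtype=np.complex128)
        vec[spec.block_slice(n)] = v
        img = synthesize(vec, spec)[0]
        nrm = np.linalg.norm(img)
        imgs[i] = img / nrm if nrm > 0 else img
        vals[i] = lam
        orders[i] = n
    return imgs, vals, orders
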
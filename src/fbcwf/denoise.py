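"""Covariance Wiener filtering (CWF): joint CTF correction and denoising.

Given the estimated mean ``mu`` and block covariance ``Sigma`` of the clean
coefficients, the linear minimum-MSE estimate of the clean coefficients of
image ``i`` in defocus group ``g`` is, per angular block,

    x_hat = mu + Sigma C_g (C_g Sigma C_g + sigma2 I)^{-1} (y - C_g mu),

where ``C_g`` is the diagonal matrix of the group's CTF weights restricted
to the block.  The filter simultaneously deconvolves the CTF (where the
covariance carries signal) and suppresses noise.  A phase-flipping baseline
(multiplying coefficients by the sign of the CTF) is provided for
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .basis import BasisSpec, synthesize
from .covariance import BlockCovariance, MeanCoefficients, _check_groups
from .ctf import weights_matrix


@dataclass
class DenoisedStack:
    """CWF output: denoised coefficients and synthesized images."""

    coeffs: np.ndarray       # (N, b) complex, conjugate-symmetric
    images: np.ndarray       # (N, L, L) real
    spec: BasisSpec
    sigma2: float
    groups: np.ndarray


def _solve_block(M: np.ndarray, rhs: np.ndarray, sigma2: float) -> np.ndarray:
    """Hermitian solve with a trace-scaled jitter retry on breakdown."""
    try:
        return cho_solve(cho_factor(M, lower=True, check_finite=False), rhs,
                         check_finite=False)
    except np.linalg.LinAlgError:
        pass
    except ValueError:
        pass
    if sigma2 <= 0:
        raise np.linalg.LinAlgError(
            "Wiener system singular at sigma2 = 0: some CTF weight vanishes "
            "on a block with full-rank covariance; supply sigma2 > 0")
    jitter = 1e-12 * np.trace(M).real / M.shape[0]
    M = M + jitter * np.eye(M.shape[0])
    return cho_solve(cho_factor(M, lower=True, check_finite=False), rhs,
                     check_finite=False)


def cwf_denoise(coeffs, weights, groups, mean: MeanCoefficients,
                cov: BlockCovariance, sigma2: float = 1.0,
                batch_size: int = 1000) -> DenoisedStack:
    """Apply the covariance Wiener filter to a coefficient stack.

    Images are processed group by group so each group's per-block system
    ``C Sigma C + sigma2 I`` is factored once; ``batch_size`` bounds the
    number of rows handled per solve (memory control for large stacks).
    Negative-order coefficients are filled in from the conjugate symmetry
    of real images.
    """
    data = coeffs.data if hasattr(coeffs, "data") else np.atleast_2d(coeffs)
    spec = coeffs.spec
    W = weights_matrix(weights)
    groups = _check_groups(data.shape[0], groups, W.shape[0])
    N = data.shape[0]

    out = np.zeros((N, spec.size), dtype=np.complex128)
    nonneg = [int(n) for n in spec.n_values if n >= 0]
    for d in np.unique(groups):
        rows = np.flatnonzero(groups == d)
        cd = W[d]
        for n in nonneg:
            sl = spec.block_slice(n)
            c = cd[sl]
            S = cov.block(n)
            mu = mean.vec[sl]
            M = (c[:, None] * S * c[None, :]) + sigma2 * np.eye(c.size)
            B = S * c[None, :]                      # Sigma C
            for lo in range(0, rows.size, max(batch_size, 1)):
                rr = rows[lo:lo + max(batch_size, 1)]
                rhs = (data[rr][:, sl] - c * mu).T  # (k, batch)
                xb = mu[:, None] + B @ _solve_block(M, rhs, sigma2)
                out[rr[:, None], np.arange(sl.start, sl.stop)[None, :]] = xb.T
                if n > 0:
                    slm = spec.block_slice(-n)
                    out[rr[:, None], np.arange(slm.start, slm.stop)[None, :]] = \
                        ((-1.0) ** n) * np.conj(xb.T)
    images = synthesize(out, spec)
    return DenoisedStack(coeffs=out, images=images, spec=spec,
                         sigma2=sigma2, groups=groups)


def phase_flip(coeffs, weights, groups) -> np.ndarray:
    """Phase-flipping baseline: multiply coefficients by sign(CTF).

    Corrects the CTF sign flips but neither its amplitude attenuation nor
    the noise; the standard crude comparator for CWF output.
    """
    data = coeffs.data if hasattr(coeffs, "data") else np.atleast_2d(coeffs)
    W = weights_matrix(weights)
    groups = _check_groups(data.shape[0], groups, W.shape[0])
    return data * np.sign(W[groups])
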
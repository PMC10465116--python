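"""Evaluation metrics: per-angular-order covariance error and Fourier ring
correlation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import fft2
from scipy.ndimage import map_coordinates

from .covariance import BlockCovariance


@dataclass
class FRCCurve:
    """Fourier ring correlation: per-ring normalized cross-correlation."""

    freqs: np.ndarray    # ring radii, cycles/pixel
    values: np.ndarray   # real correlations, |value| <= 1 (+ tolerance)


def block_relative_error(est: BlockCovariance, truth: BlockCovariance) -> dict[int, float]:
    """Frobenius relative error per angular order,
    ``err(n) = ||S_est(n) - S_true(n)||_F / ||S_true(n)||_F``.

    Orders whose true block vanishes are undefined and omitted from the
    result.
    """
    if est.spec.size != truth.spec.size or est.spec.L != truth.spec.L:
        raise ValueError("covariances use different basis specs")
    out: dict[int, float] = {}
    for n in truth.n_values:
        T = truth.block(n)
        denom = np.linalg.norm(T)
        if denom == 0:
            continue
        E = est.block(n)
        out[int(n)] = float(np.linalg.norm(E - T) / denom)
    return out


def _ring_samples(data: np.ndarray, n_rings: int, n_ang: int, pad_factor: int = 4):
    """Sample each image's Fourier transform on concentric rings.

    Rings sit at integer cycles per image (radius k/L cycles/pixel,
    k = 1..n_rings) with ``n_ang`` equispaced angles; values are read from
    a zero-padded FFT by bilinear interpolation of the real and imaginary
    parts.  Returns an array of shape (N, n_rings, n_ang), complex.
    """
    N, L, _ = data.shape
    pad = pad_factor * L
    F = np.fft.fftshift(fft2(data, s=(pad, pad), axes=(-2, -1)),
                        axes=(-2, -1))
    ang = 2 * np.pi * np.arange(n_ang) / n_ang
    radii = np.arange(1, n_rings + 1)            # cycles per image
    rr = radii[:, None] * pad_factor             # index units of padded grid
    ci = pad // 2 + rr * np.sin(ang)[None, :]
    cj = pad // 2 + rr * np.cos(ang)[None, :]
    coords = np.stack([ci, cj])
    out = np.empty((N, n_rings, n_ang), dtype=np.complex128)
    for i in range(N):
        out[i] = (map_coordinates(F[i].real, coords, order=1)
                  + 1j * map_coordinates(F[i].imag, coords, order=1))
    return out


def frc(stack_a, stack_b, n_rings: int | None = None,
        pooled: bool = False) -> FRCCurve:
    """Fourier ring correlation between two image stacks.

    For each ring the normalized inner product of the two transforms is
    computed per image pair and averaged (``pooled=False``, default), or the
    inner products and norms are pooled across the stack before normalizing
    (``pooled=True``).  The real part is returned; it is exact for
    real-valued images by conjugate symmetry.
    """
    A = np.asarray(getattr(stack_a, "data", stack_a), dtype=float)
    B = np.asarray(getattr(stack_b, "data", stack_b), dtype=float)
    if A.ndim == 2:
        A = A[None]
    if B.ndim == 2:
        B = B[None]
    if A.shape != B.shape:
        raise ValueError(f"stack shapes differ: {A.shape} vs {B.shape}")
    N, L, _ = A.shape
    if n_rings is None:
        n_rings = L // 2
    n_ang = 4 * L
    Fa = _ring_samples(A, n_rings, n_ang)
    Fb = _ring_samples(B, n_rings, n_ang)
    inner = np.einsum("irk,irk->ir", Fa, np.conj(Fb))
    na = np.sqrt(np.einsum("irk,irk->ir", Fa, np.conj(Fa)).real)
    nb = np.sqrt(np.einsum("irk,irk->ir", Fb, np.conj(Fb)).real)
    if pooled:
        vals = (inner.sum(axis=0).real
                / np.maximum(np.sqrt((na ** 2).sum(axis=0) * (nb ** 2).sum(axis=0)),
                             1e-300))
    else:
        vals = (inner.real / np.maximum(na * nb, 1e-300)).mean(axis=0)
    freqs = np.arange(1, n_rings + 1) / L
    return FRCCurve(freqs=freqs, values=vals)


def disk_mse(stack_a, stack_b, L: int | None = None) -> float:
    """Mean squared difference over the pixels of the inscribed unit disk."""
    A = np.asarray(getattr(stack_a, "data", stack_a), dtype=float)
    B = np.asarray(getattr(stack_b, "data", stack_b), dtype=float)
    if A.shape != B.shape:
        raise ValueError("stack shapes differ")
    if A.ndim == 2:
        A, B = A[None], B[None]
    side = A.shape[-1]
    c = side // 2
    t = (np.arange(side) - c) * (2.0 / side)
    mask = np.hypot(t[None, :], t[:, None]) <= 1.0
    return float(((A - B) ** 2)[:, mask].mean())
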
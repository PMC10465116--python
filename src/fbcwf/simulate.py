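"""Synthetic-data generation: rotation-invariant phantom ensembles, defocus
groups, CTF corruption, and colored noise at controlled SNR.

The generator emulates the standard single-particle simulation design:
clean disk-supported templates are drawn with random in-plane rotations
(the ensemble is exactly rotation invariant, so its coefficient covariance
is block diagonal), assigned to ``D`` defocus groups whose defocus values
are equally spaced over a range, convolved with the group CTFs, and
corrupted with colored noise scaled to a target SNR.  SNR is defined as the
ratio of clean (pre-CTF) signal power to noise power over the inscribed
disk.

All draws are routed through one seeded generator, so every output is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import fft2, ifft2

from .basis import BasisSpec, CoefficientSet, compute_basis, expand, steer_array, synthesize
from .covariance import BlockCovariance, MeanCoefficients
from .ctf import CTFParams, eval_ctf, _radial_freq_grid
from .stack import ImageStack, disk_mask as _disk_mask


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    Defaults reproduce the reference experimental design: 10^4 images,
    defocus groups spanning 1-4 um at 300 kV with Cs = 2 mm, SNR 0.1, and a
    Lorentzian noise power spectrum.  The default pixel size mimics
    downsampling a 0.832 Angstrom / 512-pixel map to size L.
    """

    L: int = 32
    n_images: int = 10_000
    n_defocus_groups: int = 16
    defocus_min_um: float = 1.0
    defocus_max_um: float = 4.0
    voltage_kV: float = 300.0
    cs_mm: float = 2.0
    amplitude_contrast: float = 0.07
    snr: float = 0.1
    noise_s0: float = 0.1          # Lorentzian knee, cycles/pixel
    pixel_size_A: float | None = None
    n_templates: int = 4
    random_groups: bool = False    # round-robin assignment by default
    seed: int = 0

    def __post_init__(self):
        if self.n_defocus_groups > self.n_images:
            raise ValueError("more defocus groups than images")
        if self.defocus_min_um <= 0 or self.defocus_max_um < self.defocus_min_um:
            raise ValueError("defocus range must be positive and ordered")
        if self.pixel_size_A is None:
            self.pixel_size_A = 0.832 * 512 / self.L

    def noise_psd(self, s):
        """Noise power spectral density (unnormalized), Lorentzian family
        ``1 / (1 + (s / s0)^2)`` in cycles/pixel."""
        s = np.asarray(s, dtype=float)
        return 1.0 / (1.0 + (s / self.noise_s0) ** 2)


def make_templates(L: int, n_templates: int, seed: int = 0,
                   p_fold: int | None = None,
                   pixel_size_A: float = 1.0) -> ImageStack:
    """Smooth disk-supported phantoms built from anisotropic Gaussian blobs.

    Each template sums 6-10 signed blobs with centers inside radius 0.55
    and widths 0.08-0.22 (unit-disk units); with ``p_fold`` set, the blob
    set is replicated at the p rotations, making the template exactly
    p-fold symmetric.  Templates are normalized to unit mean square over
    the disk.
    """
    if n_templates < 1:
        raise ValueError("need at least one template")
    rng = np.random.default_rng(seed)
    c = L // 2
    t = (np.arange(L) - c) * (2.0 / L)
    x = t[None, :]
    y = t[:, None]
    mask = _disk_mask(L)
    out = np.zeros((n_templates, L, L))
    for it in range(n_templates):
        n_blobs = int(rng.integers(6, 11))
        img = np.zeros((L, L))
        for _ in range(n_blobs):
            rho = 0.55 * np.sqrt(rng.uniform())
            phi0 = rng.uniform(0, 2 * np.pi)
            sig1, sig2 = rng.uniform(0.08, 0.22, size=2)
            alpha = rng.uniform(0, np.pi)
            amp = rng.uniform(0.4, 1.0) * rng.choice([-1.0, 1.0])
            reps = p_fold if p_fold else 1
            for j in range(reps):
                ang = phi0 + 2 * np.pi * j / max(reps, 1)
                cx, cy = rho * np.cos(ang), rho * np.sin(ang)
                ca, sa = np.cos(alpha + ang - phi0), np.sin(alpha + ang - phi0)
                u = ca * (x - cx) + sa * (y - cy)
                v = -sa * (x - cx) + ca * (y - cy)
                img += amp * np.exp(-0.5 * ((u / sig1) ** 2 + (v / sig2) ** 2))
        img = img * mask
        power = (img[mask] ** 2).mean()
        out[it] = img / np.sqrt(power) if power > 0 else img
    return ImageStack(data=out, pixel_size_A=pixel_size_A)


def sample_rotated_ensemble(templates: ImageStack, N: int, seed: int = 0,
                            spec: BasisSpec | None = None,
                            return_coeffs: bool = False):
    """Draw N images: a uniform template steered by a uniform angle.

    Rotation is applied in coefficient space (exact steering), then the
    images are synthesized back to the grid.  With ``return_coeffs`` the
    exact rotated coefficients are returned alongside the stack.
    """
    if spec is None:
        spec = compute_basis(templates.L)
    rng = np.random.default_rng(seed)
    tmpl_coeffs = expand(templates.data, spec).data
    which = rng.integers(0, templates.n_images, size=N)
    angles = rng.uniform(0.0, 2 * np.pi, size=N)
    coeffs = steer_array(tmpl_coeffs[which], spec, angles)
    images = synthesize(coeffs, spec)
    stack = ImageStack(data=images, pixel_size_A=templates.pixel_size_A)
    if return_coeffs:
        return stack, CoefficientSet(data=coeffs, spec=spec)
    return stack


def sample_from_block_covariance(cov0: BlockCovariance, mean0: MeanCoefficients,
                                 N: int, seed: int = 0) -> CoefficientSet:
    """Gaussian coefficient draws with a prescribed block covariance.

    Order-0 coefficients are real Gaussian; orders n > 0 are circular
    complex Gaussian with the block covariance, and the negative orders are
    filled by the conjugate symmetry so synthesized images are real.
    """
    spec = cov0.spec
    rng = np.random.default_rng(seed)
    out = np.tile(mean0.vec[None, :], (N, 1)).astype(np.complex128)
    for n in cov0.n_values:
        S = cov0.blocks[n]
        lam, V = np.linalg.eigh(0.5 * (S + S.conj().T))
        if lam.min() < -1e-10 * max(lam.max(), 1e-300):
            raise ValueError(f"block n={n} is not positive semidefinite")
        A = V * np.sqrt(np.clip(lam, 0.0, None))[None, :]
        sl = spec.block_slice(n)
        k = sl.stop - sl.start
        if n == 0:
            g = rng.standard_normal((N, k))
            out[:, sl] += g @ A.real.T
        else:
            g = (rng.standard_normal((N, k)) + 1j * rng.standard_normal((N, k))) \
                / np.sqrt(2.0)
            draw = g @ A.T          # E[draw draw^H] = A A^H = S
            out[:, sl] += draw
            slm = spec.block_slice(-n)
            out[:, slm] += ((-1.0) ** n) * np.conj(draw)
    return CoefficientSet(data=out, spec=spec)


def realized_noise_psd(clean: ImageStack, config: SimulationConfig,
                       n_freqs: int = 512):
    """The exact noise PSD (including the SNR scale) that :func:`corrupt`
    applies to this clean stack, as a :class:`~fbcwf.ctf.NoisePSD`.

    The frequency grid extends to the grid-diagonal Nyquist so no corner
    frequency is clamped.  Whitening the corrupted stack with this PSD
    (``pad=False``) makes the residual noise exactly white on the grid.
    """
    from .ctf import NoisePSD, _radial_freq_grid

    mask = _disk_mask(clean.L)
    signal_power = float((clean.data[:, mask] ** 2).mean())
    expected_power = float(config.noise_psd(_radial_freq_grid(clean.L)).mean())
    scale2 = signal_power / (config.snr * expected_power)
    freqs = np.linspace(0.0, 0.5 * np.sqrt(2.0) * 1.001, n_freqs)
    return NoisePSD(freqs=freqs, values=scale2 * config.noise_psd(freqs))


def rotation_invariant_moments(template_coeffs: np.ndarray, spec: BasisSpec):
    """Exact mean and block covariance of the rotated-template ensemble.

    For images drawn as a uniform template steered by a uniform angle, the
    angular phases average out analytically: the mean is the template-
    averaged order-0 component, and the covariance block at order n is the
    template average of ``a_n a_n^H`` (minus the mean outer product at
    n = 0).  Serves as ground truth for estimator validation.
    """
    A = np.atleast_2d(template_coeffs)
    mu = np.zeros(spec.size, dtype=np.complex128)
    sl0 = spec.block_slice(0)
    mu[sl0] = A[:, sl0].mean(axis=0)
    blocks = {}
    for n in spec.n_values:
        if n < 0:
            continue
        sl = spec.block_slice(n)
        An = A[:, sl]
        S = (An.T @ np.conj(An)) / A.shape[0]
        if n == 0:
            S = S - np.outer(mu[sl0], np.conj(mu[sl0]))
        blocks[int(n)] = 0.5 * (S + S.conj().T)
    mean = MeanCoefficients(vec=mu, spec=spec)
    cov = BlockCovariance(blocks=blocks, spec=spec, sigma2=0.0,
                          n_images=A.shape[0])
    return mean, cov


def defocus_table(config: SimulationConfig) -> pd.DataFrame:
    """Per-group CTF parameter table (defocus equally spaced over range)."""
    D = config.n_defocus_groups
    if D == 1:
        dfs = np.array([0.5 * (config.defocus_min_um + config.defocus_max_um)])
    else:
        dfs = np.linspace(config.defocus_min_um, config.defocus_max_um, D)
    return pd.DataFrame({
        "group_id": np.arange(D),
        "defocus_A": dfs * 1e4,
        "voltage_kV": config.voltage_kV,
        "cs_mm": config.cs_mm,
        "amplitude_contrast": config.amplitude_contrast,
        "pixel_size_A": config.pixel_size_A,
    })


def params_from_table(table: pd.DataFrame) -> list[CTFParams]:
    return [CTFParams(defocus_A=row.defocus_A, voltage_kV=row.voltage_kV,
                      cs_mm=row.cs_mm, amplitude_contrast=row.amplitude_contrast,
                      pixel_size_A=row.pixel_size_A, group_id=int(row.group_id))
            for row in table.itertuples(index=False)]


def _apply_ctf_grid(images: np.ndarray, params: CTFParams) -> np.ndarray:
    """Convolve images with the PSF by Fourier multiplication on a 2x
    zero-padded grid (limits circular wrap-around)."""
    N, L, _ = images.shape
    pad = 2 * L
    s = _radial_freq_grid(pad) / params.pixel_size_A    # cycles/Angstrom
    H = eval_ctf(params, s)
    F = fft2(images, s=(pad, pad), axes=(-2, -1))
    return ifft2(F * H[None], axes=(-2, -1)).real[:, :L, :L].copy()


def _colored_noise(rng, N: int, L: int, config: SimulationConfig) -> np.ndarray:
    """Stationary Gaussian noise with the configured radial PSD, unit
    normalization (pixel variance equals the PSD grid mean)."""
    s = _radial_freq_grid(L)
    H = np.sqrt(config.noise_psd(s))
    white = rng.standard_normal((N, L, L))
    return ifft2(fft2(white, axes=(-2, -1)) * H[None], axes=(-2, -1)).real


def corrupt(images: ImageStack, config: SimulationConfig,
            rng: np.random.Generator | None = None):
    """CTF-corrupt a clean stack and add colored noise at the target SNR.

    Images are assigned to defocus groups (round-robin by default, uniform
    random with ``config.random_groups``), each group convolved with its
    CTF, and noise added with the configured PSD scaled so that the disk-
    restricted power ratio of the clean pre-CTF signal to the noise equals
    ``config.snr``.

    Returns (noisy ImageStack with group ids, CTF table, group map).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    data = images.data
    N, L, _ = data.shape
    D = config.n_defocus_groups
    table = defocus_table(config)
    params = params_from_table(table)

    if config.random_groups:
        groups = rng.integers(0, D, size=N)
    else:
        groups = np.arange(N) % D

    out = np.empty_like(data)
    for d in range(D):
        rows = np.flatnonzero(groups == d)
        if rows.size:
            out[rows] = _apply_ctf_grid(data[rows], params[d])

    mask = _disk_mask(L)
    signal_power = float((data[:, mask] ** 2).mean())
    if np.isfinite(config.snr) and config.snr > 0:
        noise = _colored_noise(rng, N, L, config)
        expected_power = float(config.noise_psd(_radial_freq_grid(L)).mean())
        scale = np.sqrt(signal_power / (config.snr * expected_power))
        out = out + scale * noise
    stack = ImageStack(data=out, pixel_size_A=config.pixel_size_A,
                       group_ids=groups)
    return stack, table, groups
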
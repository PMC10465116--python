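"""Radial contrast transfer functions, noise power spectra, and whitening.

The CTF is the Fourier transform of the microscope's point spread function.
For a radial (astigmatism-free) PSF it is the radial function

    CTF(s) = -sqrt(1 - w^2) * sin(chi(s)) - w * cos(chi(s)),
    chi(s) = pi * lambda_e * z * s^2 - (pi/2) * Cs * lambda_e^3 * s^4,

with ``s`` the radial frequency in cycles/Angstrom, ``z`` the defocus in
Angstrom (positive = underfocus), ``Cs`` the spherical aberration in
Angstrom, ``w`` the amplitude contrast, and ``lambda_e`` the relativistic
electron wavelength.  Because the disk-harmonic basis diagonalizes radial
convolution, the action of a CTF on an image reduces to an entrywise
product with the CTF sampled at the basis frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.fft import fft2, ifft2

from .basis import BasisSpec, radial_conv_weights


@dataclass(frozen=True)
class CTFParams:
    """Imaging parameters of one defocus group."""

    defocus_A: float
    voltage_kV: float = 300.0
    cs_mm: float = 2.0
    amplitude_contrast: float = 0.07
    pixel_size_A: float = 1.0
    group_id: int = 0
    b_factor: float = 0.0  # optional envelope exp(-B s^2 / 4), Angstrom^2

    def __post_init__(self):
        if self.voltage_kV <= 0:
            raise ValueError("voltage must be positive")
        if self.pixel_size_A <= 0:
            raise ValueError("pixel size must be positive")


@dataclass
class CTFWeights:
    """CTF sampled at the basis frequencies of one defocus group."""

    c: np.ndarray          # (b,) real weights
    group_id: int = 0
    whitened: bool = False


@dataclass
class NoisePSD:
    """Radially averaged noise power spectrum.

    ``freqs`` are ring radii in cycles/pixel on (0, 0.5]; ``values`` the
    per-ring averaged power.  ``sigma2`` is the per-coefficient noise
    variance after whitening, fixed to 1 by convention.
    """

    freqs: np.ndarray
    values: np.ndarray
    sigma2: float = 1.0

    def __call__(self, s) -> np.ndarray:
        """Linear interpolation in frequency.

        Below the first ring the curve is extrapolated linearly from the
        first two rings (clamping there systematically under-whitens a
        low-frequency-peaked spectrum); the result is floored at a quarter
        of the first ring's value so it stays positive.  Above the last
        ring the value is clamped.
        """
        s = np.asarray(s, dtype=float)
        out = np.interp(s, self.freqs, self.values)
        if self.freqs.size >= 2:
            f0, f1 = self.freqs[:2]
            v0, v1 = self.values[:2]
            slope = (v1 - v0) / (f1 - f0)
            low = s < f0
            if np.any(low):
                ext = v0 + slope * (s[low] - f0)
                out = np.array(out, copy=True)
                out[low] = np.maximum(ext, 0.25 * v0)
        return out


class WhiteningError(ValueError):
    pass


def electron_wavelength(voltage_kV: float) -> float:
    """Relativistic de Broglie wavelength of the beam electrons, Angstrom."""
    if voltage_kV <= 0:
        raise ValueError("voltage must be positive")
    v = voltage_kV * 1e3
    return 12.2639 / np.sqrt(v + 0.97845e-6 * v * v)


def eval_ctf(params: CTFParams, s) -> np.ndarray:
    """Radial CTF value at frequency ``s`` (cycles/Angstrom, s >= 0)."""
    s = np.asarray(s, dtype=float)
    lam = electron_wavelength(params.voltage_kV)
    cs_A = params.cs_mm * 1e7
    chi = np.pi * lam * params.defocus_A * s ** 2 \
        - 0.5 * np.pi * cs_A * lam ** 3 * s ** 4
    w = params.amplitude_contrast
    out = -np.sqrt(1.0 - w * w) * np.sin(chi) - w * np.cos(chi)
    if params.b_factor:
        out = out * np.exp(-params.b_factor * s ** 2 / 4.0)
    return out


def ctf_weights(params: CTFParams, spec: BasisSpec) -> CTFWeights:
    """Sample the CTF at the basis frequencies.

    Index (n, k) lives at physical frequency
    ``s_{n,k} = lambda_{n,k} / (pi * L * pixel_size)`` cycles/Angstrom
    (the unit-disk radius corresponds to (L/2) * pixel_size Angstrom).
    """
    scale = 1.0 / (np.pi * spec.L * params.pixel_size_A)
    c = radial_conv_weights(lambda xi: eval_ctf(params, xi * 2.0 * np.pi * scale),
                            spec)
    return CTFWeights(c=np.asarray(c, dtype=float), group_id=params.group_id)


def weights_matrix(weights) -> np.ndarray:
    """Stack a list of :class:`CTFWeights` (or an array) into a (D, b) array."""
    if isinstance(weights, np.ndarray):
        return np.atleast_2d(weights)
    return np.stack([w.c if isinstance(w, CTFWeights) else np.asarray(w)
                     for w in weights])


def basis_freqs_per_pixel(spec: BasisSpec) -> np.ndarray:
    """Basis frequencies in cycles/pixel: lambda_{n,k} / (pi * L)."""
    return spec.roots / (np.pi * spec.L)


def _radial_freq_grid(n: int) -> np.ndarray:
    """|s| on an n x n FFT grid, cycles/pixel, fftshift-free ordering."""
    f = np.fft.fftfreq(n)
    return np.hypot(f[:, None], f[None, :])


def estimate_radial_psd(images, n_rings: int | None = None,
                        mask_radius: float | None = None) -> NoisePSD:
    """Estimate a radially symmetric noise power spectrum from images.

    The averaged periodogram (normalized so that unit-variance white noise
    has unit PSD) is sampled on concentric rings of equally spaced radii in
    (0, 0.5] cycles/pixel with 4L angular nodes per ring, and averaged over
    each ring and all images.  The periodogram is kept on the native grid —
    zero-padding would convolve the spectrum with the image window and bias
    sharply peaked spectra downward at their peak.

    If ``mask_radius`` is given (unit-disk units), pixels with r <= that
    radius are excluded so the particle signal does not contaminate the
    estimate, and the retained power is renormalized by the surviving pixel
    fraction.
    """
    from scipy.ndimage import map_coordinates

    data = np.asarray(getattr(images, "data", images), dtype=float)
    if data.ndim == 2:
        data = data[None]
    N, L, _ = data.shape
    if n_rings is None:
        n_rings = L // 2
    if n_rings < 2:
        raise ValueError("need at least two rings")
    if n_rings > L // 2:
        raise ValueError("n_rings must not exceed L/2")

    frac = 1.0
    if mask_radius is not None:
        c = L // 2
        t = (np.arange(L) - c) * (2.0 / L)
        r = np.hypot(t[None, :], t[:, None])
        keep = r > mask_radius
        frac = keep.mean()
        data = data * keep[None]

    F = fft2(data, axes=(-2, -1))
    periodogram = (np.abs(F) ** 2).mean(axis=0) / (L * L * frac)
    periodogram = np.fft.fftshift(periodogram)

    radii = 0.5 * np.arange(1, n_rings + 1) / n_rings      # cycles/pixel
    n_ang = 4 * L
    ang = 2 * np.pi * np.arange(n_ang) / n_ang
    # ring radius in FFT index units: s cycles/pixel * L pixels
    rr = radii[:, None] * L
    ci = L // 2 + rr * np.sin(ang)[None, :]
    cj = L // 2 + rr * np.cos(ang)[None, :]
    vals = map_coordinates(periodogram, np.stack([ci, cj]), order=1,
                           mode="grid-wrap")
    return NoisePSD(freqs=radii, values=vals.mean(axis=1))


def whiten(images, weights, psd: NoisePSD, spec: BasisSpec | None = None,
           pad: bool = True):
    """Whiten an image stack and the matching CTF weights.

    Images are filtered by ``psd**-1/2`` (radial Fourier multiplier applied
    on a 2x zero-padded grid to limit wrap-around) and scaled by L/2 so the
    residual noise has variance ~= 1 per basis coefficient; each CTF weight
    vector picks up the same ``(L/2) / sqrt(psd)`` factor at its basis
    frequency, which keeps the coefficient model ``y = c o x + eps`` exact
    with ``x`` still the clean-image coefficients (``spec`` supplies the
    frequency map and is required when weights are passed).  After this,
    ``sigma2 = 1`` is the noise level of the covariance model.

    With ``pad=False`` the multiplier is applied on the native L x L grid.
    For noise that is stationary on that grid (e.g. synthetically generated
    there) this whitens each Fourier mode exactly, which matters because
    percent-level errors in the residual noise variance are amplified by
    the inverse fourth power of the CTF in the covariance estimator.
    """
    if np.any(psd.values <= 0):
        raise WhiteningError("noise PSD must be strictly positive on the band")
    data = np.asarray(getattr(images, "data", images), dtype=float)
    squeeze = data.ndim == 2
    if squeeze:
        data = data[None]
    N, L, _ = data.shape

    n = 2 * L if pad else L
    s = _radial_freq_grid(n)
    H = 1.0 / np.sqrt(psd(s))
    F = fft2(data, s=(n, n), axes=(-2, -1))
    filt = ifft2(F * H[None], axes=(-2, -1)).real[:, :L, :L].copy()
    filt *= L / 2.0
    if squeeze:
        filt = filt[0]

    wlist = weights if isinstance(weights, (list, tuple)) else [weights]
    out_w = []
    if wlist:
        if spec is None:
            raise ValueError("whitening CTF weights requires the basis spec")
        gain = (L / 2.0) / np.sqrt(psd(basis_freqs_per_pixel(spec)))
        for w in wlist:
            if isinstance(w, CTFWeights):
                out_w.append(replace(w, c=w.c * gain, whitened=True))
            else:
                out_w.append(np.asarray(w) * gain)
    if not isinstance(weights, (list, tuple)):
        out_w = out_w[0] if out_w else None
    return filt, out_w


def a3_guard_minimum(weights, group_counts, spec: BasisSpec):
    """Minimum over same-block index pairs (j, l) of
    ``sum_d N_d c_{d,j}^2 c_{d,l}^2 / sum_d N_d``.

    This is the quantity that must be bounded away from zero for the
    least-squares covariance estimator to be well posed (no frequency pair
    may be annihilated by every CTF).  Returns (minimum, (n, k_j, k_l)).
    """
    W = weights_matrix(weights)
    counts = np.asarray(group_counts, dtype=float)
    ntot = counts.sum()
    best = np.inf
    arg = None
    for n in spec.n_values:
        if n < 0:
            continue
        sl = spec.block_slice(n)
        C2 = W[:, sl] ** 2
        M = (C2 * counts[:, None]).T @ C2 / ntot
        j, l = np.unravel_index(np.argmin(M), M.shape)
        if M[j, l] < best:
            best = float(M[j, l])
            arg = (int(n), int(spec.ks[sl][j]), int(spec.ks[sl][l]))
    return best, arg
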
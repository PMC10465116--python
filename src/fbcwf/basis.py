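"""Disk-harmonic (Fourier-Bessel) basis: construction, expansion, steering,
and diagonal radial convolution.

The basis functions are the Dirichlet eigenfunctions of the Laplacian on the
unit disk,

    psi_{n,k}(r, theta) = c_{n,k} * J_n(lambda_{n,k} * r) * exp(i*n*theta),

for r <= 1, where ``J_n`` is the Bessel function of the first kind of order
``n``, ``lambda_{n,k}`` its k-th positive root, and
``c_{n,k} = 1 / (sqrt(pi) * |J_{n+1}(lambda_{n,k})|)`` normalizes each
function to unit L2 norm on the disk.  The basis is orthonormal, ordered by
frequency, steerable (in-plane rotation is a diagonal phase on the
coefficients), and diagonalizes convolution with radial kernels -- the four
properties the covariance estimator relies on.

Images of side ``L`` are identified with functions on [-1, 1]^2 through the
grid map ``x = (j - L//2) * 2/L``, ``y = (i - L//2) * 2/L``; pixels outside
the inscribed unit disk are outside the support and are ignored.

The expansion is a linear least-squares fit of the truncated basis to the
pixels inside the disk.  The forward map is applied block-by-block in the
angular order ``n`` (a real Bessel factor times an angular phase), and the
normal equations are solved with a cached Cholesky factorization of the Gram
matrix, which is numerically well conditioned because the pixel-area-scaled
Gram is close to the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import jn_zeros, jv


class InvalidGridError(ValueError):
    """Raised when the requested image geometry is unusable."""


def _count_roots_below(n: int, lam_max: float) -> np.ndarray:
    """All positive roots of J_n below ``lam_max`` (ascending)."""
    # McMahon: j_{n,k} ~ (k + n/2 - 1/4) * pi, so this guess overshoots by
    # a couple of roots at most; extend if it did not.
    guess = max(int(lam_max / np.pi - n / 2) + 3, 1)
    zeros = jn_zeros(n, guess)
    while zeros[-1] <= lam_max:
        guess *= 2
        zeros = jn_zeros(n, guess)
    return zeros[zeros <= lam_max]


@dataclass
class BasisSpec:
    """Truncated disk-harmonic index set with roots and normalizers.

    Indices are ordered by angular order ``n`` ascending (negative orders
    included), then radial index ``k`` ascending, so each angular block
    occupies a contiguous slice of the coefficient vector.
    """

    L: int
    bandlimit: float
    ns: np.ndarray          # (b,) signed angular orders
    ks: np.ndarray          # (b,) radial indices, 1-based
    roots: np.ndarray       # (b,) Bessel roots lambda_{n,k}
    normalizers: np.ndarray  # (b,) c_{n,k}
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def size(self) -> int:
        return self.ns.size

    @property
    def n_max(self) -> int:
        return int(self.ns.max()) if self.size else 0

    def block_slice(self, n: int) -> slice:
        """Contiguous coefficient slice of angular order ``n``."""
        sl = self._cache.get(("slice", n))
        if sl is None:
            idx = np.flatnonzero(self.ns == n)
            if idx.size == 0:
                sl = slice(0, 0)
            else:
                sl = slice(int(idx[0]), int(idx[-1]) + 1)
            self._cache[("slice", n)] = sl
        return sl

    @property
    def n_values(self) -> np.ndarray:
        return np.unique(self.ns)

    # -- grid geometry -----------------------------------------------------

    @property
    def grid(self):
        """(x, y, r, theta) arrays of shape (L, L) in [-1, 1] coordinates."""
        g = self._cache.get("grid")
        if g is None:
            c = self.L // 2
            t = (np.arange(self.L) - c) * (2.0 / self.L)
            x = t[None, :] * np.ones((self.L, 1))
            y = t[:, None] * np.ones((1, self.L))
            r = np.hypot(x, y)
            theta = np.arctan2(y, x)
            g = (x, y, r, theta)
            self._cache["grid"] = g
        return g

    @property
    def disk_index(self) -> np.ndarray:
        """Flat indices (row-major) of pixels with r <= 1."""
        di = self._cache.get("disk_index")
        if di is None:
            _, _, r, _ = self.grid
            di = np.flatnonzero(r.ravel() <= 1.0)
            self._cache["disk_index"] = di
        return di

    @property
    def pixel_area(self) -> float:
        return (2.0 / self.L) ** 2

    def _disk_polar(self):
        p = self._cache.get("disk_polar")
        if p is None:
            _, _, r, theta = self.grid
            p = (r.ravel()[self.disk_index], theta.ravel()[self.disk_index])
            self._cache["disk_polar"] = p
        return p

    def _radius_classes(self):
        """Group disk pixels by their exact radius.

        Grid radii take only ~P/8 distinct values (squared radii are
        integers in pixel units), so Bessel factors are evaluated once per
        class and gathered per pixel.  Returns (r_class, class_id) with
        ``r_class`` the sorted distinct radii and ``class_id`` mapping each
        disk pixel to its class.
        """
        rc = self._cache.get("radius_classes")
        if rc is None:
            c = self.L // 2
            ii, jj = np.divmod(self.disk_index, self.L)
            s2 = (ii - c) ** 2 + (jj - c) ** 2
            uniq, class_id = np.unique(s2, return_inverse=True)
            r_class = np.sqrt(uniq) * (2.0 / self.L)
            rc = (r_class, class_id)
            self._cache["radius_classes"] = rc
        return rc

    def _radial_class_block(self, n_abs: int) -> np.ndarray:
        """(C, k) matrix c_{n,k} * J_n(lambda_{n,k} * r_c) on distinct radii."""
        key = ("Rc", n_abs)
        Rc = self._cache.get(key)
        if Rc is None:
            sl = self.block_slice(n_abs)
            r_class, _ = self._radius_classes()
            lam = self.roots[sl]
            Rc = jv(n_abs, r_class[:, None] * lam[None, :]) \
                * self.normalizers[sl][None, :]
            self._cache[key] = Rc
        return Rc

    def _radial_block(self, n_abs: int) -> np.ndarray:
        """(P, k) matrix c_{n,k} * J_n(lambda_{n,k} * r_p) per disk pixel."""
        _, class_id = self._radius_classes()
        return self._radial_class_block(n_abs)[class_id, :]

    def _angular_class_sum(self, d: int) -> np.ndarray:
        """Per-radius-class sum of exp(i*d*theta_p) over the class pixels."""
        key = ("S", d)
        S = self._cache.get(key)
        if S is None:
            _, theta = self._disk_polar()
            _, class_id = self._radius_classes()
            nclass = class_id.max() + 1
            if d == 0:
                S = np.bincount(class_id, minlength=nclass).astype(np.complex128)
            else:
                S = (np.bincount(class_id, weights=np.cos(d * theta),
                                 minlength=nclass)
                     + 1j * np.bincount(class_id, weights=np.sin(d * theta),
                                        minlength=nclass))
            self._cache[key] = S
        return S

    def _phase(self, n: int) -> np.ndarray:
        """exp(i*n*theta_p) on disk pixels."""
        key = ("phase", n)
        ph = self._cache.get(key)
        if ph is None:
            _, theta = self._disk_polar()
            ph = np.exp(1j * n * theta)
            self._cache[key] = ph
        return ph


@dataclass
class CoefficientSet:
    """Stack of complex coefficient vectors in a :class:`BasisSpec` ordering.

    ``data`` has shape (N, b).  For expansions of real images the
    coefficients obey the conjugate symmetry
    ``a_{-n,k} = (-1)^n * conj(a_{n,k})``; ``is_real_image`` records that
    this symmetry is meaningful for the stored stack.
    """

    data: np.ndarray
    spec: BasisSpec
    is_real_image: bool = True

    @property
    def n_images(self) -> int:
        return self.data.shape[0]

    def block(self, n: int) -> np.ndarray:
        return self.data[:, self.spec.block_slice(n)]


def _as_coeff_array(coeffs) -> np.ndarray:
    a = coeffs.data if isinstance(coeffs, CoefficientSet) else np.asarray(coeffs)
    if a.ndim == 1:
        a = a[None, :]
    return a


def compute_basis(L: int, bandlimit_factor: float = 0.9) -> BasisSpec:
    """Construct the truncated disk-harmonic basis for L x L images.

    Admits every index (n, k) whose root satisfies
    ``lambda_{n,k} <= bandlimit_factor * pi * L / 2``, a fraction of the
    grid Nyquist frequency of the [-1, 1] pixel spacing.  The default 0.9
    keeps the fastest admitted radial oscillation resolvable on the pixel
    grid (half-period >= 2.2 px).  At factor 1 the edge harmonics oscillate
    at exactly two pixels per period, their squared magnitude aliases to DC,
    and the sampled basis loses discrete orthonormality by an O(1) amount
    independent of L; below the edge the loss decays like 1/L.
    """
    if L < 4:
        raise InvalidGridError(f"image side must be >= 4 pixels, got {L}")
    if not bandlimit_factor > 0:
        raise ValueError("bandlimit_factor must be positive")
    lam_max = bandlimit_factor * np.pi * L / 2.0

    per_n: dict[int, np.ndarray] = {}
    n = 0
    while True:
        roots = _count_roots_below(n, lam_max)
        if roots.size == 0:
            break
        per_n[n] = roots
        n += 1

    ns, ks, roots_all, norms = [], [], [], []
    for n in range(-max(per_n.keys(), default=0), max(per_n.keys(), default=-1) + 1):
        r = per_n.get(abs(n))
        if r is None:
            continue
        ns.append(np.full(r.size, n, dtype=np.int64))
        ks.append(np.arange(1, r.size + 1, dtype=np.int64))
        roots_all.append(r)
        # |J_{n+1}(lam)| == |J_{|n|+1}(lam)| at a root of J_n (recurrence).
        norms.append(1.0 / (np.sqrt(np.pi) * np.abs(jv(abs(n) + 1, r))))
    if ns:
        ns = np.concatenate(ns)
        ks = np.concatenate(ks)
        roots_all = np.concatenate(roots_all)
        norms = np.concatenate(norms)
    else:  # degenerate bandlimit -> empty basis
        ns = np.empty(0, dtype=np.int64)
        ks = np.empty(0, dtype=np.int64)
        roots_all = np.empty(0)
        norms = np.empty(0)
    return BasisSpec(L=L, bandlimit=lam_max, ns=ns, ks=ks,
                     roots=roots_all, normalizers=norms)


# -- dense evaluation (reference path) -------------------------------------

def evaluate_basis(spec: BasisSpec) -> np.ndarray:
    """Dense basis images, shape (b, L, L), zero outside the unit disk."""
    out = np.zeros((spec.size, spec.L, spec.L), dtype=np.complex128)
    flat = out.reshape(spec.size, -1)
    for n in spec.n_values:
        sl = spec.block_slice(n)
        sgn = (-1.0) ** n if n < 0 else 1.0
        vals = sgn * spec._radial_block(abs(n)) * spec._phase(n)[:, None]
        flat[sl, :][:, spec.disk_index] = vals.T
    return out


# -- forward / adjoint -------------------------------------------------------

def _forward(spec: BasisSpec, coeffs: np.ndarray) -> np.ndarray:
    """Coefficients (N, b) -> complex pixel values (N, P) on disk pixels."""
    N = coeffs.shape[0]
    out = np.zeros((N, spec.disk_index.size), dtype=np.complex128)
    for n in spec.n_values:
        sl = spec.block_slice(n)
        sgn = (-1.0) ** n if n < 0 else 1.0
        W = (sgn * spec._radial_block(abs(n))) * spec._phase(n)[:, None]
        out += coeffs[:, sl] @ W.T
    return out


def _adjoint(spec: BasisSpec, pix: np.ndarray) -> np.ndarray:
    """Disk pixel values (N, P) -> adjoint coefficients (N, b)."""
    N = pix.shape[0]
    out = np.zeros((N, spec.size), dtype=np.complex128)
    for n in spec.n_values:
        sl = spec.block_slice(n)
        sgn = (-1.0) ** n if n < 0 else 1.0
        W = (sgn * spec._radial_block(abs(n))) * spec._phase(n)[:, None]
        out[:, sl] = pix @ np.conj(W)
    return out


def gram_matrix(spec: BasisSpec, scaled: bool = True) -> np.ndarray:
    """Discrete Gram matrix of the sampled basis over the disk pixels.

    With ``scaled=True`` the matrix is multiplied by the pixel area 4/L**2,
    which makes it an O(1/L) perturbation of the identity.

    Blocks whose angular orders differ by an amount not divisible by 4 are
    exactly zero: the set of interior pixels (r < 1) is invariant under 90
    degree rotation, boundary pixels contribute nothing by the Dirichlet
    condition, and the angular factor picks up exp(i*(m-n)*pi/2) under that
    rotation, forcing the sum to vanish.  Only the remaining blocks are
    computed.
    """
    b = spec.size
    G = np.zeros((b, b), dtype=np.complex128)
    nonneg = [int(n) for n in spec.n_values if n >= 0]

    def cross(Ra, Rb, d):
        """T_d(a, b) = sum_p J_a J_b e^{i d theta_p}, via radius classes."""
        S = spec._angular_class_sum(d)
        if d == 0:
            return (Ra.T @ (S.real[:, None] * Rb)).astype(np.complex128)
        return (Ra.T @ (S.real[:, None] * Rb)
                + 1j * (Ra.T @ (S.imag[:, None] * Rb)))

    def put(n, m, M):
        G[spec.block_slice(n), spec.block_slice(m)] = M
        if n != m:
            G[spec.block_slice(m), spec.block_slice(n)] = M.conj().T

    # Only orders a, b >= 0 are touched directly; the negative-order blocks
    # follow from R_{-a} = (-1)^a R_a.
    for ia, a in enumerate(nonneg):
        Ra = spec._radial_class_block(a)
        for bb in nonneg[ia:]:
            Rb = spec._radial_class_block(bb)
            if (bb - a) % 4 == 0:
                T1 = cross(Ra, Rb, bb - a)
                put(a, bb, T1)
                if a > 0 or bb > 0:
                    put(-a, -bb, ((-1.0) ** (a + bb)) * T1.conj())
            if a > 0 and bb > 0 and (bb + a) % 4 == 0:
                T2 = cross(Ra, Rb, bb + a)
                put(-a, bb, ((-1.0) ** a) * T2)
                put(a, -bb, ((-1.0) ** bb) * T2.conj())
    if scaled:
        G *= spec.pixel_area
    return G


def _gram_cho(spec: BasisSpec):
    cho = spec._cache.get("gram_cho")
    if cho is None:
        G = gram_matrix(spec, scaled=False)
        cho = cho_factor(G, lower=True, check_finite=False)
        spec._cache["gram_cho"] = cho
    return cho


# -- public operations -------------------------------------------------------

def expand(images, spec: BasisSpec, is_real_image: bool = True) -> CoefficientSet:
    """Least-squares expansion of an image stack in the truncated basis.

    ``images`` may be an (N, L, L) or (L, L) array (or an object with a
    ``data`` attribute of that shape).  Pixels outside the unit disk are
    ignored, matching the disk-supported continuous model.
    """
    data = getattr(images, "data", images)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.shape[-2:] != (spec.L, spec.L):
        raise ValueError(
            f"image shape {data.shape[-2:]} does not match basis L={spec.L}")
    pix = data.reshape(data.shape[0], -1)[:, spec.disk_index]
    rhs = _adjoint(spec, pix.astype(np.complex128))
    cho = _gram_cho(spec)
    coeffs = cho_solve(cho, rhs.T, check_finite=False).T
    return CoefficientSet(data=coeffs, spec=spec,
                          is_real_image=bool(is_real_image and np.isrealobj(data)))


def synthesize(coeffs, spec: BasisSpec) -> np.ndarray:
    """Evaluate the basis sum on the pixel grid; returns real (N, L, L) images.

    The imaginary part (zero for conjugate-symmetric coefficients up to
    roundoff) is discarded.
    """
    a = _as_coeff_array(coeffs)
    if a.shape[1] != spec.size:
        raise ValueError(
            f"coefficient length {a.shape[1]} does not match basis size {spec.size}")
    pix = _forward(spec, a.astype(np.complex128))
    out = np.zeros((a.shape[0], spec.L * spec.L))
    out[:, spec.disk_index] = pix.real
    return out.reshape(a.shape[0], spec.L, spec.L)


def steer(coeffs, angle: float):
    """Rotate images counterclockwise by ``angle`` in coefficient space.

    Applies the diagonal phase ``a_{n,k} -> exp(-i*n*angle) * a_{n,k}``.
    """
    if isinstance(coeffs, CoefficientSet):
        phase = np.exp(-1j * coeffs.spec.ns * angle)
        return replace(coeffs, data=coeffs.data * phase[None, :])
    raise TypeError("steer requires a CoefficientSet (needs the index table); "
                    "use steer_array for raw arrays")


def steer_array(data: np.ndarray, spec: BasisSpec, angle) -> np.ndarray:
    """Array form of :func:`steer`; ``angle`` may be scalar or per-image."""
    ang = np.atleast_1d(np.asarray(angle, dtype=float))
    phase = np.exp(-1j * np.outer(ang, spec.ns))
    out = np.atleast_2d(data) * phase
    return out


def radial_conv_weights(radial_profile_hat, spec: BasisSpec) -> np.ndarray:
    """Diagonal weights representing convolution with a radial kernel.

    ``radial_profile_hat`` is the kernel's Fourier transform in the
    exp(-2*pi*i*x.xi) convention, callable at any radial frequency; the
    weight for index (n, k) is its value at ``lambda_{n,k} / (2*pi)``.  Note
    these weights are not the kernel's own expansion coefficients.
    """
    return np.asarray(radial_profile_hat(spec.roots / (2.0 * np.pi)))


def apply_radial_conv(coeffs, w: np.ndarray):
    """Entrywise product of coefficients with a diagonal weight vector."""
    w = np.asarray(w)
    if isinstance(coeffs, CoefficientSet):
        if w.shape[-1] != coeffs.spec.size:
            raise ValueError("weight length does not match basis size")
        return replace(coeffs, data=coeffs.data * w)
    a = np.asarray(coeffs)
    if w.shape[-1] != a.shape[-1]:
        raise ValueError("weight length does not match coefficient length")
    return a * w


def enforce_conjugate_symmetry(data: np.ndarray, spec: BasisSpec) -> np.ndarray:
    """Project coefficients onto the real-image symmetry
    ``a_{-n,k} = (-1)^n conj(a_{n,k})`` (averaging each pair)."""
    out = np.array(np.atleast_2d(data), dtype=np.complex128, copy=True)
    for n in spec.n_values:
        if n < 0:
            continue
        sl_p = spec.block_slice(n)
        sl_m = spec.block_slice(-n)
        sgn = (-1.0) ** n
        avg = 0.5 * (out[:, sl_p] + sgn * np.conj(out[:, sl_m]))
        out[:, sl_p] = avg
        out[:, sl_m] = sgn * np.conj(avg)
    return out


def rotate90_ccw(images: np.ndarray) -> np.ndarray:
    """Exact 90-degree counterclockwise grid rotation about pixel (L//2, L//2).

    The row/column at coordinate -1 (present only for even L) has no partner
    and is zeroed; those pixels lie outside the open unit disk, so this is
    exact for disk-supported images.
    """
    imgs = np.atleast_3d(images)
    if imgs.ndim == 2:
        imgs = imgs[None]
    N, L, _ = imgs.shape
    c = L // 2
    out = np.zeros_like(imgs)
    # target pixel (i, j) at (x, y) takes source value at (y, -x):
    # src_j = i, src_i = 2c - j, valid when 0 <= 2c - j < L.
    ii, jj = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
    src_i = 2 * c - jj
    src_j = ii
    valid = (src_i >= 0) & (src_i < L)
    out[:, ii[valid], jj[valid]] = imgs[:, src_i[valid], src_j[valid]]
    return out if images.ndim == 3 else out[0]
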
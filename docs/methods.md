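# Methods

This note records the models, conventions, numerical choices, and known
limitations behind `fbcwf`.  It is the reference for anyone asking "what
exactly does this package compute, and when should I trust it?"

## Imaging model and assumptions

Each observed particle image is modeled as a clean image convolved with the
point spread function of its defocus group, plus stationary noise:

    y_i = f_{g(i)} * x_i + ε_i ,    i = 1..N,  g(i) ∈ {1..D}.

Three assumptions drive everything:

1. **Radial PSFs.**  The point spread functions (hence their Fourier
   transforms, the CTFs) are radial — no astigmatism.  Convolution is then
   a *diagonal* operation in the disk-harmonic basis.
2. **Rotation-invariant ensemble.**  The clean images are i.i.d. draws from
   a distribution invariant to in-plane rotation.  Their coefficient
   covariance is then block diagonal over angular orders, and their mean is
   purely radial (angular order 0).
3. **Joint CTF coverage (identifiability).**  For every pair of basis
   frequencies (j, l) within a block, `Σ_d N_d c_{d,j}² c_{d,l}²` must be
   bounded away from zero — some defocus group must transfer both
   frequencies.  The estimator enforces this with a guard (default
   tolerance 1e-8 relative to N) and raises an error naming the offending
   pair; a failure indicates a misconfigured CTF table, not a situation to
   be papered over by regularization.

## The disk-harmonic basis

Basis functions `psi_{n,k}(r,θ) = c_{n,k} J_n(λ_{n,k} r) e^{inθ}` on the
unit disk, Dirichlet boundary, unit L2 norm.  Pixel (i, j) of an L×L image
maps to `x = (j − ⌊L/2⌋)·2/L`, `y = (i − ⌊L/2⌋)·2/L`; the disk is
inscribed, pixels outside it are ignored.  Fourier convention
`f̂(ξ) = ∫ f(x) e^{−2πi x·ξ} dx`, so the diagonal weight of a radial kernel
at index (n, k) is its transform at radius `λ_{n,k}/2π`.

**Bandlimit.**  Indices with `λ_{n,k} ≤ bandlimit_factor · πL/2` are
admitted; the default factor is 0.9.  At factor 1 the edge harmonics
oscillate radially at exactly two pixels per period; their squared
magnitude aliases to DC and the sampled basis loses discrete orthonormality
by an L-independent O(1) amount.  At 0.9 the fastest half-period spans
≥ 2.2 px and the maximum Gram deviation decays like 1/L (measured ~1.8e-2
at L=32, ~1.1e-2 at L=64, ~3.5e-3 at L=128).  The basis size is still
Θ(L²) (≈ 0.2·L² signed coefficients).

**Expansion.**  Coefficients are the least-squares fit of the truncated
basis to the disk pixels.  The forward map is applied block-by-block (a
real Bessel factor per |n|, evaluated once per distinct pixel radius —
grid radii take only ~P/8 distinct values — times an angular phase), and
the normal equations are solved with a cached complex Cholesky
factorization of the Gram matrix.  The pixel-area-scaled Gram is within
O(1/L) of the identity, so the system is well conditioned; round-trip
(expand∘synthesize) accuracy is at solver precision (≲1e-12 relative,
asserted at 1e-6).  Gram blocks whose angular orders differ by an amount
not divisible by 4 vanish *exactly*: the interior pixel set is invariant
under 90° rotation, boundary pixels contribute nothing by the Dirichlet
condition, and the angular factor acquires `e^{i(m−n)π/2}` under that
rotation.  The implementation fills them with zeros and computes the rest
by real matrix products; correctness is verified against a dense
`A^H A` oracle in the tests.  The cost of a batch expansion is O(N·P·b)
with P ≈ πL²/4 disk pixels — direct rather than NUFFT-accelerated, which
is entirely adequate up to L=128 at the problem sizes this package
targets; a fast transform would change the constants, not the estimator.

**Steering sign.**  A counterclockwise image rotation by φ maps
`a_{n,k} → e^{−inφ} a_{n,k}` (verified against exact 90°/180° grid
rotations).

**Accuracy envelope of diagonal convolution.**  The diagonal weight
representation of radial convolution is asymptotic: the effective weight is
the kernel transform smeared over the spectral leakage of the zero-extended
basis function, of width ~1/(L·pixel_size) in physical frequency.  It is
accurate (≤1e-2 relative at L=64) when the kernel transform varies slowly
on that scale — e.g. a Gaussian of width 0.05 disk units acting on a
phantom bandlimited to a quarter of the basis band.  For CTFs the same
criterion reads: the defocus phase must advance ≪ 1 rad across 1/(L·px).
At the benchmark geometry (field of view 426 Å) this holds to ~2-5%;
for strongly oscillating CTFs (e.g. 1.5 µm defocus sampled at 2 Å/px over
a small box) the error reaches tens of percent and the diagonal model
should not be trusted near CTF extrema.

## CTF and whitening

CTF(s) = −√(1−w²)·sin χ(s) − w·cos χ(s) with
χ(s) = π λ_e z s² − (π/2) Cs λ_e³ s⁴, `z` defocus (Å), `Cs` spherical
aberration (Å), `w` amplitude contrast, λ_e the relativistic electron
wavelength (0.0197 Å at 300 kV).  An optional B-factor envelope
`exp(−B s²/4)` is off by default.  Basis index (n,k) sits at physical
frequency `λ_{n,k}/(π L pixel_size)` cycles/Å.

**Noise PSD estimation** samples the averaged periodogram on concentric
rings (radii equally spaced in (0, 0.5] cycles/pixel, 4L angles per ring,
bilinear interpolation).  The periodogram is *not* zero-padded: padding
convolves the spectrum with the image window and biases sharply peaked
spectra downward at the peak.  With particles present, the disk interior
can be masked out and the retained power renormalized by the surviving
pixel fraction; the mask convolution still distorts the estimate at the
lowest rings by a few percent.

**Whitening** filters images by psd^(−1/2) and scales by L/2, and applies
the same gain to the CTF weights at their basis frequencies.  The L/2
factor makes the per-coefficient noise variance ≈ 1 (white pixel noise of
variance v has coefficient variance 4v/L² because the scaled Gram is ≈
identity), so σ² = 1 thereafter.  Below the first PSD ring the curve is
extrapolated linearly (clamping would systematically under-whiten a
low-frequency-peaked spectrum).  Whitening of real data is applied on a 2×
zero-padded grid to limit wrap-around; for noise generated on the grid
itself (simulations) the unpadded path whitens each Fourier mode exactly,
and the synthetic benchmark uses it together with the generator's known
PSD.  This matters more than it may seem: the covariance closed form
divides by the fourth power of the CTF transfer, so a few-percent error in
the residual noise variance at weakly transferred (low) frequencies
translates into order-of-magnitude covariance bias.  With an estimated PSD
at L=32 this is the dominant error source; it is the main caveat for the
real-data pipeline at small box sizes.

## Covariance estimation

Closed forms as in the README.  Implementation notes:

- The numerator of every block is one Gram accumulation `Σ_i w_i w_i^H`
  with `w_i = c_{g(i)} ∘ (y_i − c_{g(i)} ∘ μ̂)`; the denominator
  `Σ_d N_d (c_d°²)(c_d°²)^T` is a D-row matrix product.  Total cost
  O(N·Σ_n k_n² + D·Σ_n k_n²); at N ≫ D the group count is immaterial
  (measured D=1000 vs D=10 within 1.5× at N=5000).
- **Unbiased mode** (`shrink=False`): subtract `σ²·diag(Σ_i c_i°²)` before
  the Hadamard division.  Entrywise error std is σ²/√(Σ_i c_{ij}²c_{il}²);
  this is the mode to use for consistency studies and it is what the
  recovery benchmark scores.
- **Shrinkage mode** (default): the block second moment `A/N` is
  normalized entrywise by √(mean c²) so its noise floor is exactly σ² on
  the diagonal (approximately white off it), its eigenvalues are shrunk
  with the spiked-model operator-norm rule — bulk
  (λ ≤ σ²(1+√γ)², γ = k/N) to zero, spikes debiased by
  λ → σ²((x−1−γ)+√((x−1−γ)²−4γ))/2 — and the result is mapped back and
  divided.  A final eigenvalue clip absorbs the (small) indefiniteness the
  Hadamard division can reintroduce.  Shrinkage trades consistency for
  stability: noise-dominated blocks are zeroed (their relative error
  saturates at 1), which is what the Wiener filter wants.  The normalization
  is essential — shrinking with a single scalar noise level per block lets
  noise at weakly transferred frequencies survive and be amplified by the
  division.
- Negative-order blocks are never formed; real-image conjugate symmetry
  (`a_{−n,k} = (−1)ⁿ ā_{n,k}`) defines them as conjugates.  Hermitian
  symmetrization `(S+S^H)/2` absorbs float asymmetry.
- `N_eff` for γ is N: every image contributes to every block.

**Eigenimages** merge per-block eigendecompositions, sort by eigenvalue,
and synthesize the top vectors.  For n > 0 each eigenvalue is two-fold
degenerate (shared with the conjugate block); the returned image is the
real part of the complex eigenfunction, defined up to an in-plane rotation
of its nodal pattern.

## Wiener filtering

Per image and block: `x̂ = μ̂ + ΣC (CΣC + σ²I)⁻¹ (y − Cμ̂)`, solved by
Hermitian factorization per (group, block) pair and applied to all images
of the group in batches (default 1000).  If factorization fails and σ² > 0,
a jitter of 1e-12·trace/k is added once; at σ² = 0 with a vanishing CTF
weight the system is genuinely singular and an error is raised.  Limits
worth knowing: Σ = 0 returns the mean; σ² → 0 with invertible C is exact
deconvolution; scalar blocks give the textbook Wiener gain s/(s+σ²).
Phase flipping (`y ∘ sign(c)`) is provided as the standard baseline.

## Synthetic data generator

The generator emulates the reference experimental design, and its defaults
are the benchmark conditions:

| parameter | default | meaning |
|---|---|---|
| L | 32 | image side (px) |
| n_images | 10⁴ | stack size |
| n_defocus_groups | 16 | D, round-robin assignment |
| defocus | 1–4 µm, equally spaced | one per group |
| voltage / Cs | 300 kV / 2 mm | microscope |
| amplitude_contrast | 0.07 | field-standard value |
| snr | 0.1 | disk-restricted clean-signal / noise power |
| noise PSD | ∝ 1/(1+(s/0.1)²) | Lorentzian, s in cycles/px |
| pixel_size | 0.832·512/L Å | mimics downsampling a 0.832 Å/512 map |

Templates are sums of 6–10 anisotropic Gaussian blobs (widths 0.08–0.22
disk units, centers within radius 0.55, optional exact p-fold symmetry),
normalized to unit disk power.  Ensembles draw a uniform template and a
uniform in-plane angle; rotation is exact coefficient-space steering, so
the ensemble is exactly rotation invariant and its mean and block
covariance are available in closed form from the template coefficients —
the ground truth for recovery scoring.  CTF corruption is grid-space
convolution on a 2× padded grid; colored noise is generated spectrally on
the native grid and scaled so the realized SNR matches the configuration
within ~1% at the benchmark sizes.  A direct coefficient-space sampler
(Gaussian draws from a prescribed block covariance, conjugate symmetry
enforced) supports estimator validation without any imaging steps.

What the generator does *not* emulate: real protein projections (blob
phantoms have little high-frequency structure, so high-order covariance
blocks are essentially empty and their relative errors are
noise-dominated), astigmatism, per-particle defocus variation, contrast
variation between images, motion or radiation damage, and non-radial
noise.  Passing benchmarks here demonstrates the estimator's statistical
behavior under the stated model, not end-to-end performance on micrographs.

## Benchmark design and scales

The acceptance benchmark runs at L=32 with N up to 10⁴ (basis checks at
L=64 and 128) — sizes chosen so the full suite completes on one CPU core in
a few minutes while leaving every scaling effect visible.  At SNR 0.1 with
a Lorentzian noise peak sitting exactly on the (amplitude-contrast-
suppressed) low frequencies, low-order covariance blocks are recoverable
only up to relative errors of a few units at N=10⁴; the benchmark therefore
scores the *decrease* of the per-block error from N=10³ to N=10⁴ and its
level against a fixed-seed calibration, not an absolute accuracy claim.
MSE and FRC comparisons (CWF vs phase flipping vs raw) are computed against
the known clean images of the same simulation.

## Known limitations

- Radial CTFs only; astigmatism breaks the diagonal representation.
- The diagonal convolution model degrades for fast-oscillating CTFs
  (see the accuracy envelope above).
- PSD estimation from data is biased at the lowest rings when the spectrum
  is sharply peaked; with 1/c⁴ amplification this can dominate covariance
  error at small L.  Use an externally known or jointly fitted PSD when
  available.
- Contrast-variation correction of the covariance and of denoised output
  is not implemented.
- The expansion is direct (O(L⁴) per image batch constant), not the
  O(L² log L) fast transform; irrelevant at L ≤ 128, limiting for much
  larger boxes.
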
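# fbcwf — fast steerable PCA and covariance Wiener filtering for cryo-EM images

Single-particle cryo-electron microscopy produces large stacks of very noisy
projection images, each blurred by the microscope's contrast transfer
function (CTF) — an oscillatory, radial filter whose sign flips destroy
information at its zero crossings.  Many downstream tasks (classification,
denoising, ab initio modeling) need the **2-D covariance matrix** of the
underlying clean images, estimated *through* the CTFs.  `fbcwf` implements a
fast estimator for that covariance and uses it for eigenimage PCA and
covariance Wiener filtering (CWF) — joint CTF correction and denoising.  It
is aimed at researchers in computational cryo-EM and at anyone studying PCA
of signals observed under group actions and heterogeneous linear filters.

## The method

Images of side `L` are expanded in the **disk-harmonic (Fourier–Bessel)
basis**, the Dirichlet eigenfunctions of the Laplacian on the unit disk,

```
psi_{n,k}(r, θ) = c_{n,k} J_n(λ_{n,k} r) e^{inθ},       r ≤ 1,
```

with `J_n` the Bessel function of the first kind, `λ_{n,k}` its k-th
positive root, and `c_{n,k} = 1/(√π |J_{n+1}(λ_{n,k})|)`.  The basis is
orthonormal, steerable (in-plane rotation acts as the diagonal phase
`a_{n,k} → e^{-inφ} a_{n,k}`), and diagonalizes convolution with radial
kernels: a radial PSF acts on coefficients as the entrywise product with its
Fourier transform sampled at `λ_{n,k}/2π`.  In this basis the imaging model
for an image in defocus group `d` is simply

```
y_i = c_d ∘ x_i + ε_i ,
```

where `c_d` is the CTF weight vector and `ε_i` white noise of variance `σ²`
per coefficient (unity after whitening).  Because particle orientations have
no preferred in-plane angle, the covariance `Σ` of the clean coefficients is
**block diagonal over angular orders n**, and the least-squares estimator of
each block entry has a closed form:

```
μ̂        = (Σ_i c_i ∘ y_i) ⊘ (Σ_i c_i°²)                      (n = 0 only)
Σ̂_{jl}  = Σ_i c_{ij} c_{il} (z_{ij} z̄_{il} − σ² 1{j=l})
           ───────────────────────────────────────────── ,   z_i = y_i − c_i ∘ μ̂ ,
                     Σ_i c_{ij}² c_{il}²
```

for indices `j, l` sharing one angular order.  The per-image work is a
rank-one accumulation per block, so the cost is **independent of the number
of defocus groups** — the regime where iterative conjugate-gradient
estimators become impractical.  Since the `σ²` subtraction can leave blocks
indefinite, the default estimator replaces it with spiked-model eigenvalue
shrinkage (bulk-edge truncation plus debiasing), guaranteeing positive
semidefinite blocks.  The covariance then drives the per-block Wiener filter

```
x̂ = μ̂ + Σ C_d (C_d Σ C_d + σ² I)⁻¹ (y − C_d μ̂)
```

and eigenimage PCA (block eigenvectors synthesized back to images).

## Worked example

The built-in simulator reproduces the standard synthetic benchmark:
rotation-invariant phantom ensembles, defocus groups spanning 1–4 µm at
300 kV with Cs = 2 mm, colored (Lorentzian) noise at a target SNR.

```python
import fbcwf as F
from fbcwf.pipeline import run_synthetic_study

cfg = F.SimulationConfig(L=32, n_images=2000, n_defocus_groups=8,
                         snr=0.1, seed=0)
res = run_synthetic_study(cfg, n_eval=200)
print("MSE  noisy       : %.3f" % res.mse_noisy)
print("MSE  phase-flip  : %.3f" % res.mse_phase_flip)
print("MSE  CWF         : %.3f" % res.mse_cwf)
```

prints

```
MSE  noisy       : 11.250
MSE  phase-flip  : 9.369
MSE  CWF         : 0.971
```

The clean images have unit power inside the disk, so at SNR 0.1 the raw
images carry ~11x the signal power in noise; phase flipping (multiplying by
the CTF sign) barely helps because it corrects neither amplitude nor noise,
while the covariance Wiener filter removes most of the noise energy.
`res.block_errors` holds the per-angular-order relative error of the
unbiased covariance estimate against the analytically known ensemble
covariance, and `res.frc_denoised` / `res.frc_noisy` the Fourier ring
correlations against the clean images — denoising lifts the low-frequency
rings from slightly negative (the amplitude-contrast CTF suppresses and
sign-flips low frequencies) to clearly positive.  `F.eigenimages(res.est.cov,
res.spec, 6)` returns the top principal-component images with their
eigenvalues and angular orders.

The same pipeline is scriptable from the shell:

```sh
fbcwf simulate --n-images 2000 --size 32 --groups 8 --snr 0.1 --seed 0 \
      --out-stack stack.mrcs --out-ctf ctf.csv --out-groups groups.csv
fbcwf expand stack.mrcs --ctf ctf.csv --groups groups.csv --out coeffs.npz
fbcwf estimate-mean coeffs.npz --out mean.npz
fbcwf estimate-cov  coeffs.npz --out cov.npz
fbcwf denoise coeffs.npz --mean mean.npz --cov cov.npz --out denoised.mrcs
fbcwf eigenimages cov.npz -m 6 --out eigen.mrcs
```

Stacks are MRC/MRCS files; CTF parameters and group maps are CSV;
coefficients and covariances are self-describing `.npz` containers with the
basis index table embedded.

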
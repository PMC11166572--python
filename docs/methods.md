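# Methods

## The reconstruction problem

Diffusion MRI measures, per voxel, signal attenuations S(g) along unit
gradient directions g at diffusion weighting b. In white matter the angular
profile of S carries the orientations of the axon populations crossing the
voxel. Spherical-deconvolution methods estimate the fiber orientation
distribution function (fODF) by deconvolving the measured angular profile
with a *single-fiber response kernel*. Conventional constrained spherical
deconvolution (CSD) fixes one global kernel for the whole volume, usually
estimated from the most anisotropic voxels. Where the local microstructure
is less anisotropic than that kernel, deconvolution over-sharpens and
fragments the fODF into spurious peaks (inflated NuFO, the per-voxel count
of fiber orientations); where it is more anisotropic, peaks blur and merge.

Local spherical deconvolution (LSD) removes the global-kernel assumption:
every voxel tries a bank of candidate kernels of different anisotropy and
keeps the one whose implied multi-tensor signal model best explains the
measured data under an AIC criterion.

## The LSD pipeline

Per voxel, with b0-normalized single-shell signals S(g) and noise s.d. σ:

1. **dODF.** The constant-solid-angle (CSA) estimator maps signals to a
   properly normalized diffusion ODF: fit log(−log S) in the even-order real
   spherical-harmonic (SH) basis (order ≤ lmax, default 8) with
   Laplace–Beltrami regularization λ = 0.006, then apply the Funk–Radon
   transform and spherical Laplacian order-wise
   (factor P_l(0)·(−l(l+1))/(8π); order-0 coefficient fixed to 1/(2√π) so
   the dODF integrates to 1). Signals are clamped to [1e-4, 1−1e-4] of b0
   before the double logarithm.

2. **fODF candidates.** For every candidate anisotropy ratio
   R = λ∥/λ⊥ in the bank, the dODF is deconvolved by the rotational
   harmonics of the candidate kernel's own CSA dODF (the sharpening
   deconvolution transform, SDT). Two numerical safeguards:
   * orders whose kernel harmonic magnitude falls below 1e-3 of the order-0
     harmonic contribute zero (blunt kernels carry no high-order
     information);
   * the division is solved as a regularized least-squares problem with
     iterative soft suppression of negative fODF amplitudes on a 200-point
     constraint grid (τ = 0.1 of the mean initial amplitude, λ = 1,
     ≤ 10 iterations; a voxel leaves the iteration once its active set
     stabilizes). Plain order-wise division amplifies dODF noise by
     1/r_l — a factor of several hundred at order 8 for realistic kernels —
     and is unusable at practical SNR; the nonnegativity-constrained form
     is the standard remedy in the spherical-deconvolution literature and
     is what `lsd` uses internally (the unconstrained division remains
     available as `recon.sdt_apply` / `recon.sdt_deconvolve`).

   The kernel harmonics are computed from a dense, *unregularized* fit of
   the kernel's analytic dODF. Computing them through the same regularized
   scheme fit as the data looks appealing (band-limit effects cancel) but
   silently divides out the data-side smoothing and re-amplifies noise;
   this failure mode is why the two paths are deliberately asymmetric.

3. **Multi-tensor model.** Peaks of each fODF candidate (relative threshold
   0.25, minimum separation 25°, at most 5 peaks) become compartments of a
   multi-tensor signal model: Ŝ(g) = Σᵢ fᵢ exp(−b gᵀDᵢg), all compartments
   sharing one axisymmetric eigenvalue pair (λ∥, λ⊥) with λ∥/λ⊥ = R.
   Fractions fᵢ are the peak amplitudes normalized to sum to one
   (unnormalized amplitudes would violate the constraint below). The pair
   (λ∥, λ⊥) is not fitted: it is pinned by the voxel's spherical-mean
   signal S̄ = mean_g S(g)/b0 through the closed form
   S̄ = e^{−bλ⊥}·√π·erf(√(bΔ))/(2√(bΔ)), Δ = λ∥−λ⊥, inverted by bisection
   on λ⊥ ∈ [1e-6, 4e-3] mm²/s (tolerance 1e-12; erf(x)/x series-expanded
   for bΔ < 1e-9). The spherical mean is orientation- and
   dispersion-invariant and closed under shared-eigenvalue mixtures, which
   is what makes this constraint transfer from the single-tensor formula to
   the mixture. Because the kernel eigenvalues are voxel-specific, the SDT
   kernel in step 2 uses the same constraint-derived pair — the ratio bank
   parametrizes kernel *shape*; the spherical mean fixes its *scale*.

4. **Selection.** Candidate quality is the Gaussian log-likelihood
   ln L = Σ_g [−ln(σ√(2π)) − ½((Ŝ−S)/σ)²], penalized as
   AIC = 2k − 2 ln L with k = 3·NuFO (three parameters per orientation).
   Per candidate, the AIC map is smoothed spatially (Gaussian, σ = 0.5
   voxels, mask-aware normalized convolution so unscored and out-of-mask
   voxels do not bleed in) or, in `patch3x3x3` mode, pooled over the 3×3×3
   neighborhood. The argmin candidate per voxel wins; ties go to the lowest
   ratio (parsimony). Voxels where no candidate produces any peak get
   NuFO 0 and an isotropic fODF.

Synthetic experiment datasets are reconstructed with smoothing disabled:
their voxels are independent draws arranged arbitrarily, so spatial AIC
pooling across them would be meaningless.

## Reference CSD baseline

The comparison baseline is constrained spherical deconvolution with a
single global response: iterative single-fiber response estimation
(initialize from tensor-fit principal directions, run CSD, rank voxels by
the second-to-first fODF lobe amplitude ratio read off a dense grid, keep
the best 300, re-estimate the axisymmetric m=0 response in each voxel's
peak-aligned frame, repeat ≤ 10 times or until the selection stabilizes),
then CSD with iterative soft nonnegativity (τ = 0.1, λ = 1, ≤ 50
iterations, 300-point constraint grid). Both the constrained SDT and CSD
share one active-set solver; a voxel leaves the iteration as soon as its
constraint set stops changing.

## Synthetic data generator

The generator reproduces the validation designs used to characterize LSD:

* **Voxel model.** Ground-truth fODFs are symmetrized von Mises–Fisher
  (vMF) mixtures: f(v) = meanᵢ ½[vMF(v; µᵢ, κ) + vMF(v; −µᵢ, κ)].
  Diffusion kernels are axisymmetric tensors parametrized by mean
  diffusivity MD and ratio R (λ∥ = 3·MD·R/(R+2), λ⊥ = 3·MD/(R+2)).
* **Convolution.** Discrete: the kernel is rotated to each vertex of a
  near-uniform 724-point spherical grid (spherical Fibonacci points with
  convex-hull adjacency; any near-uniform grid of this size is equivalent —
  vertex placement perturbs the discrete convolution only below the 1e-3
  level, per the grid-refinement test) and
  the per-vertex tensor signals are averaged with the fODF values as
  weights; signals normalize to 1 at b = 0. The weights are the raw vMF
  densities at the vertices, not a band-limited SH resampling: fODF
  sharpness must not be silently truncated at the reconstruction band limit
  (an lmax-8 resampling widens a κ=128 lobe enough to drop the effective
  kernel ratio from 3 to ≈2).
* **Noise.** Additive i.i.d. Gaussian with s.d. σ on the b0-normalized
  signal; SNR ≡ 1/σ. No Rician floor is modeled.
* **Seeding.** Every (geometry, replicate) pair draws its rotation and its
  noise from `SeedSequence([master_seed, geometry_id, replicate])`, so any
  voxel is reproducible in isolation.
* **Designs.**
  - *direction sweep*: 60° and 90° crossings (κ = 24), kernel MD 1e-3
    mm²/s R = 3, b = 1000 s/mm², n = 28:2:200 electrostatic directions,
    σ(n) chosen so √n/σ is constant with SNR 100 at n = 55; SH order 6.
  - *2peaks-manyK*: crossing angles 30–90° (13, linear) × κ 8–24 (5,
    log-linear) = 65 fODF shapes; MD 0.6–1.2e-3 (6, linear) × R 1.5–8
    (5, squares of a linear grid in √R) = 30 kernels; 1,950 voxel
    geometries; n = 60, b = 1500 s/mm²; SNR 10:10:100; random 3D rotation
    per voxel. The per-axis factorizations 13×5 and 6×5 are inferred; the
    published totals (65, 30, 1,950) are the binding constraints, and the
    median of the R grid (4.107) and of the MD grid (0.9e-3) exactly match
    the single kernel quoted for the companion design, corroborating the
    factorization.
  - *2peaks-oneK*: same shape ranges sampled at 39×5 = 195 shapes, single
    kernel MD 0.9e-3, R 4.107 (computed as the manyK medians, not
    hard-coded); SNR 10:10:100.
  - Each two-peak design has a single-peak *companion* (same κ and kernel
    grids) for CSD response estimation.

  Replicate counts default to the published values (1,000 or 100); tests
  and the acceptance script pass smaller counts through the same
  parameters. The kernel-ratio bank for simulations is 16 log-spaced
  candidates in [1.1, 10] (log spacing matches the multiplicative character
  of anisotropy; the count is a package choice — the published range is
  fixed but not its granularity). For measured data the default bank is 20
  log-spaced candidates in [1.1, 6].

### What the generator does and does not emulate

It emulates orientation dispersion, kernel heterogeneity, crossing
geometry, angular sampling and Gaussian thermal noise. It does not emulate
Rician/noncentral-χ noise statistics, spatial correlation of anatomy or
noise, partial-volume mixtures with CSF/gray matter, per-compartment
eigenvalue differences, or multi-shell acquisitions. Passing tests
therefore certify the estimator's behavior under the stated voxel model,
not its robustness to everything real tissue does.

## Evaluation metrics

* **NuFO error**: estimated minus true peak count.
* **Angular error**: over all injective assignments between the smaller
  peak set and the larger, the assignment minimizing the mean of per-pair
  angles (folded to [0°, 90°]); an empty estimate scores 90°. The summed
  variant is stored alongside. Mismatched counts carry no angular penalty —
  the NuFO error reports them separately.
* **Success / STAR**: success = exact NuFO and mean angular error < 5°;
  STAR is the percentage of successes per (method, SNR, crossing-angle)
  cell, reported only for cells with ≥ 20 attempts; method differences are
  percentage points. Success is deliberately bound to the *mean* angular
  error: binding it to the sum makes two-peak success require ~2.5° per
  peak and collapses STAR far below any published operating range.
* **Test–retest**: per-voxel coefficient of variation (sample s.d. over
  mean, n−1 convention) of scalar outputs across two runs, and angles
  between matched primary (and, where both runs report NuFO ≥ 2,
  secondary) orientations.

## Numerical choices

* SH basis: real, even-order, orthonormal; within order l, m runs −l…l
  with negative m on the sine terms; evaluated by a vectorized normalized
  Legendre recurrence. MRtrix-dialect coefficients differ by (−1)^m
  (converters provided).
* Peak extraction: discrete maxima on the 724 grid (~6.4° mean spacing) are
  refined by finite-difference Newton steps on the analytic SH surface in a
  local tangent frame (4 coarse steps h = 0.01 rad, then 2 fine steps
  h = 0.001; steps clipped to 0.15 rad, gradient-ascent fallback when the
  Hessian is not negative definite). Maxima below half the relative
  threshold are not refined (they cannot survive selection). Orientations
  report on the z ≥ 0 hemisphere (ties toward +y, then +x).
* Electrostatic schemes: L-BFGS minimization of the antipodally
  symmetrized 1/r energy from 10 seeded restarts; deterministic per seed.
* AIC ties: lowest ratio wins. Candidates with more than 5 peaks keep the
  5 largest (bounds k; matches the observed dynamic range of up to five
  orientations per voxel).
* Degenerate inputs: noisy spherical means outside the attainable range are
  clamped to it inside the pipeline (the public constraint inverter raises
  instead); all-zero signals and non-positive σ raise.

## Known limitations

* Under the direction-sweep noise design (√n/σ held constant), the
  per-coefficient noise level is independent of n, so this implementation's
  mean angular error is essentially flat in the number of directions
  (≈2.3° at 90°, ≈3.5–4.5° at 60°) rather than decreasing; the regularized
  fit shows no low-n breakdown (the 28-direction electrostatic scheme at
  SH order 6 is well conditioned), and the log(−log) noise bias grows with
  per-direction σ, slightly penalizing large n. Comparisons across n under
  this design should therefore be read as "no worse", not "better".
* LSD's selected ratio compensates *all* angular blur, including fODF
  dispersion: for a dispersed single fiber (κ = 24) the modal selected
  ratio sits one to two bank steps below the generating kernel's R. Exact
  ratio recovery holds only for near-parallel fibers (κ ≳ 128), which is
  what the homogeneous recovery fixtures use.
* Angular accuracy at lmax 8 with κ = 24 dispersion carries a ~2°
  systematic floor from lobe width and lobe interaction; STAR values
  saturate accordingly.
* The CSD response estimator needs the companion volume to be several times
  larger than the 300-voxel selection to actually select; on smaller
  volumes it degenerates to an all-voxel average (a warning is logged when
  the iteration does not converge).
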
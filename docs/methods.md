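# Methods

## The reconstruction problem

Arterial spin labeling (ASL) perfusion MRI measures cerebral blood flow (CBF)
from the difference between control and label images. The perfusion signal is
only ~1% of the static tissue signal, so acquisitions use large voxels
(~4 mm), many control–label (C–L) repeats, and 3D-GRASE readouts whose
T2 decay blurs the partition (through-plane) direction. Large voxels and blur
mix gray-matter (GM) and white-matter (WM) signal (partial-volume effects),
and motion between repeats degrades the average.

`mocha_asl` reconstructs a single high-resolution perfusion-weighted image
x ∈ C^Nh directly from the multi-coil k-space of all pairs by inverting an
explicit acquisition model:

    x̂ = argmin_x  w/(2 Np) Σ_i ‖E T_i B x − d_i‖² + β R(x)

where, per pair i:

* d_i — control-minus-label multi-coil k-space (Nm samples × L coils);
* B — separable Lorentzian point-spread-function blur on the high-res grid
  (through-plane GRASE blur), zero-padded boundaries, kernel truncated at
  ±8 voxels and renormalized to unit sum;
* M_i (inside T_i) — rigid transform to the i-th motion state, trilinear
  interpolation about the grid center; its adjoint is the transpose of the
  interpolation matrix, not resampling along the inverse transform;
* D (inside T_i) — block-average downsampling to the acquisition grid
  (voxel-integration model; trailing-edge crop if shapes do not divide);
* C — diagonal coil-sensitivity modulation;
* F — unitary, centered 3D DFT; Φ — Cartesian undersampling mask whose
  adjoint zero-fills (Φ'Φ is a 0/1 diagonal);
* B0 distortion and the noise-covariance weighting are identity.

Every operator satisfies the adjoint dot-product identity to round-off; the
whole chain is verified against independently assembled dense/brute-force
oracles in the test suite.

### Data-fidelity weight

The operators are unitary internally, but the objective weights the data term
by w = Nl (the number of low-res k-space samples). Equivalently, squared
residuals are counted in unnormalized-DFT energy, the convention of the
MATLAB-style reconstruction pipelines in which the reference regularization
weight β = 20 was calibrated. Measured on this package's phantom, β = 20
under a unitary-energy data term over-regularizes by roughly four orders of
magnitude, while with w = Nl the whole-brain NRMSE optimum of a β sweep over
{0, 2, 20, 200, 2000} falls exactly at β = 20. Both the data term and the
penalty are homogeneous of degree 2 in the image intensity scale, so β does
not depend on arbitrary intensity units.

## Anatomical prior

    R(x) = Σ_j Σ_{b∈N_j} ω_jb ξ_jb |x_j − x_b|²

with N_j a 3×3×3 neighborhood (26 offsets), each ordered pair counted once
(each undirected edge twice), and

    ω_jb = 1/(√(2π) σ) · exp(−(v_j − v_b)² / 2σ²),   σ = 0.15,

computed from the anatomical image v rescaled to [0, 1] by its 99.5th
percentile (σ only has meaning on a normalized intensity scale). Proximity
coefficients are inverse Euclidean distance in mm, normalized so the nearest
neighbor has ξ = 1. Out-of-bounds neighbors get weight zero. For complex x
the penalty acts on real and imaginary parts independently (|·|² is the
complex modulus), so R stays real, convex and quadratic. Weights are computed
once from v and frozen across iterations. The gradient is
∂R/∂x_j = 2 Σ_b (w_jb + w_bj)(x_j − x_b) with w = ωξ; applied to a direction
it is also the prior Hessian action.

## Solver

Steepest descent with exact line search on the convex quadratic objective:
α_k = g'g / g'Hg, with H applied matrix-free (forward + adjoint per pair plus
the prior Hessian). Initialization is the zero image; the iteration count is
fixed at 100 (an optional relative-gradient-norm early stop is off by
default). Because the line search is exact, the objective trace is monotone
non-increasing; the trace is computed at every iteration from the maintained
gradient state via the exact identity f(x) = ½ Re⟨x, g⟩ − ½ Re⟨b, x⟩ + c0
(g = Hx − b), and the gradient is recomputed from scratch every 20 iterations
to keep the recurrence drift-free. On tiny instances the 100-iteration (or
tolerance-stopped) solution matches a dense normal-equations solve to
< 1e-6 relative error.

With a fixed iteration budget the iterate is an implicitly regularized
approximation of the minimizer — the same protocol as the reference study,
and part of what β = 20 means in practice.

The M0 calibration volume is reconstructed by the identical machinery with a
single data term and identity motion. CBF then takes the magnitude of both
reconstructions (a real-part option exists).

## Baselines

* **Standard reconstruction** — per-image zero-filled inverse FFT, coil
  combination by conjugate-map weighted sum normalized by RSS² (plain IFFT
  for one uniform coil), rigid motion correction of every control and label
  image by resampling along the inverse transform, pairwise subtraction and
  averaging.
* **Coil maps** — estimated by dividing each coil image by the
  root-sum-of-squares image; zero where the RSS is negligible. The synthetic
  coil maps are RSS-normalized, so this estimator reproduces them exactly in
  the noiseless limit.
* **Lucy–Richardson deconvolution** — multiplicative updates
  u ← u · K'(img / K u) with the same separable Lorentzian kernel; boundary
  handling is configurable (periodic conserves total intensity; zero-padded
  matches the common direct-convolution implementations).
* **3D linear regression PVC (3DLR)** — per voxel, least squares over a
  5×5×5 kernel of r_k ≈ pGM_k·fGM + pWM_k·fWM on the xP/xM0 ratio, kernels
  clipped at volume edges. The two-parameter fit is used where the 2×2 normal
  matrix has condition number < 1e6; otherwise a single-tissue fit; a tissue
  map is NaN where the voxel's own PV fraction ≤ 0.05. Outputs are converted
  to CBF units by the quantification scale factor, and a combined map
  pGM·fGM + pWM·fWM is also produced.

## Quantification

Single-PLD pCASL consensus model:

    CBF = 6000 λ x_P exp(PLD/T1b) / (2 α T1b[s] x_M0 (1 − exp(−τ/T1b)))

with λ = 0.9 mL/g, τ = 1500 ms, PLD = 1800 ms, T1b = 1650 ms, α = 0.85.
Exponent ratios are unitless (ms/ms); the standalone T1b is converted to
seconds, which the 6000 (mL/g/s → mL/100g/min) factor assumes — with T1b in
ms the GM perfusion fraction would come out ~6.8 instead of the physical
~0.7%. CBF is masked to zero where x_M0 ≤ 10% of its 99th percentile.
The label-image generator inverts the same formula exactly, so
quantify ∘ invert round-trips to 1e-10.

NRMSE over an ROI is 100·√(Σ(x−x_GT)² / Σx_GT²).

PSF width estimation: repeated C–L difference volumes are mean-subtracted per
voxel; the 1D autocorrelation of the residuals along the superior–inferior
axis is averaged over measurements and both in-plane positions, normalized at
lag 0 and least-squares fitted (lags 0–10, bounded 1D minimization) with the
discrete autocorrelation of a sampled Lorentzian kernel. Note that averaging
the residuals themselves across measurements would be identically zero, so
the autocorrelations are what is averaged. Boundary truncation gives the
estimator a small negative bias (~5% at FWHM 1.5 on 29-slice volumes);
recovery is well within 20% on every tested seed.

## Synthetic data generator

The phantom emulates the validation protocol of an anatomically guided ASL
reconstruction study at desk scale:

* **Geometry** (procedural; real NIfTI PV maps are accepted as drop-ins):
  ellipsoidal WM core, cortical GM ribbon of 2–4 voxel thickness with a
  smooth random radial perturbation emulating folding, CSF shell and
  ventricles, five deep-GM nuclei (thalamus, caudate, putamen, pallidum,
  hippocampus analogs). PV fractions are lightly smoothed indicators
  (σ = 0.8 voxel), so boundary voxels genuinely mix tissues.
* **Ground truth**: CBF = 65·pGM + 20·pWM mL/100g/min; a spherical 1.34-mL
  WM lesion set to 100; GM hyper-/hypo-perfusion patches rescaled to ROI
  means 78.9 and 36.6. None of the three is visible in the T1w-like guidance
  image — the anatomy/perfusion mismatch the study probes.
* **Signals**: M0 = 100·(pGM + 0.65·pWM + 1.30·pCSF) a.u.; the ASL readout
  uses background suppression, so the static tissue in control/label is
  reduced to bs_factor = 0.1 of M0 (typical residual after two inversion
  pulses); the label image is the exact algebraic inversion of the CBF
  formula, so quantification round-trips on every dataset.
* **Acquisition chain** (per §-order of the emulated protocol): rigid motion
  (linear ramp from identity to 3° / 15 mm over 20 pairs, axis and direction
  drawn once per seed), block-average downsampling to 4-mm voxels, 6-mm FWHM
  Lorentzian blur along the partition axis on the acquisition grid,
  modulation by smooth RSS-normalized birdcage-style coil maps, centered
  unitary FFT, optional phase-encode undersampling, and circular complex
  Gaussian noise at 15 dB, defined as
  10·log10(mean |noiseless k|² per sampled complex sample / noise variance),
  pooled over all control and label samples; the M0 scan (no background
  suppression) receives the same absolute noise variance.
* **Deliberate model mismatch**: the simulator blurs after downsampling (as
  echo-train decay does, in the acquisition frame), while the reconstruction
  model applies the equivalent blur as the front-end operator on the
  high-resolution grid before motion — the model approximates, not inverts,
  the generator.
* The dataset's acquisition model carries the true motion schedule (exact
  motion estimation by construction; transforms can be perturbed to emulate
  estimation error) and the true coil maps.

What the phantom does **not** emulate: real cortical topology, vascular
transit-time or arterial signal, pulse-sequence physics beyond the net
Lorentzian PSF, B0 distortion, within-pair motion, motion-estimation error.
Passing tests therefore demonstrate correctness of the operators, solver and
study logic under realistic noise/motion/blur — not clinical performance.

## Problem sizes and runtimes

The default study grid is 64³ at 2 mm (high-res) with factor-2 downsampling
to 4-mm acquisition voxels — the in vivo acquisition voxel of the emulated
protocol, with a coarser anatomical grid (ratio Nh/Nl = 8 vs ≈ 88 in the
reference study), chosen so a full 100-iteration reconstruction of 20 pairs
takes ~90 s on one CPU. Operator/solver unit tests run on ≤ 16³ grids in
seconds.

## Known limitations

* At the factor-2 desk scale the standard reconstruction is already close to
  the evaluation grid, so the model-based method's voxel-level NRMSE beats it
  in 10 of 11 regions but narrowly loses in bulk WM (≈32 vs ≈31%), where the
  reconstruction carries a genuine ~+15% GM→WM partial-volume leakage (the
  reference behavior at full scale is the same sign, ~+10%).
* The simulated lesion bias of the model-based method (≈ −32 to −38%
  depending on the noise seed) is slightly larger in magnitude than the
  reference −29%, because at 2-mm resolution a 1.34-mL sphere has
  proportionally more boundary voxels exposed to smoothing.
* β transfers across datasets only together with the stated data-energy
  convention and iteration budget.
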
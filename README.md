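# mocha-asl

Model-based, motion-corrected, anatomically guided reconstruction of arterial
spin labeling (ASL) perfusion MRI, with CBF quantification and the classical
baselines it is compared against.

ASL measures cerebral blood flow (CBF) from control-minus-label image
differences that carry only ~1% of the static tissue signal. Practical
acquisitions therefore use large voxels (~4 mm), through-plane-blurred 3D
readouts and many repeats — which mixes gray- and white-matter signal
(partial-volume effects) and accumulates inter-repeat motion. This package is
for MR-physics and image-reconstruction researchers who want a compact,
fully tested reference implementation of the model-based alternative: instead
of averaging low-resolution difference images, reconstruct one
high-resolution perfusion-weighted image x directly from all multi-coil
k-space pairs,

    x̂ = argmin_x  w/(2Np) Σᵢ ‖(I_L ⊗ ΦF) C D Mᵢ B x − dᵢ‖²  +  β R(x)

where B is the Lorentzian point-spread blur, Mᵢ the rigid motion of pair i,
D block-average downsampling to the acquisition grid, C coil sensitivities,
ΦF the (under)sampled Fourier transform, and

    R(x) = Σⱼ Σ_{b∈Nⱼ} ω_jb ξ_jb (x_j − x_b)²,
    ω_jb = exp(−(v_j − v_b)²/2σ²) / (√(2π)σ)

an anatomically weighted quadratic penalty computed from a high-resolution
structural image v: voxel pairs that look alike anatomically are smoothed
together, boundaries are preserved. The objective is convex quadratic and is
minimized by steepest descent with exact line search (monotone by
construction). CBF is obtained with the single-PLD pCASL consensus model from
the reconstructed perfusion and M0 volumes.

Included besides the model-based method ("mocha"):

* standard reconstruction (zero-filled inverse FFT, coil combination, rigid
  motion correction, subtract + average), with optional Lucy–Richardson
  deconvolution;
* 3D linear-regression partial-volume correction (3DLR, 5×5×5 kernel);
* RSS coil-map estimation, PSF-width estimation from residual
  autocorrelation, NRMSE/ROI reporting;
* a procedural brain phantom and end-to-end k-space simulator (tissue CBF
  65/20 mL/100g/min, 1.34-mL WM lesion at 100, hyper-/hypo-perfused GM
  mismatch regions, 6-mm partition blur, 4-mm acquisition voxels, 20 pairs at
  15 dB k-space SNR, incremental 3°/15 mm motion) with exact ground truth.

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

Simulate the default phantom study and compare the three methods (~3 minutes
on one CPU):

```python
import mocha_asl as m

cfg = m.StudyConfig(phantom=m.PhantomSpec(seed=1))   # β=20, σ=0.15, 100 iterations
res = m.run_study(cfg)
t = res["table"]
print(t[t.region.isin(["wm", "cortical_gm", "lesion"])]
        [["method", "region", "mean", "gt_mean", "bias_pct", "nrmse_pct"]]
        .to_string(index=False))
```

prints

```
  method      region      mean    gt_mean   bias_pct  nrmse_pct
standard          wm 28.564610  23.025091  24.058620  32.438861
standard cortical_gm 38.590315  53.076339 -27.292810  29.318240
standard      lesion 55.909183 100.000000 -44.090817  44.819516
    3dlr          wm 25.803071  23.025091  12.065012  26.196630
    3dlr cortical_gm 52.108970  53.076339  -1.822600  14.481787
    3dlr      lesion 36.661743 100.000000 -63.338257  63.371821
   mocha          wm 27.041363  23.025091  17.443024  32.737118
   mocha cortical_gm 45.973358  53.076339 -13.382576  18.283656
   mocha      lesion 67.691438 100.000000 -32.308562  34.713605
```

All values are in mL/100 g/min; `bias_pct` is the percent error of the
ROI-mean against the ground truth and `nrmse_pct` the voxel-level normalized
RMS error, both evaluated on the high-resolution grid. The lesion is a
100 mL/100g/min hyperperfused sphere placed in white matter with **no**
counterpart in the anatomical image. The standard 4-mm reconstruction
underestimates its mean CBF by 44%; 3DLR makes it worse (−63%) because the
local PV regression smooths the anatomically invisible lesion into the
surrounding WM; the model-based reconstruction recovers most of it (−32%)
while also halving the cortical-GM bias of the standard method.

The regularization-weight sweep reproduces the characteristic trade-off —
whole-brain error is minimized at β = 20 while lesion error grows with β:

```python
sweep = m.beta_sweep(cfg, [0, 2, 20, 200, 2000])
print(sweep.pivot_table(index="beta", columns="region", values="nrmse_pct")
           [["whole_brain", "lesion"]].round(1).to_string())
```

```
region  whole_brain  lesion
beta
0             293.7    99.9
2              45.9    27.9
20             22.9    34.7
200            39.9    52.6
2000           61.8    69.7
```

A command-line interface mirrors the library (`mocha simulate`, `mocha
recon`, `mocha quantify`, `mocha sweep`, `mocha evaluate`); volumes are
NIfTI-1, k-space archives are `.npz`, transforms are JSON, tables are CSV.

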
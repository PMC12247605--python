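# dkiprep

Preprocessing and tensor estimation for clinical multi-shell diffusion MRI
(dMRI), aimed at DTI/DKI studies where thermal noise, the Rician noise
floor, and Gibbs ringing from partial-Fourier acquisitions corrupt the
parameter maps that downstream statistics depend on.

The package implements, as composable library functions and a thin CLI:

* **MPPCA denoising** — each voxel's signals across diffusion volumes are
  stacked with neighbouring voxels into a Casorati matrix; the singular
  spectrum is split into signal components and a Marchenko–Pastur noise
  bulk, giving a per-voxel noise map σ and component count P.  Patches are
  either a local box or an *adaptive* selection of the 100 voxels in a
  search window most similar to the centre voxel (bilateral score on
  spatial distance and signal difference).  Noise components are discarded
  outright or all singular values are passed through the optimal
  Frobenius-loss shrinker
  `s → σ√M · √((y²−β−1)²−4β)/y`, `y = s/(σ√M)`, `β = N/M`.
* **Rician bias correction** — method of moments,
  `Ŝ = sqrt(max(M² − σ², 0))`, with σ from the MPPCA noise map.
* **Gibbs unringing** — subvoxel-shift (SuShi) re-interpolation at the
  shift minimising local total variation, with complementary spectral
  filters for the two in-plane axes; for 6/8 and 7/8 partial-Fourier data
  an extra pass (RPG) resamples along the phase-encode axis so the
  zero-fill ringing (period `2/(2·pf−1)` voxels) acquires the 2-voxel
  period the shift search assumes.
* **WLLS DTI/DKI fitting** — two-pass weighted linear least squares on
  `ln S = ln S0 − b D(n) + (b²/6) MD²·W(n)`, second pass weighted by the
  squared predicted signal; scalar maps MD/AD/RD/FA (µm²/ms,
  dimensionless) and MK/AK/RK (directional averages of the apparent
  kurtosis `K(n) = MD²·W(n)/D(n)²`).
* **Physical-bounds outlier statistic** — percent of ROI voxels with
  D ≤ 0, FA outside (0, 1), or K ≤ −2, per map and averaged over the
  seven maps.
* **Ground-truth simulators** — a multi-shell brain phantom (CSF, cortex,
  four white-matter tract orientations with spatially correlated
  heterogeneity; exact DKI forward signals; Rician noise
  `Sm = sqrt((Sr+σϵ₁)² + (σϵ₂)²)` at SNR defined on the mean WM b0) and a
  Shepp-Logan-style slice with k-space truncation plus zero-filled 6/8
  partial Fourier for Gibbs experiments.
* **Evaluation harness** — median-percentage-error maps against ground
  truth (median over noise realizations, then over an ROI), outlier
  percentages, the CSF-excluded Gaussian-smoothing comparator
  (FWHM = 1.2 × voxel), and a quadratic age-association fitter
  (adjusted R², F-test p, ×28 Bonferroni, concavity/inflection age).
* **Pipeline orchestration** — canonical step order
  denoise → degibbs → (external EPI/eddy/motion hook) → b0 normalization
  → Rician correction → fit, with presets `none`, `em`, `em-smooth`,
  `dv1` (local patch + SuShi), `dv2` (adaptive patch + shrinkage + RPG)
  and a JSON provenance report.

External distortion/eddy/motion correction is *not* re-implemented; the
pipeline exposes a hook where such tools run.

## Worked example

```python
import numpy as np
from dkiprep import phantom, mppca, dki

truth = phantom.make_multishell_phantom((32, 32, 8), seed=0)
noise = phantom.NoiseModel.from_truth(truth, snr=20, seed=1)
noisy = phantom.add_rician_noise(truth.truth, noise)

res = mppca.denoise_volume(noisy, mppca.PatchSpec(mode="adaptive"), shrink=True)
corrected = noisy.with_data(mppca.rician_bias_correct(res.denoised, res.sigma_map))

maps = dki.scalar_maps(dki.wlls_fit(corrected))
maps_raw = dki.scalar_maps(dki.wlls_fit(noisy))
tm = phantom.truth_scalar_maps(truth)
wm = truth.wm_mask

print(f"noise sigma: true {noise.sigma:.4f}, estimated {np.median(res.sigma_map[wm]):.4f}")
```

prints, with the rest of the comparison:

```
noise sigma: true 0.0508, estimated 0.0486
retained components P (median in WM): 7
MD  median % error in WM: +0.01 (noisy) -> -0.10 (denoised)
FA  median % error in WM: +1.37 (noisy) -> -1.20 (denoised)
MK  median % error in WM: -4.79 (noisy) -> +1.04 (denoised)
outlier %: 0.444 (noisy) -> 0.072 (denoised)
```

The MP noise map recovers the generative σ to a few percent; denoising
collapses the large noise bias of the kurtosis scalars (MK here from −4.8%
to +1%) and cuts the physically-implausible-voxel rate by roughly an order
of magnitude, at the price of a small opposite-direction bias in FA from
eigenvalue shrinkage — the trade-off the shrinkage flag controls.

The same steps are available from a shell:

```sh
dkiprep phantom multishell --snr 20 --nreps 1 --seed 1 --grid 32,32,8 -o ph/
dkiprep denoise ph/noisy_snr20_rep0.nii.gz ph/truth.bval ph/truth.bvec \
        --mode adaptive --shrinkage --rician -o den.nii.gz --sigma-out sigma.nii.gz
dkiprep fit den.nii.gz ph/truth.bval ph/truth.bvec -o maps/
dkiprep benchmark gibbs --pf 0.75 --out gibbs.csv
```

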
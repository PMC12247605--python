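# Methods

This note documents the models, estimators and numerical choices behind
`dkiprep`, what the bundled simulators do and do not emulate, and the
problem sizes the test suite and `scripts/acceptance.py` run at.

## Signal model and fitting

The diffusion kurtosis signal model is

    ln S(b, n) = ln S0 − b·D(n) + (b²/6)·V(n),
    D(n) = Σᵢⱼ nᵢnⱼ Dᵢⱼ,     V(n) = Σᵢⱼₖₗ nᵢnⱼnₖnₗ Vᵢⱼₖₗ,

with b internally in ms/µm² (converted from s/mm² at I/O) so diffusivities
emerge in µm²/ms.  The 15 kurtosis coefficients carry the conventional
MD²·W scaling, so the apparent kurtosis along n is K(n) = V(n)/D(n)² and
phantom truth and fitted coefficients live on the same scale.  Tensor
coefficient order is (xx, xy, xz, yy, yz, zz) and the 15 quartic
monomials in lexicographic order, with symmetric multiplicities folded
into the design matrix (n_volumes × 22; rank 22 for the default
acquisition scheme).

Fitting is two-pass weighted linear least squares on log-signals: an
unweighted pass predicts the signals, the second pass weights each row by
the squared predicted signal.  Non-positive measurements are clamped to
1e-8 of the voxel's maximum before the log and flagged; no positivity
constraints and no outlier rejection are applied during fitting — voxels
outside physical bounds (D > 0, 0 < FA < 1, K > −2; no upper diffusivity
bound) are the subject of the outlier statistic, not of the fit.

Scalars: eigenvalues sorted descending; MD/AD/RD and FA by the standard
closed forms; AK analytically along the principal axis; RK as the mean of
K(n) over 64 equally spaced directions in the radial plane; MK as the
mean over a 256-point Fibonacci sphere.  The directional averages agree
with the isotropic closed form to better than 1e-3, which is the
documented tolerance for MK; exactness was preferred over analytic
closed-form MK because the directional average is trivially correct for
any tensor pair and is testable against the isotropic case.

## MPPCA denoising

For a patch of M voxels and N volumes (matrix oriented so M ≥ N), the
eigenvalues λ₁ ≥ … ≥ λ_N of XᵀX/M are scanned for the smallest P whose
trailing block is Marchenko–Pastur consistent: σ̂² is the mean of the
trailing N−P eigenvalues and λ_{P+1} must lie below σ̂²(1+√((N−P)/M))².
Hard truncation keeps the top P singular values; the shrinkage variant
maps every singular value through the optimal Frobenius-loss shrinker
(zero inside the MP bulk).  A noiseless matrix (σ̂ = 0) is returned
unchanged under either setting.

Adaptive patches rank all in-mask voxels in a ±7-voxel window by the sum
of the max-normalized spatial distance and max-normalized mean absolute
signal difference (equal weights, lexicographic tie-break) and keep the
best 100, centre always included; no canonical weighting of the two
criteria exists, so equal weighting is this package's choice.  Each
voxel receives the centre row of its own patch reconstruction
(centre-voxel writeback), so no overlap averaging is needed and σ and P
maps are per-voxel.  The denoiser is fully deterministic.

Rician bias correction is method-of-moments, Ŝ = sqrt(max(M² − σ², 0)),
applied after denoising with the MPPCA σ map.  Note the clamp at zero
makes the corrected second moment 2e^(−1/2)σ² ≈ 1.21σ² at zero true
signal rather than exactly σ²; this residual floor is intrinsic to the
clamped estimator.  Because the full σ² is subtracted while denoising has
already removed most of the noise, diffusivities pick up a small
(~+0.3%) positive bias — visible in the benchmarks and documented there.

## Gibbs removal

Subvoxel-shift unringing tests 2·nshifts+1 shifts (default nshifts 20,
step 1/40 voxel) per line, scores each by the minimum of left/right total
variation over neighbour differences at offsets k1..k2 (defaults 1, 3)
and linearly interpolates the optimally shifted line back onto the grid.
2D images are split with the complementary spectral weights
G_a = (1+cos k_b)/(2+cos k_a+cos k_b) (and 1−G_a) so each axis' pass only
sees ringing oriented along it; the weights sum to one, so constant
images are preserved exactly.  3D input is processed slice-wise; the
through-slice axis is untouched.  nshifts/k1/k2 defaults follow the
subvoxel-shift literature; they are package choices, not quoted values.

Zero-filled partial Fourier adds ringing of period 2/(2·pf−1) voxels
(4 voxels at 6/8) along the phase-encode axis.  RPG runs the standard
pass first, then maps that period onto the 2-voxel period the shift
search assumes by resampling *toward a coarser grid*: for 6/8 the two
stride-2 interleaved line sets are unrung separately and recombined
(no samples discarded); for 7/8 the image is Fourier-upsampled ×3
(period 8/3 → 8) and the four stride-4 phases are unrung before Fourier
resampling back.  5/8 partial Fourier is rejected: correcting it would
oversmooth.  Two stability caveats, measured on strong-ringing fixtures
and asserted in the acceptance suite: a second pass still changes the
image by ~13% of the first-pass change (the corrector contracts but is
not 10×-contractive), and the partial-Fourier pass moves the slice mean
by ~0.4% (sharpening at strong curved edges does not cancel in the
mean); SuShi alone preserves the mean to <0.1%.

## Phantoms

**Multi-shell brain phantom.**  Geometry: nested ellipsoids — cortical
ribbon (isotropic-in-plane mildly kurtotic GM), four white-matter
quadrants, central CSF ventricle (D = 3 µm²/ms, K = 0).  The acquisition
default is the clinical protocol: 5 b0, 4 × b250, 20 × b1000,
60 × b2000 s/mm², directions quasi-uniform per shell.  Every WM voxel is
its own region: an axially symmetric tensor pair (AD 1.7, RD 0.45,
AK 0.8, RK 1.8 at the mean) oriented along its quadrant's tract direction
(x, y, z, oblique), perturbed by seeded random fields.  The heterogeneity
has two parts chosen to mirror real tissue: a spatially smooth component
(Gaussian fields, correlation length 2.5 voxels; orientation σ 0.25 rad,
magnitudes 12%) standing in for tract dispersion and fanning, and a
voxel-scale white component (orientation σ 0.08 rad ≈ 5°, magnitudes
12%, S0 3%) standing in for microstructural variability.  Without the
white part, adaptive patches are exactly low rank and denoising becomes
unrealistically lossless (no residual outliers at any SNR); without the
smooth part, neighbouring voxels are so dissimilar that any spatial
smoothing is ruinous.  Truth signals are exact forward-model evaluations,
so a WLLS refit of the noiseless phantom recovers every coefficient to
machine precision — this invariant is tested.

Noise: Sm = sqrt((Sr + σϵ₁)² + (σϵ₂)²), ϵ₁, ϵ₂ i.i.d. standard normal,
imaginary channel of the truth zero; one global σ = (mean WM b0)/SNR.
SNR grid {10, 15, 20, 25, 30, 60}; realizations reproducible from seeds.

What the stand-in does *not* emulate: real anatomy (crossing fibres,
partial-volume mixtures at tissue interfaces), spatially varying receive
noise, residual distortion or motion, or the exact heterogeneity of a
phantom derived from measured data.  Consequently the *rates* of rare
events (outlier percentages) and the *small* biases (sub-percent MD/AD
errors) carry the experimental claims only at order-of-magnitude
fidelity, while orderings driven by large effects (kurtosis noise bias,
shrinkage vs truncation, RPG vs SuShi) are robust.

**Gibbs phantom.**  A Shepp-Logan-style slice: ellipses of differing S0
and diffusion parameters (ventricles are free water for maximal edge
contrast; the brain interior is mildly anisotropic through-plane so all
seven scalars have nonzero truth).  Each volume is rendered at 4× target
resolution on FFT-aligned sample positions, centrally truncated in
k-space to the target grid, and zero-filled on the negative-frequency
side of the horizontal axis for 6/8 partial Fourier; magnitude
reconstruction is compared against the directly rendered target-grid
truth.  Four rectangular ringing ROIs flank the high-contrast ventricle
edges perpendicular to the phase-encode axis, each at least two voxels
clear of any region boundary so partial-volume voxels do not drown the
ringing signal.

## Evaluation harness

Percentage-error maps are signed, 100·(est−truth)/truth, NaN where truth
is zero; aggregation is the voxelwise median over noise realizations
(robust to all-outlier low-SNR maps), then the median over the ROI.
Outlier percentages are averaged over realizations.  ROIs are the
phantom's own ground-truth masks (whole-WM by default) rather than
registered atlas regions — registration is out of scope.  The smoothing
comparator is a normalized masked Gaussian convolution (FWHM 1.2 × voxel
size per axis) in which CSF voxels neither contribute weight nor receive
smoothed values.  The quadratic age fitter reports OLS coefficients,
adjusted R², the F-test p-value against intercept-only (the overall-model
test; the source material names no test), ×28 Bonferroni capped at 1,
and classifies the curve concave/convex with its vertex age only when
the vertex lies inside the fitted age range, otherwise monotone by the
slope sign.

## Pipeline

Canonical order: denoise → degibbs (RPG iff pf < 1) → external hook
(EPI distortion / eddy / motion tools; never re-implemented, disabled in
all tests) → b0 normalization → Rician correction → fit.  Configurations
violating this order are rejected, and the executed order with all
parameters lands in a JSON provenance report.  b0 normalization rescales
the second series by the ratio of Gaussian-smoothed (σ = 3 mm, truncated
at 4σ — the source phrasing is ambiguous between kernel width and
truncation radius, so both are explicit config knobs) mean-b0 images.
With two series, denoising and unringing run per series and the σ maps
are averaged after merging.  Identical configuration and seed give
bit-identical outputs.

## Problem sizes

Unit tests run phantoms at 16–32³-scale grids.  The simulation benchmarks
in the acceptance tests use a 40 × 40 × 10 grid (≈ 2 800 WM voxels),
three Rician realizations per SNR at six SNR levels, and the 128 × 128
Shepp-Logan slice with the full 89-volume protocol.
`scripts/acceptance.py` uses 44 × 44 × 12 with eight realizations for the
outlier statistics and six for the MD sweep.  These sizes are the
package's desk-scale defaults; statistics at these sizes are stable to
well within the tolerances they are compared at (outlier percentages vary
by roughly ±0.1 percentage point across seeds).

## Known limitations

* The adaptive-patch bilateral weights, search-window size, and unring
  shift/window defaults are literature-informed package choices.
* Eigenvalue shrinkage trades outliers for a small opposite-direction
  bias in the DTI scalars (strongest at low SNR); hard truncation is more
  accurate on medians, shrinkage cleaner on outliers.  Both are exposed.
* The Rician correction subtracts the full σ² after denoising and
  therefore slightly over-corrects; a residual-noise-aware correction is
  out of scope.
* Complex-valued data, spatially varying noise models beyond the
  per-voxel σ map, 5/8 partial Fourier, and any registration-based step
  are unsupported.
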